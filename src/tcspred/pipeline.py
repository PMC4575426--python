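"""Glue between the per-method scorers and tabular pipeline artefacts:
computing the six-feature table for a pair dataset, and reading/writing
it as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from tcspred import genome_context as gc
from tcspred.config import ContextConfig
from tcspred.coevolution import i2h_score, mirror_tree_score
from tcspred.errors import DataError
from tcspred.io_data import (
    Msa,
    PairDataset,
    PairedAlignment,
    ReferenceGenomeSet,
    TcsPair,
    build_paired_alignment,
    read_msa,
)
from tcspred.meta_svm import FEATURE_ORDER, FeatureVector, assemble_features

GAP = "-"


def ungapped(msa: Msa) -> str:
    return msa.query_row.replace(GAP, "")


def pair_scorers(
    pair: TcsPair,
    msa_hk: Msa | None,
    msa_rr: Msa | None,
    genomes: ReferenceGenomeSet | None,
    cfg: ContextConfig | None = None,
    min_species: int = 25,
    max_species: int = 50,
):
    """Build the six scorer callables for one pair.

    Coevolution scorers need both MSAs; genome-context scorers need the
    reference set plus the (ungapped) query sequences.  A scorer whose
    inputs are absent is simply omitted, which downstream imputes the
    feature as missing.
    """
    cfg = cfg or ContextConfig()
    scorers = {}
    pa_cache: dict[str, PairedAlignment] = {}

    def paired() -> PairedAlignment:
        if "pa" not in pa_cache:
            pa_cache["pa"] = build_paired_alignment(
                msa_hk, msa_rr, min_species, max_species)
        return pa_cache["pa"]

    if msa_hk is not None and msa_rr is not None:
        scorers["i2h"] = lambda p: i2h_score(paired())
        scorers["mt"] = lambda p: mirror_tree_score(paired())
        if genomes is not None:
            hk_seq, rr_seq = ungapped(msa_hk), ungapped(msa_rr)
            scorers["gf"] = lambda p: gc.gf_score(hk_seq, rr_seq, genomes, cfg)
            scorers["pp"] = lambda p: gc.pp_score_pair(
                p.hk_id, hk_seq, p.rr_id, rr_seq, genomes, cfg)
            scorers["gn"] = lambda p: gc.gn_score(hk_seq, rr_seq, genomes, cfg)
            scorers["go"] = lambda p: gc.go_score(hk_seq, rr_seq, genomes, cfg)
    return scorers


def compute_feature_table(
    ds: PairDataset,
    msa_dir: str | Path | None,
    genomes: ReferenceGenomeSet | None,
    cfg: ContextConfig | None = None,
    min_species: int = 25,
    max_species: int = 50,
) -> pd.DataFrame:
    """Six-feature table for every pair in the dataset.

    MSAs are looked up as ``<msa_dir>/<protein_id>.fasta``; a pair with
    no MSA on either side can still receive context features only when
    sequences are recoverable, otherwise its coevolution features are
    missing.  Output columns: pair metadata, the six scores, and one
    ``missing_*`` flag per score.
    """
    msa_dir = Path(msa_dir) if msa_dir is not None else None
    rows = []
    msa_cache: dict[str, Msa | None] = {}

    def get_msa(pid: str) -> Msa | None:
        if pid not in msa_cache:
            path = msa_dir / f"{pid}.fasta" if msa_dir else None
            msa_cache[pid] = read_msa(path) if path and path.exists() else None
        return msa_cache[pid]

    for pair in ds:
        scorers = pair_scorers(pair, get_msa(pair.hk_id), get_msa(pair.rr_id),
                               genomes, cfg, min_species, max_species)
        try:
            fv = assemble_features(pair, scorers)
        except DataError:
            fv = FeatureVector(np.zeros(6), np.ones(6, dtype=bool), pair)
        row = {"hk_id": pair.hk_id, "rr_id": pair.rr_id,
               "label": pair.label, "species": pair.species}
        for i, name in enumerate(FEATURE_ORDER):
            row[name] = fv.scores[i]
            row[f"missing_{name}"] = bool(fv.missing_mask[i])
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(df: pd.DataFrame,
                   exclude: tuple[str, ...] = ()) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature table; excluded features are zeroed (the
    vector stays six-dimensional so models remain comparable)."""
    bad = set(exclude) - set(FEATURE_ORDER)
    if bad:
        raise DataError(f"unknown feature names to exclude: {sorted(bad)}")
    X = df[list(FEATURE_ORDER)].to_numpy(dtype=float).copy()
    for name in exclude:
        X[:, FEATURE_ORDER.index(name)] = 0.0
    y = (df["label"] == "interacting").astype(int).to_numpy()
    return X, y
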