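"""Configuration containers for the pipeline.

All tunable constants live here: the homology-search significance cutoff
(1e-5), the mutual-information cutoff for phylogenetic profiling
(0.35 bits), the intergenic-distance cutoff for gene-neighbourhood
evidence (200 bp), and the minimum/maximum number of common species
retained in a paired alignment (25/50).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from tcspred.errors import DataError


@dataclass
class ContextConfig:
    """Parameters of the genome-context predictors (GF, PP, GN, GO).

    Attributes
    ----------
    evalue_cutoff:
        Significance threshold on the e-value of the best local-alignment
        hit; a hit at or below this counts as homology evidence.
    mi_cutoff:
        Mutual information (bits) below which a phylogenetic-profile pair
        is treated as no evidence.
    gn_distance_cutoff:
        Maximum intergenic gap (bp) for two genes to count as neighbours.
    sw_matrix:
        Name of the residue similarity table used for local alignments.
    sw_gap_open / sw_gap_extend:
        Affine gap penalties (positive numbers): a gap of length L costs
        ``sw_gap_open + sw_gap_extend * (L - 1)``.
    karlin_lambda / karlin_k:
        Parameters of the Karlin-Altschul-style e-value model
        ``E = K * m * n * exp(-lambda * S)`` mapping a local-alignment
        score S on a query of length m against a search space of n
        residues to an expected hit count.  The defaults were calibrated
        for the default scheme (BLOSUM50, affine 10/2) by fitting a
        Gumbel distribution to optimal local scores of random
        uniform-composition protein pairs; they must be re-calibrated if
        the matrix or gap penalties change.
    fusion_overlap_frac:
        A single protein matching both the HK and the RR counts as a
        fusion only when the two aligned spans on it overlap by less than
        this fraction of the shorter span; separates a genuine two-domain
        fusion from one shared domain.
    distance_ceiling:
        Cap on the Jukes-Cantor 16S distance when the observed proportion
        of differing sites saturates the correction (p >= 0.75).
    """

    evalue_cutoff: float = 1e-5
    mi_cutoff: float = 0.35
    gn_distance_cutoff: int = 200
    sw_matrix: str = "BLOSUM50"
    sw_gap_open: float = 10.0
    sw_gap_extend: float = 2.0
    karlin_lambda: float = 0.143
    karlin_k: float = 0.025
    fusion_overlap_frac: float = 0.2
    distance_ceiling: float = 5.0

    def __post_init__(self) -> None:
        for name in ("evalue_cutoff", "mi_cutoff", "gn_distance_cutoff",
                     "sw_gap_open", "sw_gap_extend", "karlin_lambda",
                     "karlin_k"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")


@dataclass
class SvmConfig:
    """Grid and cross-validation settings for the meta-classifier.

    The (c, g) lattice is the standard coarse LIBSVM-guide grid of powers
    of two; the classification threshold applies to the normalised
    decision value.
    """

    c_grid: list[float] = field(
        default_factory=lambda: [2.0 ** e for e in range(-5, 16, 2)])
    g_grid: list[float] = field(
        default_factory=lambda: [2.0 ** e for e in range(-15, 4, 2)])
    k_folds: int = 10
    threshold: float = 0.5


@dataclass
class RunConfig:
    """Top-level run configuration, loadable from YAML."""

    msa_dir: str | None = None
    genome_bundle: str | None = None
    pairs_csv: str | None = None
    model_file: str | None = None
    output_dir: str = "."
    min_species: int = 25
    max_species: int = 50
    k_folds: int = 10
    seed: int = 0
    log_level: str = "INFO"
    context: ContextConfig = field(default_factory=ContextConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        ctx = ContextConfig(**raw.pop("context", {}))
        svm = SvmConfig(**raw.pop("svm", {}))
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(context=ctx, svm=svm, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
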