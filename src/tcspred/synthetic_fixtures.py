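"""Seeded generators of synthetic inputs carrying the statistical
structure each predictor assumes, so the whole pipeline is testable
offline.

Three families of fixtures are produced:

* co-evolving MSA pairs, where a tunable fraction of column pairs
  mutates in lock-step through a shared latent state (the signal i2h and
  mirror-tree look for);
* reference genome sets with planted fusion proteins, neighbouring gene
  pairs, shared operons and presence/absence patterns (the signals GF,
  GN, GO and PP look for), returned together with a truth table;
* six-dimensional Gaussian feature tables with a class shift
  concentrated on the i2h slot, at the ~1:10 class imbalance typical of
  curated interaction data, for exercising the SVM meta-layer.

A synthetic stand-in for the curated gold-standard pair list is also
generated: 113 interacting pairs (56 encoded by neighbouring genes, 57
orphan) against 1134 experimentally validated non-interacting pairs,
distributed over six model organisms with the per-species class ratios
of real curated testing sets.  It reproduces the *structure* of curated
data (counts, species composition, adjacency), not its sequences.

Every generator is bit-reproducible given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import json
from pathlib import Path

from tcspred.errors import DataError
from tcspred.io_data import (
    GeneRecord,
    GenomeAnnotation,
    Msa,
    PairDataset,
    ReferenceGenomeSet,
    TcsPair,
    save_pair_dataset,
    write_genome_bundle,
    write_msa,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


@dataclass
class SimulationSpec:
    """Knobs of the synthetic generators.

    Defaults are sized so that every planted signal is recoverable while
    the full suite stays cheap: 30 species and 150 alignment columns for
    the coevolution fixtures, 8 reference genomes of a dozen ~100-residue
    proteins for the genome-context fixtures.
    """

    seed: int = 0
    n_species: int = 30
    msa_length: int = 150
    coupling: float = 0.5
    #: per-site chance a column deviates from its latent state
    noise: float = 0.02
    n_genomes: int = 8
    n_background_proteins: int = 12
    protein_length: int = 100
    class_separation: float = 2.0
    n_pairs: int = 1247
    imbalance: float = 113 / 1134
    planted_fusions: list[int] = field(default_factory=list)
    planted_neighbours: list[int] = field(default_factory=list)
    neighbour_gap: int = 150
    planted_operons: list[int] = field(default_factory=list)
    profile_hk: list[int] | None = None
    profile_rr: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise DataError("coupling must lie in [0, 1]")
        for name in ("n_species", "msa_length", "n_genomes",
                     "protein_length", "n_pairs"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# co-evolving MSAs
# ---------------------------------------------------------------------------

def _species_names(n: int) -> list[str]:
    return [f"Synthspecies sp{idx:03d}" for idx in range(1, n + 1)]


def simulate_coevolving_msas(spec: SimulationSpec) -> tuple[Msa, Msa]:
    """Two MSAs over the same species in which a ``coupling`` fraction of
    column pairs co-varies through a shared 4-state latent variable.

    Column i of protein A is coupled to column i of protein B for the
    first ``round(coupling * msa_length)`` columns: the two columns share
    both the latent state and its 4-letter residue mapping, mutating in
    lock-step up to the noise rate.  Uncoupled columns draw independent
    latent states through private alphabets.
    """
    if spec.n_species < 3:
        raise DataError("need at least 3 species")
    rng = np.random.default_rng(spec.seed)
    species = _species_names(spec.n_species)
    n, L = spec.n_species, spec.msa_length
    n_coupled = int(round(spec.coupling * L))
    aa = np.array(list(AMINO_ACIDS))

    def column_alphabet() -> np.ndarray:
        return rng.choice(20, size=4, replace=False)

    cols_a = np.empty((L, n), dtype="<U1")
    cols_b = np.empty((L, n), dtype="<U1")
    for j in range(L):
        coupled = j < n_coupled
        alpha_a = column_alphabet()
        alpha_b = alpha_a if coupled else column_alphabet()
        z_a = rng.integers(0, 4, size=n)
        z_b = z_a if coupled else rng.integers(0, 4, size=n)
        noise_a = rng.random(n) < spec.noise
        noise_b = rng.random(n) < spec.noise
        za = np.where(noise_a, rng.integers(0, 4, size=n), z_a)
        zb = np.where(noise_b, rng.integers(0, 4, size=n), z_b)
        cols_a[j] = aa[alpha_a[za]]
        cols_b[j] = aa[alpha_b[zb]]
    rows_a = {sp: "".join(cols_a[:, i]) for i, sp in enumerate(species)}
    rows_b = {sp: "".join(cols_b[:, i]) for i, sp in enumerate(species)}
    msa_a = Msa("synthHK", rows_a, query_species=species[0])
    msa_b = Msa("synthRR", rows_b, query_species=species[0])
    return msa_a, msa_b


# ---------------------------------------------------------------------------
# reference genomes with planted context signals
# ---------------------------------------------------------------------------

def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_16s(rng: np.random.Generator, length: int = 600) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in NUCLEOTIDES if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


def simulate_reference_genomes(
    spec: SimulationSpec,
    hk: str | None = None,
    rr: str | None = None,
) -> tuple[ReferenceGenomeSet, str, str, dict]:
    """Reference genomes with planted context events for a single HK/RR
    pair; returns ``(genome_set, hk_seq, rr_seq, truth)``.

    Planted events (genome indices are 0-based):

    * ``planted_fusions`` -- the genome encodes ``hk + rr`` as one protein;
    * ``planted_neighbours`` -- hk and rr genes sit ``neighbour_gap`` bp
      apart;
    * ``planted_operons`` -- the two genes share an operon id;
    * ``profile_hk`` / ``profile_rr`` -- explicit presence patterns.

    Background proteins are random-composition sequences, far enough
    from any real homolog that the significance cutoff excludes them.
    16S distances grow with genome index (per-genome mutation rates from
    1% to 20%), so aggregation weights vary across the set.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_genomes < 2:
        raise DataError("need at least 2 reference genomes")
    for lst in (spec.planted_fusions, spec.planted_neighbours,
                spec.planted_operons):
        if any(i < 0 or i >= spec.n_genomes for i in lst):
            raise DataError("planted genome index out of range")
    hk = hk or random_protein(rng, spec.protein_length)
    rr = rr or random_protein(rng, spec.protein_length)
    base_16s = _random_16s(rng)
    profile_hk = spec.profile_hk or [0] * spec.n_genomes
    profile_rr = spec.profile_rr or [0] * spec.n_genomes

    genomes: list[GenomeAnnotation] = []
    distances: dict[str, float] = {}
    truth: dict[str, dict] = {}
    for i in range(spec.n_genomes):
        gid = f"g{i:03d}"
        proteome: dict[str, str] = {}
        genes: list[GeneRecord] = []
        pos = 1

        def add_gene(gene_id: str, seq: str, gap: int,
                     operon_id: str | None = None) -> None:
            nonlocal pos
            start = pos + gap
            end = start + 3 * len(seq) - 1
            genes.append(GeneRecord(gene_id, start, end, "+", operon_id))
            proteome[gene_id] = seq
            pos = end + 1

        for b in range(spec.n_background_proteins):
            add_gene(f"{gid}_bg{b:02d}",
                     random_protein(rng, spec.protein_length),
                     gap=int(rng.integers(250, 700)))

        has_pair = (i in spec.planted_neighbours or i in spec.planted_operons
                    or (profile_hk[i] and profile_rr[i]))
        operon = f"{gid}_op1" if i in spec.planted_operons else None
        if has_pair:
            gap_between = spec.neighbour_gap if i in spec.planted_neighbours \
                else int(rng.integers(400, 900))
            add_gene(f"{gid}_hk", hk, gap=int(rng.integers(250, 700)),
                     operon_id=operon)
            add_gene(f"{gid}_rr", rr, gap=gap_between, operon_id=operon)
        else:
            if profile_hk[i]:
                add_gene(f"{gid}_hk", hk, gap=int(rng.integers(250, 700)))
            if profile_rr[i]:
                add_gene(f"{gid}_rr", rr, gap=int(rng.integers(250, 700)))
        if i in spec.planted_fusions:
            add_gene(f"{gid}_fus", hk + rr, gap=int(rng.integers(250, 700)))

        rate = 0.01 + 0.19 * i / max(spec.n_genomes - 1, 1)
        rrna = _mutate(rng, base_16s, rate)
        genomes.append(GenomeAnnotation(gid, genes, proteome, rrna))
        p_obs = sum(a != b for a, b in zip(base_16s, rrna)) / len(base_16s)
        distances[gid] = -0.75 * np.log(1 - 4 * min(p_obs, 0.7499) / 3)
        truth[gid] = {
            "fusion": i in spec.planted_fusions,
            "neighbour": i in spec.planted_neighbours,
            "operon": i in spec.planted_operons,
            "hk_present": bool(has_pair or profile_hk[i]
                               or i in spec.planted_fusions),
            "rr_present": bool(has_pair or profile_rr[i]
                               or i in spec.planted_fusions),
        }
    ref = ReferenceGenomeSet(genomes, distances)
    return ref, hk, rr, truth


# ---------------------------------------------------------------------------
# feature tables for the meta-layer
# ---------------------------------------------------------------------------

#: relative class shift per feature slot (i2h, MT, GF, PP, GN, GO):
#: the coevolution signals dominate, i2h most of all.
SHIFT_PROFILE = np.array([1.0, 0.5, 0.25, 0.25, 0.25, 0.25])


def simulate_feature_table(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Six-dimensional Gaussian feature table with the positive class
    shifted by ``class_separation`` times :data:`SHIFT_PROFILE`.

    Class sizes follow ``n_pairs`` and ``imbalance`` (positives :
    negatives); defaults give 113 positives vs 1134 negatives, the size
    and ~1:10 ratio of curated HK-RR interaction data.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_pairs * spec.imbalance / (1.0 + spec.imbalance)))
    n_neg = spec.n_pairs - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be requested")
    X_neg = rng.normal(size=(n_neg, 6))
    X_pos = rng.normal(size=(n_pos, 6)) + spec.class_separation * SHIFT_PROFILE
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


# ---------------------------------------------------------------------------
# complete multi-pair fixtures
# ---------------------------------------------------------------------------

def _roll(pattern: list[int], k: int) -> list[int]:
    k %= len(pattern)
    return pattern[-k:] + pattern[:-k]


def simulate_fixture(
    spec: SimulationSpec,
    n_pos: int = 4,
    n_neg: int = 8,
) -> tuple[PairDataset, dict[str, Msa], ReferenceGenomeSet, dict]:
    """A complete end-to-end fixture: pair list, per-protein MSAs, and a
    shared reference genome set with planted context signals.

    Interacting pairs get coupled MSAs (``spec.coupling``), co-presence
    across half the genomes, adjacency at ``spec.neighbour_gap`` bp, a
    shared operon, and one fused HK+RR protein; non-interacting pairs get
    uncoupled MSAs and presence patterns constructed to be statistically
    independent.  Returns ``(pairs, msas, genomes, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    n_g = spec.n_genomes
    half = [1] * (n_g // 2) + [0] * (n_g - n_g // 2)
    alt = ([1, 1, 0, 0] * ((n_g + 3) // 4))[:n_g]

    pairs: list[TcsPair] = []
    msas: dict[str, Msa] = {}
    plan: list[dict] = []
    truth: dict[str, dict] = {}
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        hk_id = f"hk{'P' if positive else 'N'}{i:02d}"
        rr_id = f"rr{'P' if positive else 'N'}{i:02d}"
        sub = SimulationSpec(
            seed=int(rng.integers(2**31)), n_species=spec.n_species,
            msa_length=spec.msa_length,
            coupling=spec.coupling if positive else 0.0, noise=spec.noise)
        ma, mb = simulate_coevolving_msas(sub)
        ma.query_id, mb.query_id = hk_id, rr_id
        msas[hk_id], msas[rr_id] = ma, mb
        hk_seq = ma.query_row.replace("-", "")
        rr_seq = mb.query_row.replace("-", "")
        label = "interacting" if positive else "non-interacting"
        pairs.append(TcsPair(hk_id, rr_id, label, "Synthspecies sp001",
                             positive or None))
        if positive:
            present = _roll(half, i)
            entry = {"hk_id": hk_id, "rr_id": rr_id, "hk": hk_seq, "rr": rr_seq,
                     "hk_present": present, "rr_present": present,
                     "adjacent": present, "operon": present,
                     "fusion": [int(present.index(1))]}
        else:
            entry = {"hk_id": hk_id, "rr_id": rr_id, "hk": hk_seq, "rr": rr_seq,
                     "hk_present": _roll(half, i), "rr_present": _roll(alt, i),
                     "adjacent": [], "operon": [], "fusion": []}
        plan.append(entry)
        truth[f"{hk_id}:{rr_id}"] = {
            "label": label, "coupling": sub.coupling,
            "fusion_genomes": entry["fusion"],
            "co_present": entry["hk_present"] if positive else [],
        }

    base_16s = _random_16s(rng)
    genomes: list[GenomeAnnotation] = []
    distances: dict[str, float] = {}
    for g in range(n_g):
        gid = f"g{g:03d}"
        proteome: dict[str, str] = {}
        genes: list[GeneRecord] = []
        pos_cursor = 1

        def add_gene(gene_id: str, seq: str, gap: int,
                     operon_id: str | None = None) -> None:
            nonlocal pos_cursor
            start = pos_cursor + gap
            end = start + 3 * len(seq) - 1
            genes.append(GeneRecord(gene_id, start, end, "+", operon_id))
            proteome[gene_id] = seq
            pos_cursor = end + 1

        for b in range(spec.n_background_proteins):
            add_gene(f"{gid}_bg{b:02d}",
                     random_protein(rng, spec.protein_length),
                     gap=int(rng.integers(250, 700)))
        for entry in plan:
            fused_here = g in entry["fusion"]
            both_here = entry["hk_present"][g] and entry["rr_present"][g]
            if fused_here:
                add_gene(f"{gid}_{entry['hk_id']}_fus", entry["hk"] + entry["rr"],
                         gap=int(rng.integers(250, 700)))
                continue  # the fused unit stands in for both genes
            operon = f"{gid}_{entry['hk_id']}_op" \
                if both_here and g in [j for j, v in enumerate(entry["operon"]) if v] \
                else None
            adjacent_here = both_here and entry["adjacent"] \
                and entry["adjacent"][g]
            if entry["hk_present"][g]:
                add_gene(f"{gid}_{entry['hk_id']}", entry["hk"],
                         gap=int(rng.integers(250, 700)), operon_id=operon)
            if entry["rr_present"][g]:
                gap = spec.neighbour_gap if adjacent_here \
                    else int(rng.integers(400, 900))
                add_gene(f"{gid}_{entry['rr_id']}", entry["rr"],
                         gap=gap, operon_id=operon)
        rate = 0.01 + 0.19 * g / max(n_g - 1, 1)
        rrna = _mutate(rng, base_16s, rate)
        p_obs = sum(a != b for a, b in zip(base_16s, rrna)) / len(base_16s)
        distances[gid] = -0.75 * np.log(1 - 4 * min(p_obs, 0.7499) / 3)
        genomes.append(GenomeAnnotation(gid, genes, proteome, rrna))
    ds = PairDataset(pairs, "synthetic end-to-end fixture")
    return ds, msas, ReferenceGenomeSet(genomes, distances), truth


def write_fixture(
    directory: str | Path,
    spec: SimulationSpec,
    n_pos: int = 4,
    n_neg: int = 8,
) -> None:
    """Materialise a complete fixture directory: ``pairs.csv``,
    ``msas/<protein_id>.fasta``, ``genomes/`` bundle and ``truth.json``."""
    directory = Path(directory)
    (directory / "msas").mkdir(parents=True, exist_ok=True)
    ds, msas, ref, truth = simulate_fixture(spec, n_pos, n_neg)
    save_pair_dataset(ds, directory / "pairs.csv")
    for pid, msa in msas.items():
        write_msa(msa, directory / "msas" / f"{pid}.fasta")
    write_genome_bundle(ref, directory / "genomes")
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# gold-standard-structured pair list
# ---------------------------------------------------------------------------

#: per-species (positives, negatives) of the synthetic gold standard,
#: following the class ratios of curated species-specific testing sets;
#: totals: 113 interacting / 1134 non-interacting.
GOLD_COMPOSITION = {
    "Escherichia coli": (22, 64),
    "Myxococcus xanthus": (20, 216),
    "Synechocystis sp.": (20, 319),
    "Mesorhizobium loti": (20, 364),
    "Caulobacter crescentus": (16, 86),
    "Mycobacterium tuberculosis": (15, 85),
}
#: of the 113 positives, 56 are encoded by neighbouring genes, 57 orphan
GOLD_N_NEIGHBOURING = 56


def simulate_gold_standard(
    seed: int = 0,
) -> tuple[PairDataset, dict[str, GenomeAnnotation]]:
    """Synthetic stand-in for the curated HK-RR gold standard.

    Emits 113 interacting and 1134 non-interacting pairs across six
    species (per-species composition in :data:`GOLD_COMPOSITION`), with
    toy per-species gene coordinates arranged so that exactly 56 of the
    positives are encoded by consecutive genes and 57 are orphans.
    Negatives are cross-pairings of the same proteins.  Returns the
    dataset and the per-species annotations used for adjacency splits.
    """
    rng = np.random.default_rng(seed)
    pairs: list[TcsPair] = []
    annotations: dict[str, GenomeAnnotation] = {}
    n_adjacent_left = GOLD_N_NEIGHBOURING
    total_pos = sum(p for p, _ in GOLD_COMPOSITION.values())
    assigned = 0
    for species, (n_pos, n_neg) in GOLD_COMPOSITION.items():
        tag = "".join(w[0] for w in species.split()[:2]).upper()
        # alternate adjacency across species so both splits contain
        # every species; the global count of adjacent positives is fixed
        genes: list[GeneRecord] = []
        pos_cursor = 1
        hk_ids, rr_ids = [], []
        for i in range(n_pos):
            remaining_pairs = total_pos - assigned
            adjacent = n_adjacent_left > 0 and (
                n_adjacent_left >= remaining_pairs or assigned % 2 == 0)
            assigned += 1
            if adjacent:
                n_adjacent_left -= 1
            hk_id = f"{tag}_hk{i:03d}"
            rr_id = f"{tag}_rr{i:03d}"
            hk_ids.append(hk_id)
            rr_ids.append(rr_id)
            glen = 900

            def place(gene_id: str) -> None:
                nonlocal pos_cursor
                start = pos_cursor + 300
                genes.append(GeneRecord(gene_id, start, start + glen - 1))
                pos_cursor = start + glen
            place(hk_id)
            if not adjacent:
                place(f"{tag}_sp{i:03d}")  # intervening gene: orphan pair
            place(rr_id)
            pairs.append(TcsPair(hk_id, rr_id, "interacting", species, adjacent))
        # negatives: deterministic sample of cross pairings
        cross = [(h, r) for h in hk_ids for r in rr_ids
                 if h[-3:] != r[-3:]]
        order = rng.permutation(len(cross))[:n_neg]
        if len(order) < n_neg:
            raise DataError(f"not enough cross pairs for {species}")
        for idx in sorted(order):
            h, r = cross[idx]
            pairs.append(TcsPair(h, r, "non-interacting", species, None))
        annotations[species] = GenomeAnnotation(tag, genes, {}, "")
    return PairDataset(pairs, "synthetic gold standard"), annotations
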