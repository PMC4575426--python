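"""Readers/writers for MSAs, pair datasets and genome bundles, plus
dataset splitting and train/test orthogonalisation.

File conventions
----------------
* MSAs are aligned FASTA; the source species is parsed from the header
  as a trailing bracketed organism name, e.g. ``>P0AE82 [Escherichia
  coli]``.  The convention is overridable with a regex.
* Pair sets are CSV with columns ``hk_id, rr_id, label, species`` (an
  optional ``adjacent`` column holds ``true``/``false``/empty).
* A genome bundle is a directory with a ``manifest.json`` naming, per
  genome, a proteome FASTA, a gene-coordinate TSV
  (``gene_id  start  end  strand  operon_id``), and a 16S rRNA FASTA.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tcspred.errors import DataError, FormatError, InsufficientOverlapError

Label = Literal["interacting", "non-interacting", "unknown"]
VALID_LABELS = ("interacting", "non-interacting", "unknown")

#: default species-tag convention: trailing "[Genus species ...]"
SPECIES_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TcsPair:
    """One candidate HK-RR pairing.

    ``adjacent`` records whether the two genes neighbour each other on
    the chromosome; ``None`` means unknown.  Labels come only from the
    input -- they are never inferred.
    """

    hk_id: str
    rr_id: str
    label: Label = "unknown"
    species: str = ""
    adjacent: bool | None = None

    def __post_init__(self) -> None:
        if self.hk_id == self.rr_id:
            raise DataError(f"pair has identical HK and RR id: {self.hk_id}")
        if self.label not in VALID_LABELS:
            raise DataError(f"invalid label {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.hk_id, self.rr_id)


@dataclass
class PairDataset:
    """Ordered, duplicate-free collection of candidate pairs."""

    pairs: list[TcsPair]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p.key in seen:
                raise DataError(f"duplicate pair {p.key}")
            seen.add(p.key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def n_positive(self) -> int:
        return sum(p.label == "interacting" for p in self.pairs)

    @property
    def n_negative(self) -> int:
        return sum(p.label == "non-interacting" for p in self.pairs)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.hk_id)
            out.add(p.rr_id)
        return out

    def subset(self, pairs: Iterable[TcsPair], provenance: str = "") -> "PairDataset":
        return PairDataset(list(pairs), provenance or self.provenance)


@dataclass
class Msa:
    """Per-protein multiple sequence alignment keyed by source species."""

    query_id: str
    rows: dict[str, str]
    query_species: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("MSA must contain at least one row")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"ragged alignment in MSA {self.query_id!r}: lengths {sorted(lengths)}")
        if lengths == {0}:
            raise FormatError(f"MSA {self.query_id!r} has zero-length rows")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> set[str]:
        return set(self.rows)

    @property
    def query_row(self) -> str:
        """Aligned sequence of the query; the first record by convention."""
        key = self.query_species if self.query_species in self.rows \
            else next(iter(self.rows))
        return self.rows[key]


@dataclass
class PairedAlignment:
    """Rows of two MSAs restricted to their common species, matched by
    position: ``rows_a[i]`` and ``rows_b[i]`` come from ``species_list[i]``.
    """

    species_list: list[str]
    rows_a: list[str]
    rows_b: list[str]

    def __post_init__(self) -> None:
        n = len(self.species_list)
        if len(self.rows_a) != n or len(self.rows_b) != n:
            raise DataError("paired alignment rows out of step with species")

    @property
    def n_species(self) -> int:
        return len(self.species_list)

    def swapped(self) -> "PairedAlignment":
        return PairedAlignment(list(self.species_list),
                               list(self.rows_b), list(self.rows_a))


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 1-based inclusive coordinates, GFF3-style."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    operon_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id}: start must precede end "
                f"({self.start} >= {self.end})")


@dataclass
class GenomeAnnotation:
    """One reference genome: gene coordinates, proteome, 16S rRNA."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    proteome: dict[str, str] = field(default_factory=dict)
    rrna_16s: str = ""

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise FormatError(f"duplicate gene ids in genome {self.genome_id}")

    def gene(self, gene_id: str) -> GeneRecord | None:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        return None

    def genes_by_position(self) -> list[GeneRecord]:
        return sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))


@dataclass
class ReferenceGenomeSet:
    """Reference genomes with per-genome evolutionary distances to the
    target organism and the aggregation weights derived from them
    (``w = 1 / (1 + d)``)."""

    genomes: list[GenomeAnnotation]
    distances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            raise DataError("duplicate genome ids in reference set")
        for gid, d in self.distances.items():
            if d < 0:
                raise DataError(f"negative distance for genome {gid}")

    @property
    def weights(self) -> dict[str, float]:
        return {g.genome_id: 1.0 / (1.0 + self.distances.get(g.genome_id, 0.0))
                for g in self.genomes}

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)


# ---------------------------------------------------------------------------
# MSA I/O
# ---------------------------------------------------------------------------

def _pct_identity(a: str, b: str) -> float:
    """Percent identity over columns where neither row is gapped."""
    same = total = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        total += 1
        same += x == y
    return 100.0 * same / total if total else 0.0


def read_msa(path: str | Path, species_re: re.Pattern = SPECIES_RE) -> Msa:
    """Read an aligned FASTA into an :class:`Msa`.

    The species is taken from the trailing bracketed organism name in
    each header.  On duplicate species the row with the highest identity
    to the query (first record) is kept, with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    query_id = records[0].id
    query_seq = str(records[0].seq)
    if len(query_seq) == 0:
        raise FormatError(f"zero-length record {query_id!r} in {path}")
    rows: dict[str, str] = {}
    query_species: str | None = None
    for rec in records:
        m = species_re.search(rec.description)
        if not m:
            raise FormatError(
                f"record {rec.id!r} in {path} has no parseable species tag")
        sp = m.group(1).strip()
        seq = str(rec.seq)
        if query_species is None:
            query_species = sp
        if sp in rows:
            warnings.warn(
                f"duplicate species {sp!r} in {path}; keeping the row most "
                "identical to the query", stacklevel=2)
            if _pct_identity(seq, query_seq) <= _pct_identity(rows[sp], query_seq):
                continue
        rows[sp] = seq
    return Msa(query_id=query_id, rows=rows, query_species=query_species)


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write an :class:`Msa` back to aligned FASTA (inverse of read_msa)."""
    records = []
    order = list(msa.rows)
    if msa.query_species in msa.rows:  # query row first, round-trip stable
        order.remove(msa.query_species)
        order.insert(0, msa.query_species)
    for i, sp in enumerate(order):
        rid = msa.query_id if i == 0 else f"{msa.query_id}_h{i}"
        records.append(SeqRecord(Seq(msa.rows[sp]), id=rid, description=f"[{sp}]"))
    SeqIO.write(records, str(path), "fasta")


def filter_homologs(
    hits: Sequence[tuple[str, float, float]],
    min_id: float = 30.0,
    max_id: float = 95.0,
    min_cov: float = 70.0,
) -> list[tuple[str, float, float]]:
    """Filter homolog hits to a band of sequence identity and a minimum
    alignment coverage, discarding both near-identical and very remote
    homologs so that the retained set is diverse yet reliable.

    Each hit is ``(sequence, pct_identity, pct_coverage)``.
    """
    for _, ident, cov in hits:
        if not (0 <= ident <= 100 and 0 <= cov <= 100):
            raise DataError("identity/coverage must lie in [0, 100]")
    return [h for h in hits if min_id <= h[1] <= max_id and h[2] >= min_cov]


def build_paired_alignment(
    msa_a: Msa,
    msa_b: Msa,
    min_species: int = 25,
    max_species: int = 50,
) -> PairedAlignment:
    """Match two MSAs on their common species.

    If more than ``max_species`` species are shared, the ones whose rows
    are most identical to the respective query sequences (mean of the
    two identities, ties broken lexicographically by species name) are
    kept.  Fewer than ``min_species`` common species raises
    :class:`InsufficientOverlapError`; the pair's coevolution features
    are then treated as missing.
    """
    common = sorted(msa_a.species & msa_b.species)
    if len(common) < min_species:
        raise InsufficientOverlapError(
            f"{len(common)} common species < minimum {min_species}")
    if len(common) > max_species:
        qa, qb = msa_a.query_row, msa_b.query_row
        scored = sorted(
            common,
            key=lambda sp: (-(_pct_identity(msa_a.rows[sp], qa)
                              + _pct_identity(msa_b.rows[sp], qb)) / 2.0, sp))
        common = sorted(scored[:max_species])
    return PairedAlignment(
        species_list=common,
        rows_a=[msa_a.rows[sp] for sp in common],
        rows_b=[msa_b.rows[sp] for sp in common])


# ---------------------------------------------------------------------------
# pair datasets
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("hk_id", "rr_id", "label", "species")


def load_pair_dataset(path: str | Path, provenance: str = "") -> PairDataset:
    """Load a pair CSV (``hk_id, rr_id, label, species[, adjacent]``)."""
    pairs: list[TcsPair] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            label = row["label"].strip()
            if label not in VALID_LABELS:
                raise FormatError(
                    f"{path} line {i}: unknown label token {label!r}")
            adj_raw = (row.get("adjacent") or "").strip().lower()
            adjacent = {"true": True, "false": False, "": None}.get(adj_raw)
            if adjacent is None and adj_raw not in ("", ):
                raise FormatError(
                    f"{path} line {i}: bad adjacent value {adj_raw!r}")
            try:
                pairs.append(TcsPair(row["hk_id"].strip(), row["rr_id"].strip(),
                                     label, row["species"].strip(), adjacent))
            except DataError as exc:
                raise FormatError(f"{path} line {i}: {exc}") from exc
    try:
        return PairDataset(pairs, provenance or str(path))
    except DataError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_pair_dataset(ds: PairDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*_CSV_FIELDS, "adjacent"])
        for p in ds.pairs:
            adj = "" if p.adjacent is None else str(p.adjacent).lower()
            writer.writerow([p.hk_id, p.rr_id, p.label, p.species, adj])


def split_by_adjacency(
    ds: PairDataset,
    annotations: dict[str, GenomeAnnotation],
) -> tuple[PairDataset, PairDataset, PairDataset]:
    """Partition a dataset into neighbouring and orphan pairs.

    A pair is *neighbouring* when its two genes are consecutive on the
    chromosome (no intervening annotated gene), else *orphan*.  Pairs
    whose genes cannot be located go to an *unresolved* bucket with a
    warning.  Returns ``(neighbouring, orphan, unresolved)``.
    """
    neigh: list[TcsPair] = []
    orphan: list[TcsPair] = []
    unresolved: list[TcsPair] = []
    order_cache: dict[str, list[str]] = {}
    for p in ds.pairs:
        ann = annotations.get(p.species)
        if ann is None:
            warnings.warn(f"no annotation for species {p.species!r}; "
                          f"pair {p.key} unresolved", stacklevel=2)
            unresolved.append(p)
            continue
        if p.species not in order_cache:
            order_cache[p.species] = [g.gene_id for g in ann.genes_by_position()]
        order = order_cache[p.species]
        try:
            ia, ib = order.index(p.hk_id), order.index(p.rr_id)
        except ValueError:
            warnings.warn(f"gene of pair {p.key} not found in "
                          f"{p.species!r} annotation", stacklevel=2)
            unresolved.append(p)
            continue
        (neigh if abs(ia - ib) == 1 else orphan).append(p)
    return (ds.subset(neigh, "neighbouring"),
            ds.subset(orphan, "orphan"),
            ds.subset(unresolved, "unresolved"))


def orthogonalize(
    train: PairDataset,
    test: PairDataset,
    mode: Literal["pair", "protein"] = "protein",
) -> PairDataset:
    """Remove training pairs that overlap the test set.

    ``mode="pair"`` drops exact (hk, rr) matches; ``mode="protein"``
    drops any training pair sharing a protein with any test pair, the
    stricter guard against information leakage.
    """
    if mode == "pair":
        test_keys = {p.key for p in test.pairs}
        kept = [p for p in train.pairs if p.key not in test_keys]
    elif mode == "protein":
        test_proteins = test.proteins()
        kept = [p for p in train.pairs
                if p.hk_id not in test_proteins and p.rr_id not in test_proteins]
    else:
        raise DataError(f"unknown orthogonalisation mode {mode!r}")
    if not kept:
        raise DataError("orthogonalisation removed every training pair")
    return train.subset(kept, f"{train.provenance} (orthogonal to test, {mode})")


# ---------------------------------------------------------------------------
# genome bundles
# ---------------------------------------------------------------------------

def write_genome_bundle(ref: ReferenceGenomeSet, directory: str | Path) -> None:
    """Write a reference genome set as a manifest + per-genome files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"genomes": [], "distances": dict(ref.distances)}
    for g in ref.genomes:
        faa = f"{g.genome_id}.faa"
        tsv = f"{g.genome_id}.genes.tsv"
        rna = f"{g.genome_id}.16s.fna"
        SeqIO.write(
            [SeqRecord(Seq(seq), id=pid, description="")
             for pid, seq in g.proteome.items()],
            str(directory / faa), "fasta")
        with open(directory / tsv, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["gene_id", "start", "end", "strand", "operon_id"])
            for gene in g.genes:
                w.writerow([gene.gene_id, gene.start, gene.end, gene.strand,
                            gene.operon_id or ""])
        SeqIO.write([SeqRecord(Seq(g.rrna_16s), id=f"{g.genome_id}_16S",
                               description="")],
                    str(directory / rna), "fasta")
        manifest["genomes"].append(
            {"genome_id": g.genome_id, "proteome": faa, "genes": tsv, "rrna_16s": rna})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_genome_bundle(directory: str | Path) -> ReferenceGenomeSet:
    """Read a genome bundle written by :func:`write_genome_bundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    genomes: list[GenomeAnnotation] = []
    for entry in manifest["genomes"]:
        proteome = {r.id: str(r.seq)
                    for r in SeqIO.parse(str(directory / entry["proteome"]), "fasta")}
        genes: list[GeneRecord] = []
        with open(directory / entry["genes"], newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                genes.append(GeneRecord(
                    row["gene_id"], int(row["start"]), int(row["end"]),
                    row["strand"], row["operon_id"] or None))
        rna_recs = list(SeqIO.parse(str(directory / entry["rrna_16s"]), "fasta"))
        rrna = str(rna_recs[0].seq) if rna_recs else ""
        genomes.append(GenomeAnnotation(entry["genome_id"], genes, proteome, rrna))
    return ReferenceGenomeSet(genomes, manifest.get("distances", {}))
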