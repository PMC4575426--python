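"""Genome-context interaction evidence: gene fusion (GF), phylogenetic
profiling (PP), gene neighbourhood (GN) and gene operon (GO), aggregated
over a reference genome set with 16S-derived evolutionary-distance
weights.

Homology search backend
-----------------------
Presence/absence and ortholog calls use optimal local alignment
(Smith-Waterman with affine gaps, via Biopython's pairwise aligner) over
each reference proteome, with significance judged by a
Karlin-Altschul-style e-value model ``E = K * m * n * exp(-lambda * S)``
(m = query length, n = residues searched).  The default parameters
(lambda = 0.23, K = 0.1, BLOSUM50, gap 10/2) approximate gapped
protein-search statistics; tabular hit lists from an external search
tool can be plugged in instead through :func:`profile_from_hits`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from tcspred.config import ContextConfig
from tcspred.errors import DataError, MissingFeature
from tcspred.io_data import GeneRecord, GenomeAnnotation, ReferenceGenomeSet

Evidence = Literal["evidence", "no-evidence", "not-evaluable"]


# ---------------------------------------------------------------------------
# local alignment + e-value model
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load(matrix)
    # first gap position costs gap_open, each further one gap_extend
    aln.open_gap_score = -gap_open
    aln.extend_gap_score = -gap_extend
    return aln


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM50",
    gap_open: float = 10.0,
    gap_extend: float = 2.0,
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Optimal local alignment score and the aligned span on each sequence.

    Gap cost is affine: a run of L gaps costs
    ``gap_open + gap_extend * (L - 1)``.  Spans are half-open [start, end)
    on the unaligned sequences.  Returns ``(score, span_a, span_b)``;
    a score of 0 means no positive-scoring local alignment exists and the
    spans are empty.
    """
    if not a or not b:
        raise DataError("sequences must be non-empty")
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    best = aligner.align(a, b)[0]
    sa, sb = best.aligned
    span_a = (int(sa[0][0]), int(sa[-1][1]))
    span_b = (int(sb[0][0]), int(sb[-1][1]))
    return float(score), span_a, span_b


def evalue(score: float, m: int, n: int, cfg: ContextConfig | None = None) -> float:
    """Expected number of chance local alignments at or above ``score``
    for a length-m query over n searched residues."""
    cfg = cfg or ContextConfig()
    return cfg.karlin_k * m * n * math.exp(-cfg.karlin_lambda * score)


# ---------------------------------------------------------------------------
# phylogenetic profiling
# ---------------------------------------------------------------------------

@dataclass
class PhyloProfile:
    """Binary presence/absence of a protein across reference genomes."""

    protein_id: str
    presence: dict[str, int]
    evalue_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        bad = {v for v in self.presence.values()} - {0, 1}
        if bad:
            raise DataError(f"profile entries must be 0/1, got {bad}")

    def vector(self, genome_ids: list[str]) -> np.ndarray:
        return np.array([self.presence[g] for g in genome_ids], dtype=int)


@dataclass
class ContextEvidence:
    """Per-genome evidence calls for one context method on one pair."""

    method: Literal["GF", "GN", "GO"]
    per_genome: dict[str, Evidence] = field(default_factory=dict)


def best_hit(
    protein: str,
    genome: GenomeAnnotation,
    cfg: ContextConfig | None = None,
) -> tuple[str | None, float, float]:
    """Best local-alignment hit of ``protein`` in a genome's proteome.

    Returns ``(gene_id, score, evalue)``; gene_id is None when the
    proteome is empty or no hit is significant at ``cfg.evalue_cutoff``.
    """
    cfg = cfg or ContextConfig()
    if not genome.proteome:
        return None, 0.0, math.inf
    space = sum(len(s) for s in genome.proteome.values())
    best_id, best_score = None, 0.0
    aligner = _aligner(cfg.sw_matrix, cfg.sw_gap_open, cfg.sw_gap_extend)
    for pid, seq in genome.proteome.items():
        if not seq:
            continue
        s = aligner.score(protein, seq)
        if s > best_score or (s == best_score and best_id is not None and pid < best_id):
            best_id, best_score = pid, s
    e = evalue(best_score, len(protein), space, cfg)
    if best_id is None or e > cfg.evalue_cutoff:
        return None, best_score, e
    return best_id, best_score, e


def reciprocal_best_hit(
    query_id: str,
    query_proteome: dict[str, str],
    genome: GenomeAnnotation,
    cfg: ContextConfig | None = None,
) -> str | None:
    """Ortholog call by reciprocal best hit: the best hit of the query in
    the reference genome must itself hit back the query in the query's
    own proteome."""
    cfg = cfg or ContextConfig()
    hit, _, _ = best_hit(query_proteome[query_id], genome, cfg)
    if hit is None:
        return None
    query_genome = GenomeAnnotation("query", [], dict(query_proteome), "")
    back, _, _ = best_hit(genome.proteome[hit], query_genome, cfg)
    return hit if back == query_id else None


def build_phylo_profile(
    protein_id: str,
    protein: str,
    genomes: ReferenceGenomeSet,
    cfg: ContextConfig | None = None,
) -> PhyloProfile:
    """Presence/absence of a protein across the reference genomes."""
    cfg = cfg or ContextConfig()
    if len(genomes) == 0:
        raise DataError("reference genome set is empty")
    presence: dict[str, int] = {}
    for g in genomes:
        if not g.proteome:
            warnings.warn(f"genome {g.genome_id} has an empty proteome",
                          stacklevel=2)
            presence[g.genome_id] = 0
            continue
        hit, _, _ = best_hit(protein, g, cfg)
        presence[g.genome_id] = int(hit is not None)
    return PhyloProfile(protein_id, presence, cfg.evalue_cutoff)


def profile_from_hits(
    protein_id: str,
    hits: dict[str, float],
    genomes: ReferenceGenomeSet,
    cfg: ContextConfig | None = None,
) -> PhyloProfile:
    """Build a profile from externally computed best-hit e-values per
    genome (e.g. parsed from tabular search output)."""
    cfg = cfg or ContextConfig()
    presence = {g.genome_id: int(hits.get(g.genome_id, math.inf) <= cfg.evalue_cutoff)
                for g in genomes}
    return PhyloProfile(protein_id, presence, cfg.evalue_cutoff)


def mutual_information(p: PhyloProfile, q: PhyloProfile) -> float:
    """Mutual information (bits) between two presence/absence profiles,
    ``MI = sum f(x,y) log2 f(x,y) / (f(x) f(y))`` with 0*log0 = 0."""
    if set(p.presence) != set(q.presence):
        raise DataError("profiles cover different genome sets")
    ids = sorted(p.presence)
    x = p.vector(ids)
    y = q.vector(ids)
    n = len(ids)
    mi = 0.0
    for xv in (0, 1):
        for yv in (0, 1):
            fxy = float(((x == xv) & (y == yv)).sum()) / n
            if fxy == 0.0:
                continue
            fx = float((x == xv).sum()) / n
            fy = float((y == yv).sum()) / n
            mi += fxy * math.log2(fxy / (fx * fy))
    return max(mi, 0.0)


def pp_score(p: PhyloProfile, q: PhyloProfile,
             cfg: ContextConfig | None = None) -> float:
    """Phylogenetic-profile feature: mutual information in bits, clamped
    to [0, 1], zeroed below the evidence cutoff (default 0.35 bits).

    A constant profile (protein present everywhere or nowhere) carries no
    co-occurrence information: :class:`MissingFeature` is raised.
    """
    cfg = cfg or ContextConfig()
    for prof in (p, q):
        vals = set(prof.presence.values())
        if len(vals) < 2:
            raise MissingFeature(
                f"profile of {prof.protein_id} is constant across genomes")
    mi = min(mutual_information(p, q), 1.0)
    return mi if mi >= cfg.mi_cutoff else 0.0


# ---------------------------------------------------------------------------
# gene fusion
# ---------------------------------------------------------------------------

def detect_fusion(
    hk: str,
    rr: str,
    genome: GenomeAnnotation,
    cfg: ContextConfig | None = None,
) -> Evidence:
    """Rosetta-stone evidence: some single protein in the genome aligns
    significantly to BOTH the HK and the RR, on spans that overlap by
    less than ``cfg.fusion_overlap_frac`` of the shorter span (two
    distinct domains, not one shared domain)."""
    cfg = cfg or ContextConfig()
    space = sum(len(s) for s in genome.proteome.values())
    if space == 0:
        return "no-evidence"
    for seq in genome.proteome.values():
        if not seq:
            continue
        s_hk, _, span_hk = smith_waterman(hk, seq, cfg.sw_matrix,
                                          cfg.sw_gap_open, cfg.sw_gap_extend)
        if evalue(s_hk, len(hk), space, cfg) > cfg.evalue_cutoff:
            continue
        s_rr, _, span_rr = smith_waterman(rr, seq, cfg.sw_matrix,
                                          cfg.sw_gap_open, cfg.sw_gap_extend)
        if evalue(s_rr, len(rr), space, cfg) > cfg.evalue_cutoff:
            continue
        overlap = min(span_hk[1], span_rr[1]) - max(span_hk[0], span_rr[0])
        shorter = min(span_hk[1] - span_hk[0], span_rr[1] - span_rr[0])
        if shorter > 0 and overlap < cfg.fusion_overlap_frac * shorter:
            return "evidence"
    return "no-evidence"


# ---------------------------------------------------------------------------
# neighbourhood / operon
# ---------------------------------------------------------------------------

def intergenic_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Base pairs between two genes (end of upstream to start of
    downstream); overlapping genes yield 0."""
    up, down = (a, b) if a.start <= b.start else (b, a)
    return max(0, down.start - up.end - 1)


def neighbourhood_evidence(
    hk_gene: GeneRecord,
    rr_gene: GeneRecord,
    cfg: ContextConfig | None = None,
) -> Evidence:
    """Evidence when the intergenic gap is at most the 200-bp cutoff;
    strand-agnostic (operon calls carry strand logic upstream)."""
    cfg = cfg or ContextConfig()
    gap = intergenic_gap(hk_gene, rr_gene)
    return "evidence" if gap <= cfg.gn_distance_cutoff else "no-evidence"


def operon_evidence(hk_gene: GeneRecord, rr_gene: GeneRecord) -> Evidence:
    """Evidence only when both genes carry the same operon id; a missing
    call on either side is conservatively no evidence."""
    if hk_gene.operon_id is None or rr_gene.operon_id is None:
        return "no-evidence"
    return "evidence" if hk_gene.operon_id == rr_gene.operon_id else "no-evidence"


# ---------------------------------------------------------------------------
# 16S distances and weighted aggregation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=2)
def _nt_aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1
    aln.mismatch_score = -1
    aln.open_gap_score = -3
    aln.extend_gap_score = -1
    return aln


def evolutionary_distance_16s(a: str, b: str,
                              cfg: ContextConfig | None = None) -> float:
    """Jukes-Cantor-corrected distance between two 16S rRNA sequences.

    The sequences are globally aligned, the proportion p of differing
    (non-gap) aligned sites is measured, and
    ``d = -(3/4) ln(1 - 4p/3)``; p >= 0.75 saturates the correction and
    the distance is capped at ``cfg.distance_ceiling``.
    """
    cfg = cfg or ContextConfig()
    if not a or not b:
        raise DataError("16S sequences must be non-empty")
    if a == b:
        return 0.0
    aln = _nt_aligner().align(a, b)[0]
    sa, sb = aln[0], aln[1]
    diff = total = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        total += 1
        diff += x != y
    if total == 0:
        raise DataError("16S sequences share no aligned sites")
    p = diff / total
    if p >= 0.75:
        return cfg.distance_ceiling
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return min(d, cfg.distance_ceiling)


def aggregate_context_score(
    ev: ContextEvidence,
    genomes: ReferenceGenomeSet,
) -> float:
    """Weighted fraction of evaluable genomes showing evidence, with
    weights ``w = 1/(1+d)`` decreasing in 16S distance: evidence from
    close relatives counts more because shared context there is less
    likely to be ancestral noise.  Raises :class:`MissingFeature` when
    no genome is evaluable.
    """
    weights = genomes.weights
    unknown = set(ev.per_genome) - set(weights)
    if unknown:
        raise DataError(f"evidence for genomes outside the reference set: "
                        f"{sorted(unknown)}")
    wsum = esum = 0.0
    for gid, call in ev.per_genome.items():
        if call == "not-evaluable":
            continue
        w = weights[gid]
        wsum += w
        if call == "evidence":
            esum += w
    if wsum == 0.0:
        raise MissingFeature(f"{ev.method}: no evaluable genome")
    return esum / wsum


# ---------------------------------------------------------------------------
# per-pair feature scores
# ---------------------------------------------------------------------------

def gf_score(hk: str, rr: str, genomes: ReferenceGenomeSet,
             cfg: ContextConfig | None = None) -> float:
    """Gene-fusion feature: distance-weighted fraction of reference
    genomes encoding a single HK+RR hybrid protein."""
    cfg = cfg or ContextConfig()
    ev = ContextEvidence("GF", {g.genome_id: detect_fusion(hk, rr, g, cfg)
                                for g in genomes})
    return aggregate_context_score(ev, genomes)


def _adjacency_evidence(
    method: Literal["GN", "GO"],
    hk: str,
    rr: str,
    genomes: ReferenceGenomeSet,
    cfg: ContextConfig,
) -> ContextEvidence:
    per: dict[str, Evidence] = {}
    for g in genomes:
        hit_hk, _, _ = best_hit(hk, g, cfg)
        hit_rr, _, _ = best_hit(rr, g, cfg)
        if hit_hk is None or hit_rr is None or hit_hk == hit_rr:
            per[g.genome_id] = "not-evaluable"
            continue
        gene_hk = g.gene(hit_hk)
        gene_rr = g.gene(hit_rr)
        if gene_hk is None or gene_rr is None:
            per[g.genome_id] = "not-evaluable"
            continue
        if method == "GN":
            per[g.genome_id] = neighbourhood_evidence(gene_hk, gene_rr, cfg)
        else:
            per[g.genome_id] = operon_evidence(gene_hk, gene_rr)
    return ContextEvidence(method, per)


def gn_score(hk: str, rr: str, genomes: ReferenceGenomeSet,
             cfg: ContextConfig | None = None) -> float:
    """Gene-neighbourhood feature: weighted fraction of genomes where
    the two orthologs sit within the intergenic-distance cutoff."""
    cfg = cfg or ContextConfig()
    return aggregate_context_score(
        _adjacency_evidence("GN", hk, rr, genomes, cfg), genomes)


def go_score(hk: str, rr: str, genomes: ReferenceGenomeSet,
             cfg: ContextConfig | None = None) -> float:
    """Gene-operon feature: weighted fraction of genomes where the two
    orthologs share a transcription unit."""
    cfg = cfg or ContextConfig()
    return aggregate_context_score(
        _adjacency_evidence("GO", hk, rr, genomes, cfg), genomes)


def pp_score_pair(hk_id: str, hk: str, rr_id: str, rr: str,
                  genomes: ReferenceGenomeSet,
                  cfg: ContextConfig | None = None) -> float:
    """Phylogenetic-profiling feature for a pair of sequences."""
    cfg = cfg or ContextConfig()
    p = build_phylo_profile(hk_id, hk, genomes, cfg)
    q = build_phylo_profile(rr_id, rr, genomes, cfg)
    return pp_score(p, q, cfg)
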