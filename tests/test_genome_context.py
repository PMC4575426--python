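import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tcspred import genome_context as gc
from tcspred.config import ContextConfig
from tcspred.errors import DataError, MissingFeature
from tcspred.io_data import GeneRecord, GenomeAnnotation, ReferenceGenomeSet
from tcspred.synthetic_fixtures import (
    SimulationSpec,
    random_protein,
    simulate_reference_genomes,
)

CFG = ContextConfig()


def sw_oracle(a, b, matrix, gap_open, gap_extend):
    """Exhaustive affine-gap local-alignment DP (Gotoh three-state).

    The first residue of a gap costs ``gap_open``, each further one
    ``gap_extend`` -- the same convention as the implementation under
    test.
    """
    n, m = len(a), len(b)
    neg = -math.inf
    M = np.full((n + 1, m + 1), 0.0)     # match/mismatch state
    Ix = np.full((n + 1, m + 1), neg)    # gap in b (consuming a)
    Iy = np.full((n + 1, m + 1), neg)    # gap in a (consuming b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0,
                          M[i - 1, j - 1] + s,
                          Ix[i - 1, j - 1] + s,
                          Iy[i - 1, j - 1] + s)
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestSmithWaterman:
    def test_self_alignment_sums_diagonal(self):
        mat = substitution_matrices.load("BLOSUM50")
        seq = "HEAGAWGHEE"
        score, span_a, span_b = gc.smith_waterman(seq, seq)
        assert score == sum(mat[c, c] for c in seq)
        assert span_a == span_b == (0, len(seq))

    def test_textbook_instance_matches_dp_oracle(self):
        # the classic HEAGAWGHEE / PAWHEAE exercise with linear gap 8
        mat = substitution_matrices.load("BLOSUM50")
        score, _, _ = gc.smith_waterman("HEAGAWGHEE", "PAWHEAE",
                                        gap_open=8.0, gap_extend=8.0)
        assert score == sw_oracle("HEAGAWGHEE", "PAWHEAE", mat, 8.0, 8.0)
        assert score == 28.0

    def test_matches_dp_oracle_on_short_random_pairs(self, rng):
        mat = substitution_matrices.load("BLOSUM50")
        alphabet = list("ACDE")  # reduced alphabet keeps the oracle cheap
        for _ in range(40):
            a = "".join(rng.choice(alphabet, size=rng.integers(1, 13)))
            b = "".join(rng.choice(alphabet, size=rng.integers(1, 13)))
            score, _, _ = gc.smith_waterman(a, b, gap_open=10.0, gap_extend=2.0)
            assert score == sw_oracle(a, b, mat, 10.0, 2.0), (a, b)

    def test_symmetry(self, rng):
        alphabet = list("ACDEFGHIKL")
        for _ in range(10):
            a = "".join(rng.choice(alphabet, size=10))
            b = "".join(rng.choice(alphabet, size=8))
            sa, _, _ = gc.smith_waterman(a, b)
            sb, _, _ = gc.smith_waterman(b, a)
            assert sa == sb

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            gc.smith_waterman("", "ACDE")


class TestPhyloProfile:
    def test_planted_presence_recovered_exactly(self):
        pattern = [1, 0, 1, 1, 0, 1, 0, 0]
        spec = SimulationSpec(seed=21, n_genomes=8, n_background_proteins=6,
                              protein_length=60, profile_hk=pattern,
                              profile_rr=pattern)
        ref, hk, _, truth = simulate_reference_genomes(spec)
        prof = gc.build_phylo_profile("hk", hk, ref, CFG)
        assert [prof.presence[g.genome_id] for g in ref] == pattern

    def test_random_protein_absent_everywhere(self, rng):
        spec = SimulationSpec(seed=22, n_genomes=4, n_background_proteins=6,
                              protein_length=60)
        ref, _, _, _ = simulate_reference_genomes(spec)
        probe = random_protein(rng, 60)
        prof = gc.build_phylo_profile("probe", probe, ref, CFG)
        assert set(prof.presence.values()) == {0}

    def test_empty_genome_set_is_error(self):
        with pytest.raises(DataError):
            gc.build_phylo_profile("p", "ACDE", ReferenceGenomeSet([]), CFG)


def profile(pid, bits):
    return gc.PhyloProfile(pid, {f"g{i}": b for i, b in enumerate(bits)})


class TestMutualInformation:
    def test_identical_balanced_profiles_one_bit(self):
        p = profile("a", [1, 1, 1, 1, 0, 0, 0, 0])
        assert gc.mutual_information(p, p) == pytest.approx(1.0)

    def test_independent_profiles_zero_bits(self):
        p = profile("a", [1, 1, 0, 0])
        q = profile("b", [1, 0, 1, 0])
        assert gc.mutual_information(p, q) == pytest.approx(0.0)

    def test_matches_direct_sum_oracle(self):
        p = profile("a", [1, 1, 1, 0])
        q = profile("b", [1, 1, 0, 1])
        # direct evaluation of the four-term sum
        expected = (0.5 * math.log2(0.5 / (0.75 * 0.75))
                    + 0.25 * math.log2(0.25 / (0.75 * 0.25))
                    + 0.25 * math.log2(0.25 / (0.25 * 0.75))
                    + 0.0)
        assert gc.mutual_information(p, q) == pytest.approx(expected)

    def test_symmetry_and_entropy_bound_on_random_profiles(self, rng):
        def entropy(bits):
            f = sum(bits) / len(bits)
            if f in (0.0, 1.0):
                return 0.0
            return -f * math.log2(f) - (1 - f) * math.log2(1 - f)
        for _ in range(50):
            p = profile("a", rng.integers(0, 2, size=10).tolist())
            q = profile("b", rng.integers(0, 2, size=10).tolist())
            mi = gc.mutual_information(p, q)
            assert mi == pytest.approx(gc.mutual_information(q, p))
            assert mi <= min(entropy(list(p.presence.values())),
                             entropy(list(q.presence.values()))) + 1e-12

    def test_mismatched_genome_sets_rejected(self):
        with pytest.raises(DataError):
            gc.mutual_information(profile("a", [1, 0]), profile("b", [1, 0, 1]))


class TestPpScore:
    def test_above_cutoff_passes_through(self):
        # MI of these profiles is ~0.61 bits, above the 0.35 cutoff
        p = profile("a", [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        q = profile("b", [1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        mi = gc.mutual_information(p, q)
        assert 0.35 < mi < 1.0
        assert gc.pp_score(p, q, CFG) == pytest.approx(mi)

    def test_below_cutoff_zeroed(self):
        p = profile("a", [1, 1, 1, 0, 0, 0, 1, 0])
        q = profile("b", [1, 1, 0, 1, 0, 1, 0, 0])
        assert gc.mutual_information(p, q) < 0.35
        assert gc.pp_score(p, q, CFG) == 0.0

    def test_identical_balanced_profiles_score_one(self):
        p = profile("a", [1, 1, 0, 0])
        assert gc.pp_score(p, p, CFG) == 1.0

    def test_constant_profile_signals_missing(self):
        p = profile("a", [1, 1, 1, 1])
        q = profile("b", [1, 0, 1, 0])
        with pytest.raises(MissingFeature):
            gc.pp_score(p, q, CFG)


@pytest.fixture(scope="module")
def planted():
    spec = SimulationSpec(seed=31, n_genomes=6, n_background_proteins=6,
                          protein_length=60, planted_fusions=[2, 5])
    return simulate_reference_genomes(spec)


class TestFusion:
    def test_planted_fusions_recovered_exactly(self, planted):
        ref, hk, rr, truth = planted
        calls = {g.genome_id: gc.detect_fusion(hk, rr, g, CFG) for g in ref}
        expected = {gid: "evidence" if t["fusion"] else "no-evidence"
                    for gid, t in truth.items()}
        assert calls == expected

    def test_separate_proteins_are_not_fusion(self):
        spec = SimulationSpec(seed=32, n_genomes=2, n_background_proteins=4,
                              protein_length=60, planted_neighbours=[0])
        ref, hk, rr, _ = simulate_reference_genomes(spec)
        assert gc.detect_fusion(hk, rr, ref.genomes[0], CFG) == "no-evidence"

    def test_single_side_match_is_not_fusion(self, rng):
        spec = SimulationSpec(seed=33, n_genomes=2, n_background_proteins=4,
                              protein_length=60, profile_hk=[1, 0])
        ref, hk, rr, _ = simulate_reference_genomes(spec)
        # genome 0 contains hk (twice counting nothing else) but never rr
        assert gc.detect_fusion(hk, rr, ref.genomes[0], CFG) == "no-evidence"


class TestAdjacencyEvidence:
    def test_gap_within_cutoff(self):
        a = GeneRecord("a", 100, 400)
        b = GeneRecord("b", 551, 900)  # gap 150
        assert gc.intergenic_gap(a, b) == 150
        assert gc.neighbourhood_evidence(a, b, CFG) == "evidence"

    def test_gap_just_beyond_cutoff(self):
        a = GeneRecord("a", 100, 400)
        b = GeneRecord("b", 602, 900)  # gap 201
        assert gc.intergenic_gap(a, b) == 201
        assert gc.neighbourhood_evidence(a, b, CFG) == "no-evidence"

    def test_overlapping_genes_count_as_adjacent(self):
        a = GeneRecord("a", 100, 500)
        b = GeneRecord("b", 400, 900)
        assert gc.intergenic_gap(a, b) == 0
        assert gc.neighbourhood_evidence(a, b, CFG) == "evidence"

    def test_operon_calls(self):
        a = GeneRecord("a", 1, 10, operon_id="op1")
        b = GeneRecord("b", 20, 30, operon_id="op1")
        c = GeneRecord("c", 40, 50, operon_id="op2")
        d = GeneRecord("d", 60, 70, operon_id=None)
        assert gc.operon_evidence(a, b) == "evidence"
        assert gc.operon_evidence(a, c) == "no-evidence"
        assert gc.operon_evidence(a, d) == "no-evidence"


class TestDistance16s:
    def test_identical_sequences_zero(self):
        assert gc.evolutionary_distance_16s("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_ten_percent(self):
        a = "ACGT" * 25
        b = list(a)
        for i in range(0, 100, 10):  # exactly 10 % differing sites
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        d = gc.evolutionary_distance_16s(a, "".join(b))
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.10 / 3))

    def test_symmetry(self, rng):
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), size=120))
            b = "".join(rng.choice(list("ACGT"), size=120))
            assert gc.evolutionary_distance_16s(a, b) == pytest.approx(
                gc.evolutionary_distance_16s(b, a))

    def test_saturation_hits_ceiling(self):
        a = "A" * 100
        b = "C" * 100
        assert gc.evolutionary_distance_16s(a, b) == CFG.distance_ceiling


class TestAggregation:
    @staticmethod
    def _ref(distances):
        genomes = [GenomeAnnotation(gid, [], {"p": "ACDE"}, "")
                   for gid in distances]
        return ReferenceGenomeSet(genomes, distances)

    def test_full_evidence_is_one(self):
        ref = self._ref({"g0": 0.1, "g1": 0.9})
        ev = gc.ContextEvidence("GN", {"g0": "evidence", "g1": "evidence"})
        assert gc.aggregate_context_score(ev, ref) == 1.0

    def test_no_evidence_is_zero(self):
        ref = self._ref({"g0": 0.1, "g1": 0.9})
        ev = gc.ContextEvidence("GN", {"g0": "no-evidence", "g1": "no-evidence"})
        assert gc.aggregate_context_score(ev, ref) == 0.0

    def test_hand_evaluated_weighted_mean(self):
        # weights 1/(1+d): 1.0, 0.5, 0.25 -> evidence in the first only
        ref = self._ref({"g0": 0.0, "g1": 1.0, "g2": 3.0})
        ev = gc.ContextEvidence("GO", {"g0": "evidence", "g1": "no-evidence",
                                       "g2": "no-evidence"})
        assert gc.aggregate_context_score(ev, ref) == pytest.approx(1.0 / 1.75)

    def test_monotone_in_added_genomes(self):
        ref = self._ref({"g0": 0.2, "g1": 0.6, "g2": 1.4})
        base = gc.ContextEvidence("GN", {"g0": "evidence", "g1": "no-evidence"})
        s0 = gc.aggregate_context_score(base, ref)
        plus_ev = gc.ContextEvidence("GN", dict(base.per_genome, g2="evidence"))
        plus_no = gc.ContextEvidence("GN", dict(base.per_genome, g2="no-evidence"))
        assert gc.aggregate_context_score(plus_ev, ref) >= s0
        assert gc.aggregate_context_score(plus_no, ref) <= s0

    def test_nothing_evaluable_signals_missing(self):
        ref = self._ref({"g0": 0.1})
        ev = gc.ContextEvidence("GF", {"g0": "not-evaluable"})
        with pytest.raises(MissingFeature):
            gc.aggregate_context_score(ev, ref)


class TestPlantedContextOrdering:
    def test_planted_pairs_outscore_random_pairs(self):
        """GN/GO/GF/PP for planted interacting pairs dominate the scores
        of pairs with nothing planted (rank-sum over seeded replicates)."""
        from scipy.stats import mannwhitneyu

        planted_scores = {m: [] for m in ("gf", "pp", "gn", "go")}
        null_scores = {m: [] for m in ("gf", "pp", "gn", "go")}
        for seed in range(6):
            spec = SimulationSpec(
                seed=seed, n_genomes=6, n_background_proteins=5,
                protein_length=50, planted_fusions=[1],
                planted_neighbours=[0, 2, 4], planted_operons=[0, 2],
                profile_hk=[1, 0, 1, 0, 1, 0], profile_rr=[1, 0, 1, 0, 1, 0])
            ref, hk, rr, _ = simulate_reference_genomes(spec)
            planted_scores["gf"].append(gc.gf_score(hk, rr, ref, CFG))
            planted_scores["pp"].append(gc.pp_score_pair("h", hk, "r", rr, ref, CFG))
            planted_scores["gn"].append(gc.gn_score(hk, rr, ref, CFG))
            planted_scores["go"].append(gc.go_score(hk, rr, ref, CFG))
            null_spec = SimulationSpec(
                seed=seed + 100, n_genomes=6, n_background_proteins=5,
                protein_length=50,
                profile_hk=[1, 1, 1, 0, 0, 0], profile_rr=[1, 1, 0, 0, 1, 0])
            nref, nhk, nrr, _ = simulate_reference_genomes(null_spec)
            null_scores["gf"].append(gc.gf_score(nhk, nrr, nref, CFG))
            try:
                null_scores["pp"].append(
                    gc.pp_score_pair("h", nhk, "r", nrr, nref, CFG))
            except MissingFeature:
                null_scores["pp"].append(0.0)
            null_scores["gn"].append(gc.gn_score(nhk, nrr, nref, CFG))
            null_scores["go"].append(gc.go_score(nhk, nrr, nref, CFG))
        for m in ("gf", "pp", "gn", "go"):
            stat, p = mannwhitneyu(planted_scores[m], null_scores[m],
                                   alternative="greater")
            assert p < 0.05, (m, planted_scores[m], null_scores[m])
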