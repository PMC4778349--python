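import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from utrscreen import enrichment
from utrscreen import simulate as sim
from conftest import random_alignment_block


def fisher_oracle(b, n, B, N):
    """Exact-integer minimum-likelihood enumeration (independent oracle)."""
    denom = math.comb(N, B)
    weights = {
        k: math.comb(n, k) * math.comb(N - n, B - k)
        for k in range(max(0, n + B - N), min(n, B) + 1)
    }
    obs = weights[b]
    return sum(w for w in weights.values() if w <= obs) / denom


class TestFisherTwoSided:
    def test_small_table_enumeration(self):
        # full enumeration for (b=2, n=2, B=2, N=4): pmf = (1/6, 2/3, 1/6);
        # outcomes no more likely than the observed 1/6 are both tails -> 1/3
        assert enrichment.fisher_two_sided(2, 2, 2, 4) == pytest.approx(1 / 3)
        assert fisher_oracle(2, 2, 2, 4) == pytest.approx(1 / 3)

    def test_no_association_p_one(self):
        assert enrichment.fisher_two_sided(1, 2, 2, 4) == pytest.approx(1.0)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            enrichment.fisher_two_sided(3, 2, 2, 4)
        with pytest.raises(ValueError):
            enrichment.fisher_two_sided(0, 5, 2, 4)

    @given(
        st.integers(1, 25),
        st.data(),
    )
    @settings(max_examples=150)
    def test_matches_exact_enumeration(self, N, data):
        n = data.draw(st.integers(0, N))
        B = data.draw(st.integers(0, N))
        b = data.draw(st.integers(max(0, n + B - N), min(n, B)))
        p = enrichment.fisher_two_sided(b, n, B, N)
        assert p == pytest.approx(fisher_oracle(b, n, B, N), rel=1e-9, abs=1e-12)

    def test_matches_scipy_convention(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(4, 200))
            n = int(rng.integers(1, N))
            B = int(rng.integers(1, N))
            b = int(rng.integers(max(0, n + B - N), min(n, B) + 1))
            table = [[b, n - b], [B - b, N - n - B + b]]
            _, p_scipy = fisher_exact(table, alternative="two-sided")
            p_ours = enrichment.fisher_two_sided(b, n, B, N)
            assert p_ours == pytest.approx(p_scipy, rel=1e-6)

    def test_doubling_convention_at_least_tail(self):
        p_min = enrichment.fisher_two_sided(5, 10, 10, 50, convention="minlike")
        p_dbl = enrichment.fisher_two_sided(5, 10, 10, 50, convention="doubling")
        assert 0 < p_min <= 1
        assert 0 < p_dbl <= 1


class TestCategoryEnrichment:
    def test_category_equals_universe(self):
        u = {f"AAAAAAA{c}" for c in "ACGU"}
        res = enrichment.category_enrichment(u, u, u)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_fold_arithmetic(self):
        motifs = list(sim.generate_truth(1000, (0, 0, 1), 1.5, seed=2).motif)
        universe = set(motifs)
        category = set(motifs[:10])
        calls = set(motifs[:5]) | set(motifs[500:595])  # b=5, B=100
        res = enrichment.category_enrichment(category, calls, universe)
        assert (res.b, res.n, res.B, res.N) == (5, 10, 100, 1000)
        assert res.fold == pytest.approx(5.0)

    def test_fold_identity(self):
        # fold * (B/N) * n = b whenever fold is defined
        rng = np.random.default_rng(4)
        motifs = list(sim.generate_truth(200, (0, 0, 1), 1.5, seed=4).motif)
        universe = set(motifs)
        for _ in range(20):
            category = set(rng.choice(motifs, size=rng.integers(1, 100), replace=False))
            calls = set(rng.choice(motifs, size=rng.integers(1, 100), replace=False))
            res = enrichment.category_enrichment(category, calls, universe)
            assert res.fold * (res.B / res.N) * res.n == pytest.approx(res.b)

    def test_outside_universe_dropped_with_warning(self):
        motifs = [f"AAAAAAA{c}" for c in "ACGU"]
        universe = set(motifs[:3])
        with pytest.warns(UserWarning, match="outside"):
            res = enrichment.category_enrichment(
                set(motifs), set(motifs[:2]), universe
            )
        assert res.n == 3
        assert res.N == 3

    def test_biased_category_detected_in_simulation(self):
        truth = sim.generate_truth(800, (0.25, 0.25, 0.5), 1.5, seed=5)
        cells = sim.simulate_cells(truth, 50, 1.0, seed=6)
        pops = sim.gate_and_sort(cells, sim.SortScheme(), seed=7)
        table = sim.sequence_counts(pops, depth=500_000, seed=8)
        from utrscreen import scoring

        scored = scoring.score_screen(table)
        universe = set(scored.index)
        calls = set(scored.index[scored["label"] == "activating"])
        # category generated activating-biased: the true activating motifs
        category = set(truth.motif[truth.true_class == "activating"]) & universe
        res = enrichment.category_enrichment(category, calls, universe)
        assert res.fold > 1
        assert res.p < 0.05

    def test_subsampling_preserves_direction(self):
        rng = np.random.default_rng(9)
        motifs = list(sim.generate_truth(2000, (0, 0, 1), 1.5, seed=9).motif)
        universe = set(motifs)
        category = set(motifs[:200])
        calls = set(motifs[:100]) | set(rng.choice(motifs[200:], 100, replace=False))
        full = enrichment.category_enrichment(category, calls, universe)
        sub_motifs = set(rng.choice(motifs, size=1000, replace=False))
        sub = enrichment.category_enrichment(
            category & sub_motifs, calls & sub_motifs, sub_motifs
        )
        assert full.fold > 1
        assert sub.fold > 1
        assert sub.fold == pytest.approx(full.fold, rel=0.35)


class TestReverseComplement:
    def test_hand_oracle(self):
        assert enrichment.reverse_complement("ACAGGGUA") == "UACCCUGU"

    @given(st.text(alphabet="ACGU", min_size=8, max_size=8))
    def test_involution(self, motif):
        assert enrichment.reverse_complement(
            enrichment.reverse_complement(motif)
        ) == motif

    def test_self_complementary_palindromes_exist(self):
        # even-length self-reverse-complementary 8mers exist in RNA sense too
        assert enrichment.reverse_complement("ACGUACGU") == "ACGUACGU"

    def test_dna_input_normalized(self):
        assert enrichment.reverse_complement("ACAGGGTA") == "UACCCUGU"


class TestRevcompScoreCorrelation:
    def test_symmetric_scores_r_one(self):
        rng = np.random.default_rng(10)
        scores = {}
        for _ in range(50):
            m = "".join(rng.choice(list("ACGU"), 8))
            scores[m] = float(rng.normal())
            scores[enrichment.reverse_complement(m)] = scores[m]
        r, _, n = enrichment.revcomp_score_correlation(scores)
        assert n >= 25
        assert r == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(11)
        scores = {}
        for _ in range(2000):
            m = "".join(rng.choice(list("ACGU"), 8))
            scores[m] = float(rng.normal())
            scores[enrichment.reverse_complement(m)] = float(rng.normal())
        r, _, n = enrichment.revcomp_score_correlation(scores)
        assert n > 500
        assert abs(r) < 0.1

    def test_no_pairs_warns(self):
        with pytest.warns(UserWarning, match="pairs"):
            r, p, n = enrichment.revcomp_score_correlation({"AAAAAAAA": 1.0})
        assert math.isnan(r)
        assert n == 0


class TestConservedInstanceCount:
    def test_identical_rows_single_occurrence(self):
        block = ["GGGACAGGGTAGGG"] * 4
        assert enrichment.conserved_instance_count(block, "ACAGGGUA") == 1

    def test_substitution_in_one_species_breaks(self):
        block = ["GGGACAGGGTAGGG"] * 3 + ["GGGACAGGGAAGGG"]
        assert enrichment.conserved_instance_count(block, "ACAGGGUA") == 0

    def test_gap_breaks_conservation(self):
        block = ["GGGACAGGGTAGGG"] * 3 + ["GGGACAG-GTAGGG"]
        assert enrichment.conserved_instance_count(block, "ACAGGGUA") == 0

    def test_overlapping_occurrences_counted(self):
        block = ["AAAAAAAAAA"] * 4
        assert enrichment.conserved_instance_count(block, "AAAAAAAA") == 3

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(12)
        motif = "ACGTACGT"
        for i in range(100):
            block = random_alignment_block(
                rng, length=80, conserved=bool(i % 2),
                motif=motif if i % 3 == 0 else None,
            )
            observed = enrichment.conserved_instance_count(block, motif)
            # independent naive scan: column-by-column comparison
            expected = 0
            k = len(motif)
            for start in range(len(block[0]) - k + 1):
                cols = [row[start : start + k] for row in block]
                if cols[0] == motif and all(c == cols[0] for c in cols):
                    expected += 1
            assert observed == expected

    def test_unequal_row_lengths_rejected(self):
        with pytest.raises(ValueError):
            enrichment.conserved_instance_count(["ACGT", "ACG"], "ACGU")


class TestConservationSignal:
    def test_homopolymer_degenerate_shuffle(self):
        block = ["CCAAAAAAAACC"] * 4
        res = enrichment.conservation_signal("AAAAAAAA", [block], n_shuffles=10, seed=1)
        assert res.signal == pytest.approx(1.0)

    def test_absent_motif_zero_signal(self):
        block = ["C" * 40] * 4
        res = enrichment.conservation_signal("AAAAAAAA", [block], n_shuffles=10, seed=1)
        assert res.conserved_count == 0
        assert res.signal == 0.0

    def test_planted_signal_above_one(self):
        # long fully conserved blocks give shuffled controls a nonzero
        # background rate; the planted motif stands far above it
        rng = np.random.default_rng(13)
        motif = "ACGGTCAT"
        blocks = [
            random_alignment_block(rng, length=2000, conserved=True, motif=motif)
            for _ in range(40)
        ]
        res = enrichment.conservation_signal(motif, blocks, n_shuffles=30, seed=2)
        assert res.conserved_count >= 40
        assert res.signal > 1.0
        # an unplanted random motif sits near the shuffled background
        other = enrichment.conservation_signal(
            "GTATCCGA", blocks, n_shuffles=30, seed=3
        )
        assert other.conserved_count < res.conserved_count

    def test_zero_background_planted_signal_unbounded(self):
        # C-padding guarantees no permutation of the motif matches any
        # shifted window (the C count is too high off-target)
        motif = "ACGGTCAT"
        blocks = [["CCCC" + motif + "CCCC"] * 4]
        with pytest.warns(UserWarning, match="unbounded"):
            res = enrichment.conservation_signal(motif, blocks, n_shuffles=20, seed=4)
        assert res.conserved_count == 1
        assert res.signal == math.inf

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        blocks = [random_alignment_block(rng, conserved=True) for _ in range(5)]
        a = enrichment.conservation_signal("ACGTACGT", blocks, n_shuffles=20, seed=9)
        b = enrichment.conservation_signal("ACGTACGT", blocks, n_shuffles=20, seed=9)
        assert a == b

    def test_shuffles_preserve_composition(self):
        rng = np.random.default_rng(15)
        motif = "AACCGGUU"
        for _ in range(50):
            s = enrichment.shuffle_motif(motif, rng)
            assert sorted(s) == sorted(motif)
            assert s != motif
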