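"""Jaccard-index scoring, multimer matching, centroid distances, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allobench.benchmark import (
    accuracy_curve,
    best_ji_match,
    centroid_distance,
    jaccard_index,
    normalize_prediction,
    score_prediction,
    summarize,
)
from allobench.core_model import BenchmarkResult, PredictionRecord, ResidueRef
from conftest import build_structure


def R(n, chain="A"):
    return ResidueRef(chain, n)


def rset(*nums, chain="A"):
    return frozenset(R(n, chain) for n in nums)


class TestJaccardIndex:
    def test_identical_sets_score_one(self):
        K = rset(1, 2, 3)
        assert jaccard_index(K, K) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert jaccard_index(rset(1, 2), rset(3, 4)) == 0.0

    def test_known_overlap(self):
        K = rset(*range(10))
        P = rset(*range(5, 15))
        assert jaccard_index(K, P) == pytest.approx(5 / 15)

    def test_empty_prediction_zero(self):
        assert jaccard_index(rset(1), frozenset()) == 0.0

    def test_empty_known_site_rejected(self):
        with pytest.raises(ValueError, match="empty_known_site"):
            jaccard_index(frozenset(), rset(1))

    def test_matches_set_arithmetic_oracle_random(self):
        """1000+ random set pairs against direct |K∩P|/|K∪P| arithmetic."""
        rng = np.random.default_rng(777)
        for _ in range(1000):
            K = frozenset(R(int(n)) for n in rng.integers(0, 40, rng.integers(1, 20)))
            P = frozenset(R(int(n)) for n in rng.integers(0, 40, rng.integers(0, 20)))
            expected = len(K & P) / len(K | P) if P else 0.0
            assert jaccard_index(K, P) == expected
            if P:
                assert jaccard_index(P, K) == jaccard_index(K, P)  # symmetric
            assert 0.0 <= jaccard_index(K, P) <= 1.0

    def test_closed_form_equal_sizes(self):
        """|K|=|P|=n with overlap m gives JI = m/(2n−m), all n<=20, m<=n."""
        for n in range(1, 21):
            for m in range(0, n + 1):
                K = rset(*range(n))
                P = rset(*range(n - m, 2 * n - m))
                assert jaccard_index(K, P) == pytest.approx(m / (2 * n - m))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.sets(st.integers(0, 50), min_size=1, max_size=25),
           st.sets(st.integers(0, 50), max_size=25))
    def test_oracle_property(self, k_nums, p_nums):
        K, P = rset(*k_nums), rset(*p_nums)
        expected = len(K & P) / len(K | P) if P else 0.0
        assert jaccard_index(K, P) == expected


class TestBestJiMatch:
    def test_best_of_multiple_known_sites(self):
        topmost = rset(4, 5, 6)
        known = [rset(10, 11), rset(4, 5, 6), rset(4, 5)]
        assert best_ji_match(topmost, known) == (1.0, 1)

    def test_single_site_reduces_to_ji(self):
        topmost = rset(1, 2)
        known = [rset(1, 2, 3)]
        ji, idx = best_ji_match(topmost, known)
        assert (ji, idx) == (jaccard_index(known[0], topmost), 0)

    def test_empty_topmost(self):
        assert best_ji_match(frozenset(), [rset(1)]) == (0.0, 0)

    def test_tie_goes_to_lowest_index(self):
        topmost = rset(1)
        known = [rset(1, 2), rset(1, 3)]
        assert best_ji_match(topmost, known)[1] == 0


class TestNormalizePrediction:
    def _structure(self):
        return build_structure([("A", i, "CA", (float(i), 0, 0))
                                for i in range(1, 101)])

    def test_spurious_removed_valid_retained(self):
        p = PredictionRecord("t", "x", [(rset(10, 9999), None)])
        cleaned, n = normalize_prediction(p, self._structure())
        assert cleaned.ranked_sites[0][0] == rset(10)
        assert n == 1

    def test_all_valid_identity(self):
        p = PredictionRecord("t", "x", [(rset(1, 2, 3), 0.9)])
        cleaned, n = normalize_prediction(p, self._structure())
        assert cleaned.ranked_sites == p.ranked_sites and n == 0

    def test_fully_spurious_site_removed(self):
        p = PredictionRecord("t", "x", [(rset(9998, 9999), None)])
        cleaned, n = normalize_prediction(p, self._structure())
        assert cleaned.ranked_sites == [] and n == 2
        result = score_prediction(cleaned, [rset(1)])
        assert result.ji == 0.0 and result.failed


class TestCentroidDistance:
    def _structure(self):
        atoms = [("A", 1, "CA", (0.0, 0.0, 0.0)),
                 ("A", 2, "CA", (0.0, 0.0, 0.0)),
                 ("A", 3, "CA", (3.0, 4.0, 0.0)),
                 ("A", 4, "CA", (3.0, 4.0, 0.0)),
                 ("A", 5, "CA", (10.0, 0.0, 0.0))]
        return build_structure(atoms)

    def test_identical_sites_zero(self):
        s = self._structure()
        assert centroid_distance(rset(1, 2), rset(1, 2), s) == 0.0

    def test_three_four_five_triangle(self):
        s = self._structure()
        d = centroid_distance(rset(1, 2), rset(3, 4), s)
        assert d == pytest.approx(5.0)
        result = BenchmarkResult("x", "t", ji=0.5, matched_known_site_index=0,
                                 centroid_distance=d)
        assert result.inverse_distance == pytest.approx(0.2)

    def test_single_residue_sites(self):
        s = self._structure()
        assert centroid_distance(rset(1), rset(5), s) == pytest.approx(10.0)

    def test_site_without_ca_rejected(self):
        s = build_structure([("A", 1, "CB", (0, 0, 0)), ("A", 2, "CA", (1, 0, 0))])
        with pytest.raises(ValueError):
            centroid_distance(rset(1), rset(2), s)

    def test_coincident_centroid_inverse_absent(self):
        result = BenchmarkResult("x", "t", ji=1.0, matched_known_site_index=0,
                                 centroid_distance=0.0)
        assert result.inverse_distance is None


class TestAccuracyCurve:
    def _results(self, jis, tool="t"):
        return [BenchmarkResult(f"p{i}", tool, ji=ji, matched_known_site_index=0)
                for i, ji in enumerate(jis)]

    def test_counting(self):
        curve = accuracy_curve(self._results([0.0, 0.2, 0.6]), cutoffs=(0.5,))
        assert curve.percent_above["t"] == [pytest.approx(100 / 3)]

    def test_cutoff_zero_all_positive(self):
        curve = accuracy_curve(self._results([0.1, 0.5, 0.9]), cutoffs=(0.0,))
        assert curve.percent_above["t"] == [100.0]

    def test_all_zero_scores(self):
        curve = accuracy_curve(self._results([0.0, 0.0]), cutoffs=(0.0, 0.5))
        assert curve.percent_above["t"] == [0.0, 0.0]

    def test_non_increasing_in_cutoff(self, rng):
        jis = rng.uniform(0, 1, size=50).tolist()
        curve = accuracy_curve(self._results(jis),
                               cutoffs=tuple(np.linspace(0, 1, 11)))
        values = curve.percent_above["t"]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_duplicate_protein_tool_rejected(self):
        results = self._results([0.5]) + self._results([0.6])
        with pytest.raises(ValueError, match="duplicate"):
            accuracy_curve(results)


class TestSummarize:
    def _results(self, jis, tool="t"):
        return [BenchmarkResult(f"p{i}", tool, ji=ji, matched_known_site_index=0)
                for i, ji in enumerate(jis)]

    def test_median_and_mean(self):
        summary = summarize(self._results([0.0, 0.0, 1.0]))
        assert summary.loc["t", "median_ji"] == 0.0
        assert summary.loc["t", "mean_ji"] == pytest.approx(1 / 3)

    def test_even_n_median_mean_of_middle_two(self):
        summary = summarize(self._results([0.0, 0.2, 0.4, 1.0]))
        assert summary.loc["t", "median_ji"] == pytest.approx(0.3)

    def test_all_equal(self):
        summary = summarize(self._results([0.5] * 4))
        assert summary.loc["t", "median_ji"] == summary.loc["t", "mean_ji"] == 0.5

    def test_single_value(self):
        summary = summarize(self._results([0.7]))
        assert summary.loc["t", "median_ji"] == summary.loc["t", "mean_ji"] == 0.7


class TestJiVsInverseDistance:
    def test_positive_rank_correlation_on_slide_away_ensemble(self):
        """As a predicted site slides away from the known site along the
        chain, JI decreases while centroid distance grows: their inverse
        relationship shows JI also measures 3D proximity."""
        from scipy.stats import spearmanr
        n = 60
        atoms = [("A", i, "CA", (3.8 * i, 0.0, 0.0)) for i in range(1, n + 1)]
        s = build_structure(atoms)
        K = rset(*range(10, 20))
        jis, inv_d = [], []
        for shift in range(0, 30, 2):
            P = rset(*range(10 + shift, 20 + shift))
            jis.append(jaccard_index(K, P))
            d = centroid_distance(K, P, s)
            inv_d.append(1.0 / d if d > 0 else np.inf)
        finite = [(a, b) for a, b in zip(jis, inv_d) if np.isfinite(b)]
        rho, _ = spearmanr([a for a, _ in finite], [b for _, b in finite])
        assert rho > 0
        # within the overlapping regime the relationship is almost perfectly
        # monotone (ties at JI=0 once the sites are disjoint dilute rho)
        overlapping = [(a, b) for a, b in finite if a > 0]
        rho_overlap, _ = spearmanr([a for a, _ in overlapping],
                                   [b for _, b in overlapping])
        assert rho_overlap > 0.9
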