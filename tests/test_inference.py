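import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tssvar.binning import BinGrid, BinMatrix, BinProfile
from tssvar.inference import (
    bcs_class_anova,
    bonferroni,
    bvf_delta_test,
    dagostino_skewness,
    fisher_combine,
    neutral_bin_test,
    pearson_test,
    profile_ttest_pair,
    wilcoxon_updown,
    window_split,
)
from tssvar.synthetic_data import simulate_bin_counts

GRID = BinGrid()


def make_matrix(counts, label=None):
    counts = np.asarray(counts, dtype=float)
    ids = [f"t{i}" for i in range(counts.shape[0])]
    return BinMatrix(ids, counts, "BVF", label=label)


def make_profile(mean, signal="x"):
    mean = np.asarray(mean, dtype=float)
    return BinProfile(GRID.indices, mean, np.zeros(200), np.full(200, 1.0), signal)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.001], 200)[0] == pytest.approx(0.2)
        assert bonferroni([0.9], 200)[0] == 1.0
        assert bonferroni([0.123], 1)[0] == pytest.approx(0.123)

    def test_order_preserved(self):
        adj = bonferroni([0.01, 0.001, 0.5], 3)
        assert list(adj) == pytest.approx([0.03, 0.003, 1.0])

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestFisherCombine:
    def test_single_p_is_identity(self):
        x, p = fisher_combine([0.3])
        assert x == pytest.approx(-2 * math.log(0.3), abs=1e-3)
        assert x == pytest.approx(2.408, abs=1e-3)
        assert p == pytest.approx(0.3, abs=1e-12)

    def test_all_ones(self):
        x, p = fisher_combine([1.0] * 5)
        assert x == 0.0 and p == 1.0

    def test_200_halves_closed_form(self):
        x, p = fisher_combine([0.5] * 200)
        assert x == pytest.approx(277.2589, abs=1e-3)
        # closed-form chi-square upper tail for even df:
        # P(X > x) = exp(-x/2) * sum_{k<df/2} (x/2)^k / k!
        half = x / 2.0
        term, total = 1.0, 1.0
        for k in range(1, 200):
            term *= half / k
            total += term
        expected = math.exp(-half) * total
        assert p == pytest.approx(expected, rel=1e-9)
        assert p > 0.99

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10),
           st.integers(0, 9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_each_p(self, ps, idx):
        idx %= len(ps)
        x0, _ = fisher_combine(ps)
        smaller = list(ps)
        smaller[idx] = smaller[idx] / 2
        x1, _ = fisher_combine(smaller)
        assert x1 > x0

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r, t, p, n = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12 and n == 10

    def test_antisymmetry(self):
        x = np.arange(10.0)
        r, *_ = pearson_test(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed(self):
        r, t, p, n = pearson_test([1, 2, 3, 4], [1, 2, 4, 3])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert t == pytest.approx(1.8856, abs=1e-3)
        assert n == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_covariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, t, p, _ = pearson_test(x, y)
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        r_oracle = sxy / math.sqrt(sxx * syy)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        t_oracle = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        assert t == pytest.approx(t_oracle, abs=1e-9)

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        r, _, _, n = pearson_test(x, y)
        assert n == 3 and r == 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_test([1, 1, 1, 1], [1, 2, 3, 4])


class TestWilcoxon:
    def test_identical_samples(self):
        assert wilcoxon_updown([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_disjoint_ranges_exact_minimum(self):
        up = list(range(10))
        down = list(range(100, 110))
        p = wilcoxon_updown(up, down)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(1.08e-5, rel=0.01)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_small_n(self, seed):
        """Exact agreement with a brute-force permutation oracle (n <= 8),
        including tie-heavy samples."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5), rng.integers(2, 5)
        pool = rng.integers(0, 4, size=n1 + n2).astype(float)  # many ties
        up, down = pool[:n1], pool[n2:] if False else pool[n1:]
        if np.ptp(pool) == 0:
            pool[0] += 1
            up, down = pool[:n1], pool[n1:]
        p = wilcoxon_updown(up, down)
        # oracle: count pairs (x > y) + half ties over all relabelings
        def u_stat(a, b):
            return sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        obs = abs(u_stat(up, down) - n1 * n2 / 2)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), int(n1)):
            grp = pool[list(idx)]
            rest = np.delete(pool, list(idx))
            total += 1
            if abs(u_stat(grp, rest) - n1 * n2 / 2) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_updown([], [1.0])

    def test_large_sample_asymptotic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        b = rng.normal(loc=2.0, size=50)
        assert wilcoxon_updown(a, b) < 1e-6


class TestDagostino:
    def test_symmetric_sample(self):
        values = [-2, -1, 1, 2, -3, 3, -4, 4]
        skew, z, p = dagostino_skewness(values)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_right_skew_detected(self):
        rng = np.random.default_rng(2)
        skew, z, p = dagostino_skewness(rng.exponential(size=5000))
        assert skew > 0 and p < 0.001

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            dagostino_skewness([1, 2, 3, 4, 5, 6, 7])


class TestNeutralBinTest:
    def test_uniform_rows_analytic_t_zero(self):
        counts = np.full((5, 200), 2.0)  # every row exactly uniform
        res = neutral_bin_test(make_matrix(counts), null="analytic")
        assert not res.significant.any()
        assert np.isnan(res.t).all()  # zero variance in every bin -> flagged

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(21)
        fold = np.ones(200)
        fold[GRID.column_of(1):GRID.column_of(4) + 1] = 1.7
        counts = simulate_bin_counts(4000, 20.0, rng, fold=fold)
        res = neutral_bin_test(make_matrix(counts), seed=77)
        sig = set(res.significant_bins())
        assert {1, 2, 3, 4} <= sig
        assert sig <= {-1, 1, 2, 3, 4, 5}  # only contiguous neighbors beyond

    def test_needs_two_rows(self):
        counts = np.zeros((2, 200))
        counts[0, 0] = 1
        with pytest.raises(ValueError):
            neutral_bin_test(make_matrix(counts))

    def test_simulated_null_deterministic(self):
        rng = np.random.default_rng(5)
        counts = simulate_bin_counts(300, 10.0, rng)
        a = neutral_bin_test(make_matrix(counts), seed=3)
        b = neutral_bin_test(make_matrix(counts), seed=3)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)


class TestBvfDelta:
    def test_identical_placements_no_signal(self):
        counts = np.zeros((4, 200))
        counts[:, 10] = 3
        prof, res = bvf_delta_test(make_matrix(counts, "rare"),
                                   make_matrix(counts, "common"))
        assert np.all(prof.mean == 0)
        assert not res.significant.any()

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(6)
        a = make_matrix(rng.poisson(0.1, (40, 200)), "rare")
        b = make_matrix(rng.poisson(0.1, (40, 200)), "common")
        prof_ab, res_ab = bvf_delta_test(a, b)
        prof_ba, res_ba = bvf_delta_test(b, a)
        np.testing.assert_array_equal(prof_ab.mean, -prof_ba.mean)
        np.testing.assert_array_equal(res_ab.p_raw, res_ba.p_raw)

    def test_rare_only_enrichment_gives_positive_delta(self):
        rng = np.random.default_rng(30)
        fold = np.ones(200)
        cols = slice(GRID.column_of(1), GRID.column_of(4) + 1)
        fold[cols] = 1.7
        rare = make_matrix(simulate_bin_counts(6000, 20.0, rng, fold=fold), "rare")
        common = make_matrix(simulate_bin_counts(6000, 31.0, rng), "common")
        prof, res = bvf_delta_test(rare, common)
        sig = res.significant_bins()
        assert prof.mean[cols].min() > 0
        assert {1, 2, 3, 4} <= set(sig)

    def test_requires_shared_tss(self):
        a = make_matrix(np.ones((3, 200)))
        b = BinMatrix(["x", "y", "z"], np.ones((3, 200)), "BVF")
        with pytest.raises(ValueError):
            bvf_delta_test(a, b)


class TestProfileTtestPair:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(30, 200))
        df = profile_ttest_pair(mat, mat.copy())
        assert not df["significant"].any()
        assert df["p_raw"].min() > 0.99  # same samples -> t = 0

    def test_shift_detected_everywhere(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(100, 200))
        df = profile_ttest_pair(a, a + 1.0)
        assert df["significant"].all()

    def test_missing_bins_propagate(self):
        a = np.full((5, 200), np.nan)
        a[:, 0] = 1.0 + np.arange(5)
        b = a.copy() + 0.1
        df = profile_ttest_pair(a, b)
        assert np.isnan(df["p_raw"][1:]).all()
        assert np.isfinite(df["p_raw"][0])


class TestAnova:
    def _scores(self, arrays):
        # one populated bin, the rest empty
        per_bin = {c: [np.array([])] * 200 for c in arrays}
        for c, arr in arrays.items():
            per_bin[c][0] = np.asarray(arr, dtype=float)
        return per_bin

    def test_matches_direct_formula(self):
        groups = {
            "rare": [1.0, 2.0, 3.0],
            "mid1": [2.0, 4.0],
            "mid2": [5.0, 6.0, 7.0, 8.0],
            "common": [1.0, 1.5],
        }
        df = bcs_class_anova(self._scores(groups))
        data = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
        df_b = len(data) - 1
        df_w = sum(len(g) for g in data) - len(data)
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        assert df["F"][0] == pytest.approx(f_oracle, rel=1e-12)

    def test_identical_constant_scores_f_zero(self):
        groups = {c: [2.0, 2.0] for c in ("rare", "mid1", "mid2", "common")}
        df = bcs_class_anova(self._scores(groups))
        assert df["F"][0] == 0.0 and df["p_raw"][0] == 1.0

    def test_null_calibration_after_bonferroni(self):
        rng = np.random.default_rng(9)
        per_bin = {c: [rng.normal(size=30) for _ in range(200)]
                   for c in ("rare", "mid1", "mid2", "common")}
        df = bcs_class_anova(per_bin)
        assert int(df["significant"].sum()) == 0

    def test_shifted_class_detected(self):
        rng = np.random.default_rng(10)
        per_bin = {c: [rng.normal(size=50)] for c in ("rare", "mid1", "mid2")}
        per_bin["common"] = [rng.normal(loc=2.0, size=50)]  # 2 within-class SDs
        df = bcs_class_anova({c: v + [np.array([])] * 199
                              for c, v in per_bin.items()})
        assert df["p_adjusted"][0] < 0.001

    def test_underpopulated_bin_missing(self):
        per_bin = {c: [np.array([1.0])] * 200 for c in ("rare", "common")}
        df = bcs_class_anova(per_bin)
        assert np.isnan(df["p_raw"]).all()


class TestWindowSplit:
    def test_constant_delta_errors(self):
        bbs = make_profile(np.random.default_rng(0).normal(size=200))
        bgs = make_profile(np.random.default_rng(1).normal(size=200))
        delta = make_profile(np.zeros(200))
        with pytest.raises(ValueError):
            window_split(bbs, bgs, delta)

    def test_trace_covers_candidates(self):
        rng = np.random.default_rng(12)
        res = window_split(make_profile(rng.normal(size=200)),
                           make_profile(rng.normal(size=200)),
                           make_profile(rng.normal(size=200)))
        assert list(res.trace["i"]) == list(range(2, 99))
        assert 2 <= res.boundary <= 98
        inner, outer = set(res.inner_bins), set(res.outer_bins)
        assert inner | outer == set(GRID.indices) and not inner & outer

    def test_outer_only_coupling_flagged_weak(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=200)
        delta = make_profile(v + 0.05 * rng.normal(size=200))
        bgs = make_profile(v + 0.05 * rng.normal(size=200))  # coupled everywhere
        bbs = make_profile(rng.normal(size=200))             # uncoupled
        res = window_split(bbs, bgs, delta)
        assert res.weak_inner and abs(res.r_inner) < 0.2
        assert abs(res.r_outer) > 0.9
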