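"""Statistical tests on bin profiles.

The positional tests treat each TSS as one observation: the per-TSS normalized
bin frequencies ``f(i,j)`` are compared bin-by-bin against the uniform null
mean ``1/n_bins`` with one-sample t-tests, and the rare-minus-common paired
differences against 0.  All 200 per-bin p-values of a family are Bonferroni
corrected; the study-wide significance level defaults to 0.001.

Whole-signal contrasts (e.g. nucleosome occupancy of CGI- vs nCGI-TSSs) are
assembled from per-bin two-sample t-tests whose p-values are pooled with
Fisher's method (-2 * sum(log p) ~ chi-square with 2k df).  The per-bin tests
are not strictly independent across bins, so the combined p-value is an
approximation; results carry a note to that effect.

The inner/outer region-splitting procedure scans symmetric windows ``[-i, +i]``
(i = 2..98), correlating the gBGC base fraction with the rare-common BVF
difference inside and the conservation score with the same difference outside,
and picks the half-width maximizing the absolute product of the two
correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinGrid, BinMatrix, BinProfile

__all__ = [
    "BinTestResult",
    "RegionSplitResult",
    "neutral_bin_test",
    "bvf_delta_test",
    "fisher_combine",
    "pearson_test",
    "window_split",
    "bcs_class_anova",
    "profile_ttest_pair",
    "wilcoxon_updown",
    "dagostino_skewness",
    "bonferroni",
    "DEFAULT_ALPHA",
    "WEAK_INNER_THRESHOLD",
]

DEFAULT_ALPHA = 0.001
WEAK_INNER_THRESHOLD = 0.2
P_FLOOR = 1e-300  # below this, TSV output reports "< 1e-300"


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, p * m)``; NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    finite = p[np.isfinite(p)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = int(np.isfinite(p).sum())
    if m < np.isfinite(p).sum():
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)


@dataclass
class BinTestResult:
    """Per-bin test summary against a common null mean."""

    bins: np.ndarray
    observed_mean: np.ndarray
    null_mean: float
    t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    alpha: float
    n: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                np.isfinite(self.p_adjusted), self.p_adjusted < self.alpha, False
            )

    def significant_bins(self) -> np.ndarray:
        return self.bins[self.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins,
                "observed_mean": self.observed_mean,
                "null_mean": self.null_mean,
                "t": self.t,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            }
        )


def _per_bin_onesample(values: np.ndarray, popmean: float, alpha: float,
                       bins: np.ndarray) -> BinTestResult:
    """Column-wise one-sample t-test of ``values`` (rows = TSSs) against popmean."""
    n_rows, n_bins = values.shape
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean - popmean) / (sd / np.sqrt(n_rows))
        p = 2 * stats.t.sf(np.abs(t), df=n_rows - 1)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, np.nan, p)
    return BinTestResult(
        bins=bins,
        observed_mean=mean,
        null_mean=popmean,
        t=t,
        p_raw=p,
        p_adjusted=bonferroni(p, n_bins),
        alpha=alpha,
        n=np.full(n_bins, n_rows, dtype=float),
    )


def neutral_bin_test(
    matrix: BinMatrix,
    alpha: float = DEFAULT_ALPHA,
    null: str = "simulated",
    n_null: int = 2,
    seed: int = 0,
) -> BinTestResult:
    """Test each bin's normalized variant frequency against the uniform null.

    Under uniform placement of a TSS's variants among its bins the expected
    per-TSS normalized frequency is ``1/n_bins`` in every bin.  With
    ``null="simulated"`` (default) each TSS's window total is redistributed
    uniformly over the bins ``n_null`` times and the test is a paired two-sided
    t-test of the observed-minus-simulated per-TSS frequencies against 0; the
    simulated arm carries the same zero-inflated sampling noise as the data,
    which keeps the extreme Bonferroni tail calibrated for sparse windows.
    With ``null="analytic"`` the test is a one-sample t-test of the observed
    frequencies directly against the constant ``1/n_bins``; that variant is
    slightly anti-conservative toward depletion when windows hold few
    variants.  All 200 p-values are Bonferroni corrected; bins with zero
    variance get a missing p-value.
    """
    f, _ = matrix.fractions()
    if f.shape[0] < 2:
        raise ValueError("need at least 2 TSSs with variants")
    null_mean = 1.0 / matrix.grid.n_bins
    if null == "analytic":
        return _per_bin_onesample(f, null_mean, alpha, matrix.grid.indices)
    if null != "simulated":
        raise ValueError(f"unknown null model {null!r}")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    totals = matrix.row_totals()
    v = totals[totals > 0].astype(np.int64)
    pvals = np.full(matrix.grid.n_bins, null_mean)
    f0 = np.zeros_like(f)
    for _ in range(n_null):
        f0 += rng.multinomial(v, pvals) / v[:, None]
    d = f - f0 / n_null
    result = _per_bin_onesample(d, 0.0, alpha, matrix.grid.indices)
    result.observed_mean = f.mean(axis=0)
    result.null_mean = null_mean
    return result


def bvf_delta_test(
    matrix_rare: BinMatrix,
    matrix_common: BinMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[BinProfile, BinTestResult]:
    """Paired per-bin test of rare-minus-common normalized frequencies against 0.

    For each TSS carrying variants of both classes, ``delta(i,j) =
    f_rare(i,j) - f_common(i,j)``; positive values mark bins where rare
    (younger) variants are relatively more frequent than common (older) ones.
    """
    if matrix_rare.tss_ids != matrix_common.tss_ids:
        raise ValueError("matrices must be over the same TSS list")
    tot_r = matrix_rare.row_totals()
    tot_c = matrix_common.row_totals()
    both = (tot_r > 0) & (tot_c > 0)
    if both.sum() < 2:
        raise ValueError("fewer than 2 TSSs carry both variant classes")
    f_r = matrix_rare.counts[both] / tot_r[both, None]
    f_c = matrix_common.counts[both] / tot_c[both, None]
    delta = f_r - f_c
    result = _per_bin_onesample(delta, 0.0, alpha, matrix_rare.grid.indices)
    n = delta.shape[0]
    profile = BinProfile(
        bins=matrix_rare.grid.indices,
        mean=delta.mean(axis=0),
        se=delta.std(axis=0, ddof=1) / np.sqrt(n),
        n=np.full(matrix_rare.grid.n_bins, float(n)),
        signal="BVF_delta",
        label=f"{matrix_rare.label or 'rare'}-{matrix_common.label or 'common'}",
        p_raw=result.p_raw,
        p_adjusted=result.p_adjusted,
        significant=result.significant.astype(float),
        grid=matrix_rare.grid,
    )
    return profile, result


def fisher_combine(pvals: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: ``X = -2 * sum(log p)`` against chi-square with 2k df."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = float(-2.0 * np.log(p).sum()) + 0.0  # avoid -0.0 when every p is 1
    return x, float(stats.chi2.sf(x, df=2 * p.size))


def pearson_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, int]:
    """Pearson correlation with its t statistic ``r*sqrt(n-2)/sqrt(1-r^2)``.

    Pairs with a missing value in either vector are dropped.  Returns
    ``(r, t, p, n)`` with a two-sided p from Student's t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, math.inf if r > 0 else -math.inf, 0.0, n
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(t), float(p), n


@dataclass
class RegionSplitResult:
    """Outcome of the inner/outer window-splitting scan."""

    boundary: int  # half-width j* in bins
    r_inner: float
    r_outer: float
    p_inner: float
    p_outer: float
    trace: pd.DataFrame  # columns: i, r_in, r_out, abs_product
    weak_inner: bool
    grid: BinGrid = field(default_factory=BinGrid)

    @property
    def inner_bins(self) -> np.ndarray:
        j = self.grid.indices
        return j[np.abs(j) <= self.boundary]

    @property
    def outer_bins(self) -> np.ndarray:
        j = self.grid.indices
        return j[np.abs(j) > self.boundary]

    @property
    def boundary_bp(self) -> int:
        return self.boundary * self.grid.bin_width


def window_split(
    bbs_profile: BinProfile,
    bgs_profile: BinProfile,
    delta_profile: BinProfile,
) -> RegionSplitResult:
    """Split the window into an inner region dominated by gBGC and an outer one
    dominated by conservation.

    For each candidate half-width ``i`` in 2..98, the gBGC fraction is
    correlated with the rare-common difference over bins ``|j| <= i`` and the
    conservation score with the same difference over ``|j| > i``; the chosen
    boundary maximizes ``|r_in * r_out|`` (smallest i on ties).  The result is
    flagged ``weak_inner`` when ``|r_in|`` at the optimum is below 0.2.
    """
    grid = delta_profile.grid
    j = grid.indices
    bbs, bgs, delta = (
        np.asarray(p.mean, dtype=float)
        for p in (bbs_profile, bgs_profile, delta_profile)
    )
    if not (len(bbs) == len(bgs) == len(delta) == grid.n_bins):
        raise ValueError("profiles must share the bin grid")
    half = grid.n_bins // 2
    rows = []
    for i in range(2, half - 1):
        inner = np.abs(j) <= i
        r_in = r_out = np.nan
        try:
            r_in, _, p_in, _ = pearson_test(bbs[inner], delta[inner])
        except ValueError:
            p_in = np.nan
        try:
            r_out, _, p_out, _ = pearson_test(bgs[~inner], delta[~inner])
        except ValueError:
            p_out = np.nan
        prod = abs(r_in * r_out) if np.isfinite(r_in) and np.isfinite(r_out) else np.nan
        rows.append((i, r_in, r_out, p_in, p_out, prod))
    trace = pd.DataFrame(
        rows, columns=["i", "r_in", "r_out", "p_in", "p_out", "abs_product"]
    )
    if not np.isfinite(trace["abs_product"]).any():
        raise ValueError("correlation undefined at every candidate split")
    best = int(trace.loc[trace["abs_product"].idxmax(), "i"])  # idxmax -> first max
    row = trace[trace["i"] == best].iloc[0]
    return RegionSplitResult(
        boundary=best,
        r_inner=float(row["r_in"]),
        r_outer=float(row["r_out"]),
        p_inner=float(row["p_in"]),
        p_outer=float(row["p_out"]),
        trace=trace,
        weak_inner=bool(abs(row["r_in"]) < WEAK_INNER_THRESHOLD),
        grid=grid,
    )


def bcs_class_anova(
    scores_by_class: dict[str, list[np.ndarray]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-bin one-way ANOVA of per-variant deleteriousness across classes.

    ``scores_by_class`` maps each class label to its 200 per-bin score arrays
    (from :func:`tssvar.binning.bin_variant_scores`).  A bin needs at least two
    classes with >= 2 scored variants; otherwise its p-value is missing.
    Returns a frame with F, raw and Bonferroni-adjusted p per bin.
    """
    labels = list(scores_by_class)
    if not labels:
        raise ValueError("no classes supplied")
    n_bins = len(scores_by_class[labels[0]])
    f_stat = np.full(n_bins, np.nan)
    p_raw = np.full(n_bins, np.nan)
    for b in range(n_bins):
        groups = [scores_by_class[c][b] for c in labels]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat[b], p_raw[b] = 0.0, 1.0
            continue
        res = stats.f_oneway(*groups)
        f_stat[b], p_raw[b] = res.statistic, res.pvalue
    adj = bonferroni(p_raw, n_bins)
    return pd.DataFrame(
        {
            "F": f_stat,
            "p_raw": p_raw,
            "p_adjusted": adj,
            "significant": np.where(np.isfinite(adj), adj < alpha, False),
        }
    )


def profile_ttest_pair(
    values_a: np.ndarray | list[np.ndarray],
    values_b: np.ndarray | list[np.ndarray],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-bin two-sided two-sample t-tests between two groups.

    Inputs are either per-TSS bin-value matrices (rows = TSSs, possibly with
    NaNs for unscored cells) or lists of per-bin sample arrays.  Returns a
    frame of t, raw p, Bonferroni-adjusted p and the two group sizes; bins
    with fewer than 2 observations on either side are missing.
    """
    cols_a = _per_bin_samples(values_a)
    cols_b = _per_bin_samples(values_b)
    if len(cols_a) != len(cols_b):
        raise ValueError("both groups must cover the same bins")
    n_bins = len(cols_a)
    t = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    n_a = np.zeros(n_bins)
    n_b = np.zeros(n_bins)
    for k in range(n_bins):
        a, b = cols_a[k], cols_b[k]
        n_a[k], n_b[k] = a.size, b.size
        if a.size < 2 or b.size < 2:
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            t[k], p[k] = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
            continue
        res = stats.ttest_ind(a, b)
        t[k], p[k] = res.statistic, res.pvalue
    adj = bonferroni(p, n_bins)
    return pd.DataFrame(
        {
            "t": t,
            "p_raw": p,
            "p_adjusted": adj,
            "n_a": n_a,
            "n_b": n_b,
            "significant": np.where(np.isfinite(adj), adj < alpha, False),
        }
    )


def _per_bin_samples(values) -> list[np.ndarray]:
    if isinstance(values, np.ndarray):
        return [col[np.isfinite(col)] for col in values.T]
    return [np.asarray(v, dtype=float) for v in values]


def signal_contrast(
    values_a, values_b, alpha: float = DEFAULT_ALPHA
) -> tuple[pd.DataFrame, float, float]:
    """Whole-signal contrast: per-bin t-tests pooled with Fisher's method.

    Returns the per-bin frame plus ``(X, combined_p)``.  The per-bin tests are
    treated as independent, which neighboring bins only approximate.
    """
    per_bin = profile_ttest_pair(values_a, values_b, alpha=alpha)
    usable = per_bin["p_raw"].dropna()
    x, p = fisher_combine(np.clip(usable.to_numpy(), P_FLOOR, 1.0))
    return per_bin, x, p


def wilcoxon_updown(
    values_up: Sequence[float], values_down: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two regions.

    Small samples (combined n <= 20) use the exact null distribution — by
    complete enumeration of group assignments when ties are present — and
    larger samples the normal approximation with tie correction.
    """
    up = np.asarray(values_up, dtype=float)
    down = np.asarray(values_down, dtype=float)
    if up.size == 0 or down.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([up, down])
    if np.ptp(pooled) == 0:
        return 1.0  # every rank tied; no evidence either way
    has_ties = np.unique(pooled).size < pooled.size
    if up.size + down.size <= 20:
        if not has_ties:
            res = stats.mannwhitneyu(up, down, alternative="two-sided",
                                     method="exact")
            return float(min(1.0, res.pvalue))
        return _exact_ranksum_enumeration(up, down)
    res = stats.mannwhitneyu(
        up, down, alternative="two-sided", method="asymptotic",
        use_continuity=False,
    )
    return float(min(1.0, res.pvalue))


def _exact_ranksum_enumeration(up: np.ndarray, down: np.ndarray) -> float:
    """Exact two-sided rank-sum p via enumeration of all group assignments.

    Uses the midrank-sum statistic; the p-value is the probability, over every
    way to relabel the pooled values, of a rank sum at least as far from its
    expectation as the observed one.  Handles ties exactly; feasible for
    combined n up to ~20.
    """
    from itertools import combinations

    pooled = np.concatenate([up, down])
    ranks = stats.rankdata(pooled)  # midranks
    n1, n_tot = up.size, pooled.size
    expected = n1 * (n_tot + 1) / 2.0
    observed = abs(ranks[:n1].sum() - expected)
    count = total = 0
    for idx in combinations(range(n_tot), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - expected) >= observed - 1e-12:
            count += 1
    return count / total


def dagostino_skewness(values: Sequence[float]) -> tuple[float, float, float]:
    """D'Agostino's skewness test: sample skewness, its normal z, two-sided p.

    Applies the 1970 transformation of the sample skewness coefficient to an
    approximately standard-normal deviate; an exactly symmetric sample maps to
    z = 0 and p = 1.  Requires n >= 8 for the transformation to be valid.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 8:
        raise ValueError("D'Agostino skewness transformation requires n >= 8")
    b1 = float(stats.skew(v))
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    z = delta * math.asinh(y / alpha)
    p = 2.0 * stats.norm.sf(abs(z))
    return b1, float(z), float(p)
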