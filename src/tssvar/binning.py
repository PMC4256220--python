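"""The 200 x 50 bp strand-aware bin grid around each TSS, and signal aggregation.

The 10 kb window flanking a TSS is divided into 200 bins of 50 bp indexed
``j in {-100..-1, +1..+100}`` (no bin 0).  Offsets are measured in the direction
of transcription: for a plus-strand TSS the offset of a base at position ``p``
is ``d = p - tss``, for a minus-strand TSS ``d = tss - p``, so positive ``j``
is always downstream (transcribed side).  Bin ``j > 0`` covers
``d in [(j-1)*50, j*50)`` and bin ``j < 0`` covers ``d in [j*50, (j+1)*50)``;
a variant exactly at the TSS (``d = 0``) therefore falls in bin ``+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .track_io import ScoreTrack, TssRecord, VariantRecord

__all__ = [
    "BinGrid",
    "BinMatrix",
    "BinProfile",
    "bin_index",
    "bin_offsets",
    "bin_variants",
    "bin_variants_by_class",
    "bvf_profile",
    "track_bin_matrix",
    "track_profile",
    "bin_variant_scores",
    "cadd_profile",
]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bin grid: 200 bins of 50 bp, indices -100..-1, +1..+100."""

    n_bins: int = 200
    bin_width: int = 50

    def __post_init__(self) -> None:
        if self.n_bins % 2 != 0 or self.n_bins <= 0:
            raise ValueError("n_bins must be a positive even number")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def half_span(self) -> int:
        """Bases covered on each side of the TSS."""
        return self.n_bins // 2 * self.bin_width

    @property
    def span(self) -> int:
        return self.n_bins * self.bin_width

    @property
    def indices(self) -> np.ndarray:
        """Bin indices in column order: -100..-1 then +1..+100."""
        half = self.n_bins // 2
        return np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])

    def column_of(self, j: int) -> int:
        """Matrix column of bin ``j``."""
        half = self.n_bins // 2
        if not (-half <= j <= half) or j == 0:
            raise ValueError(f"bin index {j} outside the grid")
        return j + half if j < 0 else j + half - 1

    def index_of_offset(self, d: np.ndarray) -> np.ndarray:
        """Vectorized offset -> bin index; 0 marks offsets outside the window."""
        d = np.asarray(d)
        j0 = np.floor_divide(d, self.bin_width)
        j = np.where(d >= 0, j0 + 1, j0)
        half = self.n_bins // 2
        return np.where((d >= -self.half_span) & (d < self.half_span), j, 0).astype(
            int
        )


DEFAULT_GRID = BinGrid()


def bin_offsets(grid: BinGrid = DEFAULT_GRID) -> np.ndarray:
    """Transcription-direction offset of each bin's TSS-proximal edge, column order."""
    j = grid.indices
    return np.where(j > 0, (j - 1) * grid.bin_width, j * grid.bin_width)


def bin_index(tss: TssRecord, chrom: str, position: int, grid: BinGrid = DEFAULT_GRID):
    """Bin index of a genomic position relative to a TSS, or ``None``.

    Returns ``None`` when the position is on another chromosome or outside the
    window (upstream offset < -half_span or downstream offset >= half_span).
    """
    if chrom != tss.chrom:
        return None
    d = position - tss.position if tss.strand == "+" else tss.position - position
    if d < -grid.half_span or d >= grid.half_span:
        return None
    j = d // grid.bin_width
    return int(j + 1) if d >= 0 else int(j)


@dataclass
class BinMatrix:
    """Per-TSS x per-bin aggregate: counts, and score sums for score signals.

    Rows align with ``tss_ids``; columns follow ``grid.indices``.  For count
    signals (variant counts, membership bases) ``sums`` is ``None``.
    """

    tss_ids: list[str]
    counts: np.ndarray
    signal: str
    sums: np.ndarray | None = None
    grid: BinGrid = field(default_factory=BinGrid)
    label: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.tss_ids), self.grid.n_bins):
            raise ValueError("counts shape does not match TSS list and grid")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.sums is not None:
            self.sums = np.asarray(self.sums, dtype=float)
            if self.sums.shape != self.counts.shape:
                raise ValueError("sums shape must match counts")

    @property
    def n_tss(self) -> int:
        return len(self.tss_ids)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def fractions(self) -> tuple[np.ndarray, list[str]]:
        """Per-TSS normalized bin frequencies ``f(i,j) = vars(i,j) / V(i)``.

        Rows with zero total are excluded (they carry no positional
        information); returns the fraction matrix and the retained TSS ids.
        """
        totals = self.row_totals()
        keep = totals > 0
        if not keep.any():
            raise ValueError("every TSS row is empty; cannot normalize")
        f = self.counts[keep] / totals[keep, None]
        ids = [tid for tid, k in zip(self.tss_ids, keep) if k]
        return f, ids

    def per_tss_means(self) -> np.ndarray:
        """Per-cell mean score ``sums/counts``; NaN where a cell has no elements."""
        if self.sums is None:
            raise ValueError("matrix has no score sums")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.sums / self.counts, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.tss_ids, columns=self.grid.indices)


@dataclass
class BinProfile:
    """A 200-length per-bin summary of one signal (mean, SE, CI, p-values)."""

    bins: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray
    signal: str
    label: str | None = None
    p_raw: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None
    significant: np.ndarray | None = None
    grid: BinGrid = field(default_factory=BinGrid)

    def __post_init__(self) -> None:
        for name in ("bins", "mean", "se", "n"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not (len(self.bins) == len(self.mean) == len(self.se) == len(self.n)):
            raise ValueError("profile arrays must have equal length")

    @property
    def ci_low(self) -> np.ndarray:
        return self.mean - 2 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.mean + 2 * self.se

    def iter_rows(self) -> Iterator[dict]:
        offsets = bin_offsets(self.grid)
        for k in range(len(self.bins)):
            yield {
                "bin": int(self.bins[k]),
                "offset_bp": int(offsets[k]),
                "mean": _opt(self.mean, k),
                "se": _opt(self.se, k),
                "ci_low": _opt(self.ci_low, k),
                "ci_high": _opt(self.ci_high, k),
                "n": _opt(self.n, k),
                "p_raw": _opt(self.p_raw, k),
                "p_adjusted": _opt(self.p_adjusted, k),
                "significant": _opt(self.significant, k),
            }


def _opt(arr, k):
    if arr is None:
        return None
    v = arr[k]
    return None if isinstance(v, float) and np.isnan(v) else v


def _positions_by_chrom(
    variants: Sequence[VariantRecord],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chrom -> (sorted positions, original indices)."""
    by: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if not variants:
        return by
    chroms = np.array([v.chrom for v in variants])
    pos = np.array([v.position for v in variants], dtype=np.int64)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        idx = np.nonzero(mask)[0]
        order = np.argsort(pos[mask], kind="stable")
        by[str(chrom)] = (pos[mask][order], idx[order])
    return by


def bin_variants(
    tss_list: Sequence[TssRecord],
    variants: Sequence[VariantRecord],
    grid: BinGrid = DEFAULT_GRID,
    label: str | None = None,
) -> BinMatrix:
    """Count variants per TSS per bin.

    A variant inside the windows of two TSSs is counted once per TSS (rows are
    independent profiles of their own window).
    """
    counts = np.zeros((len(tss_list), grid.n_bins), dtype=float)
    by_chrom = _positions_by_chrom(variants)
    half = grid.n_bins // 2
    for i, tss in enumerate(tss_list):
        entry = by_chrom.get(tss.chrom)
        if entry is None:
            continue
        pos, _ = entry
        lo = np.searchsorted(pos, tss.position - grid.half_span, side="left")
        hi = np.searchsorted(pos, tss.position + grid.half_span, side="right")
        window = pos[lo:hi]
        if window.size == 0:
            continue
        d = window - tss.position if tss.strand == "+" else tss.position - window
        j = grid.index_of_offset(d)
        j = j[j != 0]
        cols = np.where(j < 0, j + half, j + half - 1)
        np.add.at(counts[i], cols, 1.0)
    ids = [t.id for t in tss_list]
    return BinMatrix(tss_ids=ids, counts=counts, signal="BVF", grid=grid, label=label)


def bin_variants_by_class(
    tss_list: Sequence[TssRecord],
    variants: Sequence[VariantRecord],
    class_labels: Sequence[str],
    grid: BinGrid = DEFAULT_GRID,
) -> dict[str, BinMatrix]:
    """One count matrix per frequency class."""
    if len(class_labels) != len(variants):
        raise ValueError("one class label per variant is required")
    out: dict[str, BinMatrix] = {}
    labels = np.asarray(class_labels)
    for label in dict.fromkeys(class_labels):  # preserve first-seen order
        subset = [v for v, keep in zip(variants, labels == label) if keep]
        out[label] = bin_variants(tss_list, subset, grid=grid, label=label)
    return out


def bvf_profile(matrix: BinMatrix) -> BinProfile:
    """Normalized mean variant frequency per bin.

    Each TSS's counts are first normalized by its window total, then averaged
    across TSSs, so the profile sums to 1 over bins and its neutral expectation
    is ``1/n_bins`` in every bin.
    """
    f, _ = matrix.fractions()
    n = f.shape[0]
    mean = f.mean(axis=0)
    se = f.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(f.shape[1], np.nan)
    return BinProfile(
        bins=matrix.grid.indices,
        mean=mean,
        se=se,
        n=np.full(matrix.grid.n_bins, n),
        signal=matrix.signal,
        label=matrix.label,
        grid=matrix.grid,
    )


def _window_matrix(
    tss: TssRecord, track: ScoreTrack, grid: BinGrid
) -> np.ndarray:
    """Per-base track values over the TSS window, oriented by transcription.

    Row ``k`` of the flattened array corresponds to offset ``d = k - half_span``;
    reshaped to (n_bins, bin_width) the rows follow the grid's column order.
    """
    h = grid.half_span
    if tss.strand == "+":
        vals = track.window_values(tss.chrom, tss.position - h, tss.position + h)
    else:
        vals = track.window_values(tss.chrom, tss.position - h + 1, tss.position + h + 1)
        vals = vals[::-1]
    return vals.reshape(grid.n_bins, grid.bin_width)


def track_bin_matrix(
    tss_list: Sequence[TssRecord],
    track: ScoreTrack,
    grid: BinGrid = DEFAULT_GRID,
    signal: str = "track",
    label: str | None = None,
) -> BinMatrix:
    """Aggregate a per-base track into per-TSS per-bin score sums and base counts."""
    n = len(tss_list)
    sums = np.zeros((n, grid.n_bins))
    counts = np.zeros((n, grid.n_bins))
    for i, tss in enumerate(tss_list):
        w = _window_matrix(tss, track, grid)
        scored = np.isfinite(w)
        counts[i] = scored.sum(axis=1)
        sums[i] = np.where(scored, w, 0.0).sum(axis=1)
    return BinMatrix(
        tss_ids=[t.id for t in tss_list],
        counts=counts,
        sums=sums,
        signal=signal,
        grid=grid,
        label=label,
    )


def track_profile(
    tss_list: Sequence[TssRecord],
    track: ScoreTrack,
    grid: BinGrid = DEFAULT_GRID,
    mode: str = "pooled_base_mean",
    signal: str = "track",
    label: str | None = None,
) -> BinProfile:
    """Per-bin summary of a score or membership track.

    mode
        ``pooled_base_mean``
            mean over all scored bases pooled across TSSs (nucleosome, GERP);
            SE is the pooled across-base standard error.
        ``per_tss_mean``
            mean over per-TSS bin means (the non-pooled alternative).
        ``per_tss_base_fraction``
            fraction of the bin's bases covered by the (membership) track,
            averaged over every TSS (gBGC base fraction in [0, 1]).
    """
    if mode not in ("pooled_base_mean", "per_tss_mean", "per_tss_base_fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(tss_list)
    if n == 0:
        raise ValueError("empty TSS list")
    if mode == "per_tss_base_fraction":
        frac = np.zeros((n, grid.n_bins))
        for i, tss in enumerate(tss_list):
            w = _window_matrix(tss, track, grid)
            frac[i] = np.isfinite(w).sum(axis=1) / grid.bin_width
        mean = frac.mean(axis=0)
        se = (
            frac.std(axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else np.full(grid.n_bins, np.nan)
        )
        return BinProfile(
            bins=grid.indices, mean=mean, se=se, n=np.full(grid.n_bins, n),
            signal=signal, label=label, grid=grid,
        )

    total = np.zeros(grid.n_bins)
    total_sq = np.zeros(grid.n_bins)
    count = np.zeros(grid.n_bins)
    per_tss: list[np.ndarray] = []
    for tss in tss_list:
        w = _window_matrix(tss, track, grid)
        scored = np.isfinite(w)
        c = scored.sum(axis=1)
        s = np.where(scored, w, 0.0)
        total += s.sum(axis=1)
        total_sq += (s**2).sum(axis=1)
        count += c
        if mode == "per_tss_mean":
            with np.errstate(invalid="ignore"):
                per_tss.append(np.where(c > 0, s.sum(axis=1) / c, np.nan))
    if mode == "per_tss_mean":
        mat = np.vstack(per_tss)
        finite = np.isfinite(mat)
        n_eff = finite.sum(axis=0)
        s1 = np.where(finite, mat, 0.0).sum(axis=0)
        s2 = np.where(finite, mat**2, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n_eff > 0, s1 / np.maximum(n_eff, 1), np.nan)
            var = (s2 - n_eff * mean**2) / np.maximum(n_eff - 1, 1)
            se = np.where(
                n_eff > 1,
                np.sqrt(np.maximum(var, 0.0) / np.maximum(n_eff, 1)),
                np.nan,
            )
        return BinProfile(
            bins=grid.indices, mean=mean, se=se, n=n_eff.astype(float),
            signal=signal, label=label, grid=grid,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        var = np.where(
            count > 1,
            (total_sq - count * mean**2) / np.maximum(count - 1, 1),
            np.nan,
        )
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(count, 1))
    se = np.where(count > 1, se, np.nan)
    return BinProfile(
        bins=grid.indices, mean=mean, se=se, n=count,
        signal=signal, label=label, grid=grid,
    )


def bin_variant_scores(
    tss_list: Sequence[TssRecord],
    variants: Sequence[VariantRecord],
    scores: Mapping[tuple[str, int], float] | pd.DataFrame,
    grid: BinGrid = DEFAULT_GRID,
) -> list[np.ndarray]:
    """Per-bin arrays of per-variant scores pooled across TSSs.

    ``scores`` maps ``(chrom, position)`` to a score, or is a DataFrame with
    ``chrom``/``pos``/``raw`` columns.  Variants without a score are skipped.
    """
    if isinstance(scores, pd.DataFrame):
        scores = {
            (c, int(p)): float(r)
            for c, p, r in zip(scores["chrom"], scores["pos"], scores["raw"])
        }
    per_bin: list[list[float]] = [[] for _ in range(grid.n_bins)]
    scored = [v for v in variants if (v.chrom, v.position) in scores]
    by_chrom = _positions_by_chrom(scored)
    half = grid.n_bins // 2
    for tss in tss_list:
        entry = by_chrom.get(tss.chrom)
        if entry is None:
            continue
        pos, orig = entry
        lo = np.searchsorted(pos, tss.position - grid.half_span, side="left")
        hi = np.searchsorted(pos, tss.position + grid.half_span, side="right")
        window = pos[lo:hi]
        if window.size == 0:
            continue
        d = window - tss.position if tss.strand == "+" else tss.position - window
        j = grid.index_of_offset(d)
        for jj, p in zip(j, window):
            if jj == 0:
                continue
            col = jj + half if jj < 0 else jj + half - 1
            per_bin[col].append(scores[(tss.chrom, int(p))])
    return [np.asarray(b, dtype=float) for b in per_bin]


def cadd_profile(
    tss_list: Sequence[TssRecord],
    variants: Sequence[VariantRecord],
    scores: Mapping[tuple[str, int], float] | pd.DataFrame,
    grid: BinGrid = DEFAULT_GRID,
    signal: str = "BCS",
    label: str | None = None,
) -> BinProfile:
    """Bin-average per-variant deleteriousness score (pooled across TSSs)."""
    per_bin = bin_variant_scores(tss_list, variants, scores, grid=grid)
    mean = np.array([b.mean() if b.size else np.nan for b in per_bin])
    se = np.array(
        [b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else np.nan for b in per_bin]
    )
    n = np.array([float(b.size) for b in per_bin])
    return BinProfile(
        bins=grid.indices, mean=mean, se=se, n=n,
        signal=signal, label=label, grid=grid,
    )
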