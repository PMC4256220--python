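"""Inclusion filters and classifications.

Variant inclusion mirrors the dbSNP/1000 Genomes selection: bi-allelic single
nucleotide variants submitted by the 1000 Genomes project, with two positive
allele counts summing to more than 1000 chromosomes.  Minor allele frequency
(MAF) is the smaller of the two allele frequencies.  Variants are stratified
into four MAF classes — rare, mid1, mid2, common — where the rare threshold
defaults to the lowest MAF observable in a 1092-diploid panel (one heterozygote:
``1/(2*1092) ~= 4.59e-4``), common is MAF > 0.01, and the intermediate variants
are split into two equal-size groups at their median MAF.

CpG islands are predicted by maximal-scoring-segment search over dinucleotides
(+17 for CG, -1 otherwise) with the usual GC >= 50%, length > 200 bp and
observed/expected CpG > 0.6 criteria.  TSSs are classified by CGI membership,
and TSSs whose 10 kb window hosts another TSS can be excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .track_io import GenomicInterval, TssRecord, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyClass",
    "ClassBoundaries",
    "ClassifiedTss",
    "FilterTally",
    "DEFAULT_RARE_THRESHOLD",
    "DEFAULT_COMMON_THRESHOLD",
    "rare_maf_threshold",
    "filter_variants",
    "compute_maf",
    "derive_class_boundaries",
    "assign_class",
    "predict_cgi",
    "classify_tss",
    "exclude_multi_tss",
    "density_contrast",
]

CLASS_LABELS = ("rare", "mid1", "mid2", "common")

DEFAULT_PANEL_SIZE = 1092  # diploid individuals in the reference panel
DEFAULT_COMMON_THRESHOLD = 0.01


def rare_maf_threshold(panel_size: int = DEFAULT_PANEL_SIZE, digits: int = 3) -> float:
    """Lowest possible MAF in a diploid panel, rounded to ``digits`` significant digits.

    One heterozygous carrier among ``panel_size`` individuals gives
    ``1/(2*panel_size)``; for the default 1092-individual panel that is
    4.5788e-4 (4.58e-4 at three significant digits).
    """
    if panel_size <= 0:
        raise ValueError("panel_size must be positive")
    raw = 1.0 / (2 * panel_size)
    exponent = math.floor(math.log10(raw))
    factor = 10.0 ** (digits - 1 - exponent)
    return round(raw * factor) / factor


# The operational rare/mid1 boundary: the lowest MAF observed in the reference
# release (one heterozygote among ~1092 individuals, reported as 4.59e-4; the
# idealized 1/(2*1092) = 4.5788e-4 lies just below it and still classifies rare).
DEFAULT_RARE_THRESHOLD = 4.59e-4


@dataclass(frozen=True)
class FrequencyClass:
    """One MAF class: label and its half-open-from-the-left range ``(lower, upper]``."""

    label: str
    lower: float
    upper: float

    def contains(self, maf: float) -> bool:
        return self.lower < maf <= self.upper


@dataclass(frozen=True)
class ClassBoundaries:
    """The four-class MAF partition of (0, 0.5].

    rare = (0, rare_threshold]; mid1 = (rare_threshold, mid_boundary];
    mid2 = (mid_boundary, common_threshold]; common = (common_threshold, 0.5].
    """

    rare_threshold: float
    mid_boundary: float
    common_threshold: float = DEFAULT_COMMON_THRESHOLD

    def __post_init__(self) -> None:
        if not (0 < self.rare_threshold <= self.mid_boundary <= self.common_threshold < 0.5):
            raise ValueError("boundaries must satisfy 0 < rare <= mid <= common < 0.5")

    @property
    def classes(self) -> tuple[FrequencyClass, ...]:
        return (
            FrequencyClass("rare", 0.0, self.rare_threshold),
            FrequencyClass("mid1", self.rare_threshold, self.mid_boundary),
            FrequencyClass("mid2", self.mid_boundary, self.common_threshold),
            FrequencyClass("common", self.common_threshold, 0.5),
        )


@dataclass(frozen=True)
class ClassifiedTss:
    """A TSS with its CGI membership and, if inside a CGI, the signed distance
    from the island center (oriented by transcription direction)."""

    tss: TssRecord
    cgi_status: str  # "CGI" or "nCGI"
    distance_from_cgi_center: int | None = None

    def __post_init__(self) -> None:
        if self.cgi_status not in ("CGI", "nCGI"):
            raise ValueError("cgi_status must be 'CGI' or 'nCGI'")
        if (self.cgi_status == "CGI") != (self.distance_from_cgi_center is not None):
            raise ValueError("distance present iff cgi_status == 'CGI'")


@dataclass
class FilterTally:
    """Per-criterion rejection counts from :func:`filter_variants`."""

    n_input: int = 0
    n_kept: int = 0
    not_1000genomes: int = 0
    not_single: int = 0
    allele_freq_count_not_2: int = 0
    zero_allele_count: int = 0
    sample_too_small: int = 0


def filter_variants(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], FilterTally]:
    """Keep bi-allelic 1000 Genomes SNVs with usable allele counts.

    A record is kept iff all of: "1000GENOMES" appears among its submitters;
    its class is "single"; alleleFreqCount is 2; both allele counts are > 0;
    and the counts sum to > 1000.  Rejections are tallied by the first failing
    criterion, in that order.
    """
    kept: list[VariantRecord] = []
    tally = FilterTally(n_input=len(records))
    for rec in records:
        if "1000GENOMES" not in rec.submitters:
            tally.not_1000genomes += 1
        elif rec.var_class != "single":
            tally.not_single += 1
        elif rec.allele_freq_count != 2:
            tally.allele_freq_count_not_2 += 1
        elif len(rec.allele_ns) != 2 or min(rec.allele_ns) <= 0:
            tally.zero_allele_count += 1
        elif sum(rec.allele_ns) <= 1000:
            tally.sample_too_small += 1
        else:
            kept.append(rec)
    tally.n_kept = len(kept)
    return kept, tally


def compute_maf(allele_ns: Sequence[float]) -> float:
    """Minor allele frequency: the smaller of the two allele frequencies."""
    if len(allele_ns) != 2:
        raise ValueError("exactly two allele counts required")
    a, b = allele_ns
    if a <= 0 or b <= 0:
        raise ValueError("allele counts must both be positive")
    return min(a, b) / (a + b)


def derive_class_boundaries(
    mafs: Sequence[float],
    rare_threshold: float = DEFAULT_RARE_THRESHOLD,
    common_threshold: float = DEFAULT_COMMON_THRESHOLD,
) -> ClassBoundaries:
    """Split the intermediate MAF range at its median into two equal halves.

    Variants with ``rare_threshold < maf <= common_threshold`` are the
    intermediate set; its median is the mid1/mid2 boundary (mid1 keeps the
    median value, so for an odd count mid1 gets the extra variant).
    """
    if rare_threshold >= common_threshold:
        raise ValueError("rare_threshold must be below common_threshold")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("empty MAF list")
    inter = mafs[(mafs > rare_threshold) & (mafs <= common_threshold)]
    if inter.size == 0:
        raise ValueError("no intermediate-frequency variants to split")
    boundary = float(np.median(inter))
    if inter.size == 1:
        logger.warning("single intermediate variant: mid2 will be empty")
    return ClassBoundaries(rare_threshold, boundary, common_threshold)


def assign_class(maf: float, boundaries: ClassBoundaries) -> str:
    """Frequency-class label of a MAF under the boundary table."""
    if not (0 < maf <= 0.5):
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    for cls in boundaries.classes:
        if cls.contains(maf):
            return cls.label
    raise AssertionError("boundary table does not cover (0, 0.5]")  # pragma: no cover


# --- CpG island prediction -------------------------------------------------

_CG_SCORE = 17.0
_OTHER_SCORE = -1.0


def _dinucleotide_scores(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr[:-1] == b"C"
    is_g = arr[1:] == b"G"
    return np.where(is_c & is_g, _CG_SCORE, _OTHER_SCORE)


def _max_segment(prefix: np.ndarray, lo: int, hi: int) -> tuple[float, int, int]:
    """Maximum-sum contiguous segment of scores[lo:hi] via prefix sums.

    Returns (score, a, b) for the segment scores[a:b]; ties resolved by the
    smallest start, then the smallest end.
    """
    best = (-np.inf, lo, lo)
    min_p, min_at = prefix[lo], lo
    for b in range(lo + 1, hi + 1):
        score = prefix[b] - min_p
        if score > best[0]:
            best = (score, min_at, b)
        if prefix[b] < min_p:
            min_p, min_at = prefix[b], b
    return best


def _greedy_segments(scores: np.ndarray) -> list[tuple[int, int]]:
    """Non-overlapping positive-score segments, picked greedily by score."""
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    out: list[tuple[int, int]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        score, a, b = _max_segment(prefix, lo, hi)
        if score <= 0:
            continue
        out.append((a, b))
        stack.append((lo, a))
        stack.append((b, hi))
    return sorted(out)


def _cgi_criteria(sequence: str) -> bool:
    seq = sequence.upper()
    length = len(seq)
    if length <= 200:
        return False
    n_c = seq.count("C")
    n_g = seq.count("G")
    if (n_c + n_g) / length < 0.5:
        return False
    observed = sum(1 for k in range(length - 1) if seq[k : k + 2] == "CG")
    expected = n_c * n_g / length
    if expected == 0:
        return False
    return observed / expected > 0.6


def predict_cgi(sequence: str, chrom: str = "seq") -> list[GenomicInterval]:
    """Predict CpG islands in a DNA string.

    Dinucleotides score +17 for CG and -1 otherwise (N counts as "other");
    maximally scoring non-overlapping segments are extracted greedily in score
    order, then filtered by GC fraction >= 0.5, length > 200 bp, and
    observed/expected CpG ratio > 0.6 with expected = (#C * #G) / length.
    """
    if len(sequence) < 2:
        return []
    scores = _dinucleotide_scores(sequence)
    islands = []
    for a, b in _greedy_segments(scores):
        # dinucleotides a..b-1 span bases a..b+1 (half-open end b+1+... = b+1)
        start, end = a, b + 1
        if _cgi_criteria(sequence[start:end]):
            islands.append(GenomicInterval(chrom, start, end))
    return islands


# --- TSS classification ----------------------------------------------------


def classify_tss(
    tss: TssRecord, cgi_intervals: Sequence[GenomicInterval]
) -> ClassifiedTss:
    """CGI membership of a TSS (half-open intervals) and distance from island center.

    The distance is ``position - floor((start+end)/2)``, sign flipped for
    minus-strand TSSs so positive means downstream of the center.  If the TSS
    falls in two overlapping islands the first by coordinate is used (warning).
    """
    hits = sorted(
        (iv for iv in cgi_intervals if iv.chrom == tss.chrom and iv.contains(tss.position)),
        key=lambda iv: (iv.start, iv.end),
    )
    if not hits:
        return ClassifiedTss(tss, "nCGI")
    if len(hits) > 1:
        logger.warning("TSS %s inside %d overlapping CGIs; using first", tss.id, len(hits))
    iv = hits[0]
    dist = tss.position - iv.center
    if tss.strand == "-":
        dist = -dist
    return ClassifiedTss(tss, "CGI", dist)


def exclude_multi_tss(
    tss_list: Sequence[TssRecord], half_window: int = 5000
) -> list[TssRecord]:
    """Drop TSSs whose window hosts another TSS.

    A TSS is retained iff no other input TSS (kept or dropped) lies within
    ``[position - half_window, position + half_window]`` on its chromosome.
    """
    by_chrom: dict[str, list[int]] = {}
    for t in tss_list:
        by_chrom.setdefault(t.chrom, []).append(t.position)
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    kept = []
    for t in tss_list:
        pos = sorted_pos[t.chrom]
        lo = np.searchsorted(pos, t.position - half_window, side="left")
        hi = np.searchsorted(pos, t.position + half_window, side="right")
        if hi - lo <= 1:  # only itself in the window
            kept.append(t)
    return kept


def _merged_windows(
    tss_list: Sequence[TssRecord], half_window: int
) -> dict[str, np.ndarray]:
    """chrom -> (k, 2) array of merged, clipped-at-zero window intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in tss_list:
        by_chrom.setdefault(t.chrom, []).append(
            (max(0, t.position - half_window), t.position + half_window)
        )
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    return merged


def density_contrast(
    variants: Sequence[VariantRecord],
    tss_list: Sequence[TssRecord],
    genome_sizes: Mapping[str, int],
    half_window: int = 5000,
) -> tuple[float, float]:
    """Variant density (SNP/bp) inside the union of TSS windows vs the rest.

    Windows of different TSSs are merged (union semantics) before measuring;
    variants and bases outside the union make up the complement.
    """
    merged = _merged_windows(tss_list, half_window)
    union_bp = int(sum((m[:, 1] - m[:, 0]).sum() for m in merged.values()))
    total_bp = int(sum(genome_sizes.values()))
    if total_bp - union_bp <= 0:
        raise ValueError("window union covers the whole genome; empty complement")
    n_in = 0
    for v in variants:
        m = merged.get(v.chrom)
        if m is None:
            continue
        k = np.searchsorted(m[:, 0], v.position, side="right") - 1
        if k >= 0 and v.position < m[k, 1]:
            n_in += 1
    n_out = len(variants) - n_in
    return n_in / union_bp, n_out / (total_bp - union_bp)
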