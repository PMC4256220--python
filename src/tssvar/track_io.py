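"""Readers and writers for the tabular genomics dialects the pipeline consumes.

All coordinates are 0-based; intervals are half-open ``[start, end)``.  UCSC-style
table "start" fields are already 0-based and are adopted as-is.  Records on
alternative-haplotype contigs (names containing ``_hap`` or ``_alt``) are dropped
at read time with a logged count, since they duplicate primary-assembly data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TssRecord",
    "VariantRecord",
    "ScoreTrack",
    "ParseError",
    "read_tss_table",
    "read_variant_table",
    "read_bed",
    "read_bedgraph",
    "read_cadd_table",
    "write_bed",
    "write_bedgraph",
    "write_profile_tsv",
    "read_profile_tsv",
]


class ParseError(ValueError):
    """Raised when an input file violates its dialect; carries the line number."""


def _is_alt_contig(chrom: str) -> bool:
    return "_hap" in chrom or "_alt" in chrom


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TssRecord:
    """A strand-oriented transcription start site with a confidence score.

    ``position`` is the single 0-based base of the start site; the source track
    stores point features, so the record's "start" coordinate is used for both
    strands.
    """

    chrom: str
    position: int
    strand: str
    score: float
    id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")


@dataclass(frozen=True)
class VariantRecord:
    """A dbSNP-style variant row: class label, submitters, and two allele counts."""

    chrom: str
    position: int
    id: str
    var_class: str
    submitters: frozenset[str]
    allele_freq_count: int
    allele_ns: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.allele_freq_count == 2 and len(self.allele_ns) != 2:
            raise ValueError(
                "alleleNs must have exactly 2 entries when alleleFreqCount == 2"
            )


@dataclass
class ScoreTrack:
    """Per-base numeric signal stored as sorted interval runs per chromosome.

    ``semantics`` tags the signal kind: ``per_base_signal`` (nucleosome, GERP),
    ``per_variant_score`` (CADD) or ``base_membership`` (gBGC tracts, implicit
    score 1 on every covered base).
    """

    semantics: str = "per_base_signal"
    # chrom -> (starts, ends, values), arrays sorted by start, non-overlapping
    _runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    VALID_SEMANTICS = ("per_base_signal", "per_variant_score", "base_membership")

    def __post_init__(self) -> None:
        if self.semantics not in self.VALID_SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}")

    @classmethod
    def from_intervals(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        values: Sequence[float] | None = None,
        semantics: str = "per_base_signal",
    ) -> "ScoreTrack":
        """Build a track from interval records; later records win on overlap."""
        track = cls(semantics=semantics)
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        df["value"] = 1.0 if values is None else np.asarray(values, dtype=float)
        if not np.isfinite(df["value"]).all():
            raise ValueError("track values must be finite")
        for chrom, grp in df.groupby("chrom", sort=True):
            track._runs[str(chrom)] = _flatten_runs(
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["value"].to_numpy(float),
            )
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def total_scored_bases(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends, _ in self._runs.values())
        )

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)``; NaN where the track is silent."""
        out = np.full(end - start, np.nan)
        runs = self._runs.get(chrom)
        if runs is None:
            return out
        starts, ends, values = runs
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start : min(e, end) - start] = v
        return out

    def iter_runs(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


def _flatten_runs(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve overlaps with last-record-wins, returning sorted disjoint runs."""
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    overlap = bool(np.any(starts[1:] < ends[:-1])) if len(starts) > 1 else False
    if not overlap:
        return starts, ends, values
    logger.warning("overlapping track records; later records override earlier ones")
    # Sweep boundaries; at each base the record with the highest input index wins.
    bounds = np.unique(np.concatenate([starts, ends]))
    out_s, out_e, out_v = [], [], []
    orig_index = order  # input order of the sorted records
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        covering = np.nonzero((starts <= lo) & (ends >= hi))[0]
        if covering.size == 0:
            continue
        winner = covering[np.argmax(orig_index[covering])]
        v = values[winner]
        if out_s and out_e[-1] == lo and out_v[-1] == v:
            out_e[-1] = hi
        else:
            out_s.append(lo)
            out_e.append(hi)
            out_v.append(v)
    return (
        np.asarray(out_s, dtype=np.int64),
        np.asarray(out_e, dtype=np.int64),
        np.asarray(out_v, dtype=float),
    )


def _read_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_tss_table(path: str | Path, min_score: float = 0.0) -> list[TssRecord]:
    """Read a TSS point table (chrom, start, end, name, score, strand).

    Only records with ``score >= min_score`` are returned, preserving file order.
    The "start" field, already 0-based, is the TSS position for both strands.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    records: list[TssRecord] = []
    n_alt = 0
    for lineno, fields in _read_lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        chrom, start, _end, name, score, strand = fields[:6]
        if _is_alt_contig(chrom):
            n_alt += 1
            continue
        try:
            position = int(start)
            score_val = float(score)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        if score_val >= min_score:
            records.append(TssRecord(chrom, position, strand, score_val, name))
    if n_alt:
        logger.info("dropped %d TSS records on alternative-haplotype contigs", n_alt)
    return records


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a dbSNP-style variant table; no filtering is applied here.

    Expected columns: chrom, position, name, class, submitters (comma-separated),
    alleleFreqCount, alleleNs (comma-separated numeric pair).
    """
    records: list[VariantRecord] = []
    n_alt = 0
    for lineno, fields in _read_lines(path):
        if len(fields) < 7:
            raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        chrom, pos, name, var_class, submitters, afc, allele_ns = fields[:7]
        if _is_alt_contig(chrom):
            n_alt += 1
            continue
        try:
            position = int(pos)
            freq_count = int(afc)
            ns = tuple(float(x) for x in allele_ns.split(",") if x != "")
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric position/alleleFreqCount/alleleNs"
            ) from None
        records.append(
            VariantRecord(
                chrom=chrom,
                position=position,
                id=name,
                var_class=var_class,
                submitters=frozenset(s for s in submitters.split(",") if s),
                allele_freq_count=freq_count,
                allele_ns=ns,
            )
        )
    if n_alt:
        logger.info(
            "dropped %d variant records on alternative-haplotype contigs", n_alt
        )
    return records


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open); extra columns are ignored."""
    intervals: list[GenomicInterval] = []
    n_alt = 0
    for lineno, fields in _read_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        chrom, start, end = fields[0], fields[1], fields[2]
        if _is_alt_contig(chrom):
            n_alt += 1
            continue
        try:
            s, e = int(start), int(end)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if e <= s:
            raise ParseError(f"{path}:{lineno}: end ({e}) must exceed start ({s})")
        intervals.append(GenomicInterval(chrom, s, e))
    if n_alt:
        logger.info("dropped %d BED records on alternative-haplotype contigs", n_alt)
    return intervals


def read_bedgraph(path: str | Path, semantics: str = "per_base_signal") -> ScoreTrack:
    """Read a bedGraph into a :class:`ScoreTrack`.

    Every base in ``[start, end)`` receives the record's value.  On overlapping
    records the later one wins and a warning is logged.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    for lineno, fields in _read_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        chrom = fields[0]
        if _is_alt_contig(chrom):
            continue
        try:
            s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed bedGraph record") from None
        if not math.isfinite(v):
            raise ParseError(f"{path}:{lineno}: non-finite value")
        if e <= s:
            raise ParseError(f"{path}:{lineno}: end must exceed start")
        chroms.append(chrom)
        starts.append(s)
        ends.append(e)
        values.append(v)
    return ScoreTrack.from_intervals(chroms, starts, ends, values, semantics=semantics)


def read_cadd_table(path: str | Path) -> pd.DataFrame:
    """Read a per-variant deleteriousness score table.

    Columns: chrom, pos (0-based), ref, alt, raw score, scaled score.  Returns a
    DataFrame with those names; the raw score is the one downstream code uses.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "pos", "ref", "alt", "raw", "scaled"],
        dtype={"chrom": str, "pos": np.int64, "ref": str, "alt": str},
    )
    if not np.isfinite(df["raw"]).all():
        raise ParseError(f"{path}: non-finite raw scores")
    return df[~df["chrom"].map(_is_alt_contig)].reset_index(drop=True)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedgraph(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


_PROFILE_COLUMNS = [
    "bin",
    "offset_bp",
    "mean",
    "se",
    "ci_low",
    "ci_high",
    "n",
    "p_raw",
    "p_adjusted",
    "significant",
]


def write_profile_tsv(profile, path: str | Path) -> None:
    """Serialize a 200-bin profile to TSV.

    One row per bin: index ``j``, genomic offset of the bin's TSS-proximal edge,
    mean, SE, the two CI bounds, contributing count, raw and adjusted p-values,
    and a significance flag.  Missing cells are written as ``NA``.  Values are
    written with 12 significant digits so a read-back reproduces them.
    """
    if len(profile.bins) != 200:
        raise ValueError("profile must have 200 bins")

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return "NA"
        if isinstance(x, (bool, np.bool_)):
            return "1" if x else "0"
        if isinstance(x, (int, np.integer)):
            return str(int(x))
        return format(float(x), ".12g")

    with open(path, "w") as fh:
        fh.write("# signal=%s class=%s\n" % (profile.signal, profile.label or "NA"))
        fh.write("#" + "\t".join(_PROFILE_COLUMNS) + "\n")
        for row in profile.iter_rows():
            fh.write("\t".join(fmt(row[c]) for c in _PROFILE_COLUMNS) + "\n")


def read_profile_tsv(path: str | Path):
    """Read back a profile written by :func:`write_profile_tsv`."""
    from .binning import BinProfile  # local import to avoid a cycle

    signal, label = "unknown", None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# signal="):
                parts = dict(p.split("=", 1) for p in line[2:].split(" "))
                signal = parts.get("signal", "unknown")
                label = None if parts.get("class") == "NA" else parts.get("class")
                continue
            if line.startswith("#") or not line:
                continue
            rows.append(line.split("\t"))
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    df = df.where(df != "NA", np.nan)
    return BinProfile(
        bins=df["bin"].astype(int).to_numpy(),
        mean=df["mean"].astype(float).to_numpy(),
        se=df["se"].astype(float).to_numpy(),
        n=df["n"].astype(float).to_numpy(),
        signal=signal,
        label=label,
        p_raw=df["p_raw"].astype(float).to_numpy(),
        p_adjusted=df["p_adjusted"].astype(float).to_numpy(),
        significant=df["significant"].astype(float).to_numpy(),
    )
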