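"""Synthetic input bundles with planted, recoverable positional effects.

The generator emulates the real inputs the pipeline consumes — a TSS confidence
table, a dbSNP-style variant table, CGI and gBGC BED intervals, nucleosome and
conservation bedGraph tracks, and a per-variant deleteriousness table — with
configurable statistical structure:

* per-class variant counts per 50 bp bin are Poisson with a uniform baseline
  intensity times planted fold modifiers (default: a 1.7-fold rare-class
  enrichment over the first four downstream bins, the magnitude reported for
  CGI promoters);
* an inner/outer split structure: one latent per-bin deviation drives both the
  rare-class intensity and the gBGC base fraction inside a configurable
  half-width (default 14 bins = 700 bp), a second latent drives the rare-class
  intensity and the conservation score outside it, so the region-splitting
  scan has a recoverable boundary;
* the nucleosome track follows a smooth base profile plus a weighted copy of
  the rare-class intensity deviations, giving a recoverable BNP/BVF
  correlation;
* per-variant deleteriousness scores decrease with MAF class and with distance
  from the TSS.

Allele counts are built from a diploid panel of 1092 individuals (minor count
``k`` out of ``2*1092`` chromosomes), so every generated variant passes the
inclusion filters and MAF recomputation round-trips to the drawn value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinGrid, DEFAULT_GRID
from .selection import DEFAULT_COMMON_THRESHOLD, DEFAULT_RARE_THRESHOLD
from .track_io import GenomicInterval, ScoreTrack, TssRecord, VariantRecord

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "truth_report",
           "simulate_bin_counts", "simulate_class_matrices", "simulate_split_profiles"]

CLASS_ORDER = ("rare", "mid1", "mid2", "common")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Intensities are expected variants per TSS window per class; fold modifiers
    multiply the per-bin intensity of the named classes over an inclusive bin
    range.  Couplings are the amplitudes of the shared latent per-bin
    deviations that tie the rare-class intensity to the gBGC fraction (inner)
    and the conservation score (outer).
    """

    seed: int = 0
    n_chromosomes: int = 2
    n_tss: int = 2000
    tss_spacing: int = 12_000  # >= window span so windows never overlap
    frac_cgi: float = 0.53
    strand_prob: float = 0.5
    min_tss_score: float = 20.0
    panel_size: int = 1092
    # expected variants per TSS window per class; the defaults mirror the
    # real-data scale of ~96 variants per 10 kb window split ~21/23/24/32%
    class_intensity: tuple[tuple[str, float], ...] = (
        ("rare", 20.0), ("mid1", 22.0), ("mid2", 22.0), ("common", 31.0)
    )
    # (bin_lo, bin_hi, classes, fold), bins inclusive in transcription order
    positional_modifiers: tuple[tuple[int, int, tuple[str, ...], float], ...] = (
        (1, 4, ("rare",), 1.7),
    )
    nucleosome_coupling: float = 0.8
    nucleosome_noise_sd: float = 0.1
    inner_half_width: int = 14
    inner_coupling: float = 0.4    # rare-fold amplitude inside the split
    outer_coupling: float = 0.4    # rare-fold amplitude outside the split
    bbs_base: float = 0.15
    bbs_coupling: float = 0.08     # gBGC fraction amplitude on the inner latent
    bbs_noise_sd: float = 0.01
    gerp_base: float = 0.5
    gerp_coupling: float = 0.5     # conservation amplitude on the outer latent
    gerp_noise_sd: float = 0.05
    cadd_class_means: tuple[tuple[str, float], ...] = (
        ("rare", 1.5), ("mid1", 1.2), ("mid2", 0.9), ("common", 0.6)
    )
    cadd_distance_slope: float = 1e-4  # raw-score units per bp from the TSS
    cadd_noise_sd: float = 0.3
    multi_tss_clusters: int = 0  # extra TSSs planted < 10 kb from an existing one
    rare_threshold: float = DEFAULT_RARE_THRESHOLD
    common_threshold: float = DEFAULT_COMMON_THRESHOLD
    grid: BinGrid = field(default_factory=BinGrid)

    def __post_init__(self) -> None:
        if not (2 <= self.inner_half_width <= self.grid.n_bins // 2 - 2):
            raise ValueError("inner_half_width outside [2, n_bins/2 - 2]")
        if self.tss_spacing < self.grid.span:
            raise ValueError("tss_spacing must be at least the window span")
        if any(i <= 0 for _, i in self.class_intensity):
            raise ValueError("intensities must be positive")
        if any(f <= 0 for *_, f in self.positional_modifiers):
            raise ValueError("fold factors must be positive")

    @property
    def chrom_length(self) -> int:
        per_chrom = -(-self.n_tss // self.n_chromosomes)
        return (per_chrom + 2) * self.tss_spacing

    @property
    def two_n(self) -> int:
        return 2 * self.panel_size

    def minor_count_range(self, label: str) -> tuple[int, int]:
        """Inclusive range of minor-allele counts consistent with a class."""
        two_n = self.two_n
        bounds = {
            "rare": (0.0, self.rare_threshold),
            "mid1": (self.rare_threshold, 0.0014),
            "mid2": (0.0014, self.common_threshold),
            "common": (self.common_threshold, 0.5),
        }[label]
        lo = int(np.floor(bounds[0] * two_n)) + 1
        hi = int(np.floor(bounds[1] * two_n + 1e-9))
        if lo > hi:
            raise ValueError(f"class {label} admits no integer allele count")
        return lo, hi


def _fold_matrix(config: SyntheticConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class per-bin fold factors plus the two latent deviation vectors."""
    grid = config.grid
    j = grid.indices
    folds = np.ones((len(CLASS_ORDER), grid.n_bins))
    for lo, hi, classes, factor in config.positional_modifiers:
        mask = (j >= lo) & (j <= hi)
        for c in classes:
            folds[CLASS_ORDER.index(c), mask] *= factor
    inner = np.abs(j) <= config.inner_half_width
    u = np.where(inner, rng.standard_normal(grid.n_bins), 0.0)
    v = np.where(~inner, rng.standard_normal(grid.n_bins), 0.0)
    rare = CLASS_ORDER.index("rare")
    folds[rare] *= np.clip(1.0 + config.inner_coupling * u
                           + config.outer_coupling * v, 0.2, None)
    return folds, u, v


@dataclass
class SyntheticDataset:
    """An in-memory bundle plus the planted ground truth."""

    config: SyntheticConfig
    tss: list[TssRecord]
    variants: list[VariantRecord]
    variant_classes: list[str]
    cgi: list[GenomicInterval]
    gbgc: list[GenomicInterval]
    nucleosome: ScoreTrack
    gerp: ScoreTrack
    cadd: pd.DataFrame
    folds: np.ndarray          # planted per-class per-bin fold factors
    latent_inner: np.ndarray
    latent_outer: np.ndarray
    bbs_target: np.ndarray     # planted per-bin gBGC base fraction
    gerp_target: np.ndarray    # planted per-bin conservation mean

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize the bundle to the dialects the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fname for name, fname in [
            ("tss", "tss.tsv"), ("variants", "variants.tsv"),
            ("cgi", "cgi.bed"), ("gbgc", "gbgc.bed"),
            ("nucleosome", "nucleosome.bedgraph"), ("gerp", "gerp.bedgraph"),
            ("cadd", "cadd.tsv"), ("truth", "truth.tsv"),
        ]}
        with open(paths["tss"], "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for t in self.tss:
                fh.write(f"{t.chrom}\t{t.position}\t{t.position + 1}\t{t.id}\t"
                         f"{t.score:g}\t{t.strand}\n")
        with open(paths["variants"], "w") as fh:
            fh.write("#chrom\tposition\tname\tclass\tsubmitters\t"
                     "alleleFreqCount\talleleNs\n")
            for v in self.variants:
                subs = ",".join(sorted(v.submitters))
                ns = ",".join(f"{x:g}" for x in v.allele_ns)
                fh.write(f"{v.chrom}\t{v.position}\t{v.id}\t{v.var_class}\t"
                         f"{subs}\t{v.allele_freq_count}\t{ns}\n")
        _write_bed(self.cgi, paths["cgi"])
        _write_bed(self.gbgc, paths["gbgc"])
        _write_track(self.nucleosome, paths["nucleosome"])
        _write_track(self.gerp, paths["gerp"])
        with open(paths["cadd"], "w") as fh:
            fh.write("#chrom\tpos\tref\talt\traw\tscaled\n")
            for row in self.cadd.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\t"
                         f"{row.raw:.6g}\t{row.scaled:.6g}\n")
        truth_report(self).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _write_bed(intervals: Sequence[GenomicInterval], path: Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _write_track(track: ScoreTrack, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_runs():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def _bin_genomic_interval(position: int, strand: str, col: int,
                          grid: BinGrid) -> tuple[int, int]:
    """Genomic [start, end) of grid column ``col`` around a TSS."""
    d0 = (col - grid.n_bins // 2) * grid.bin_width
    if strand == "+":
        return position + d0, position + d0 + grid.bin_width
    return position - d0 - grid.bin_width + 1, position - d0 + 1


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full input bundle under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    n_bins, width = grid.n_bins, grid.bin_width

    # --- TSS layout: one row of evenly spaced, jittered sites per chromosome
    per_chrom = -(-config.n_tss // config.n_chromosomes)
    tss: list[TssRecord] = []
    counter = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for k in range(per_chrom):
            if counter >= config.n_tss:
                break
            slack = config.tss_spacing - grid.span
            jitter = int(rng.integers(0, max(slack, 1)))
            pos = (k + 1) * config.tss_spacing + jitter
            strand = "+" if rng.random() < config.strand_prob else "-"
            score = float(config.min_tss_score + rng.integers(0, 80))
            tss.append(TssRecord(chrom, pos, strand, score, f"tss{counter:05d}"))
            counter += 1
    for m in range(config.multi_tss_clusters):
        anchor = tss[int(rng.integers(0, len(tss)))]
        offset = int(rng.integers(500, grid.half_span - 500))
        tss.append(TssRecord(anchor.chrom, anchor.position + offset,
                             anchor.strand, float(config.min_tss_score + 10),
                             f"tss_multi{m:03d}"))

    # --- CGIs containing a configurable fraction of TSSs
    is_cgi = rng.random(len(tss)) < config.frac_cgi
    cgi: list[GenomicInterval] = []
    for t, flag in zip(tss, is_cgi):
        if not flag:
            continue
        length = int(rng.integers(300, 1500))
        shift = int(rng.integers(-length // 4, length // 4 + 1))
        start = max(0, t.position - length // 2 + shift)
        cgi.append(GenomicInterval(t.chrom, start, start + length))

    # --- planted per-bin structure
    folds, u, v = _fold_matrix(config, rng)
    intensity = dict(config.class_intensity)
    lam = np.stack([
        intensity[c] / n_bins * folds[ci] for ci, c in enumerate(CLASS_ORDER)
    ])  # (4, n_bins) expected counts per TSS
    j = grid.indices
    bbs_target = np.clip(config.bbs_base + config.bbs_coupling * u, 0.0, 1.0)
    gerp_target = config.gerp_base + config.gerp_coupling * v
    # smooth nucleosome base: occupancy dip centered on the TSS
    centers = np.where(j > 0, (j - 0.5), (j + 0.5))
    nuc_base = 1.0 - 0.6 * np.exp(-((centers / 20.0) ** 2))
    nuc_target = nuc_base + config.nucleosome_coupling * (folds[0] - folds[0].mean())

    # --- variants, tracks, per-variant scores
    count_ranges = {c: config.minor_count_range(c) for c in CLASS_ORDER}
    cadd_means = dict(config.cadd_class_means)
    variants: list[VariantRecord] = []
    variant_classes: list[str] = []
    cadd_rows: list[tuple] = []
    gbgc: list[GenomicInterval] = []
    nuc_records: list[tuple] = []
    gerp_records: list[tuple] = []
    two_n = config.two_n
    offsets = np.where(j > 0, (j - 1) * width, j * width)  # proximal edge per column
    vid = 0
    for t in tss:
        counts = rng.poisson(lam)  # (4, n_bins)
        for ci, label in enumerate(CLASS_ORDER):
            lo_k, hi_k = count_ranges[label]
            for col in np.nonzero(counts[ci])[0]:
                gstart, gend = _bin_genomic_interval(t.position, t.strand, col, grid)
                n = counts[ci, col]
                pos = rng.integers(gstart, gend, size=n)
                ks = rng.integers(lo_k, hi_k + 1, size=n)
                d_edge = offsets[col]
                for p, kminor in zip(pos, ks):
                    variants.append(VariantRecord(
                        chrom=t.chrom, position=int(p), id=f"rs{vid:08d}",
                        var_class="single",
                        submitters=frozenset({"1000GENOMES", "OTHER"}),
                        allele_freq_count=2,
                        allele_ns=(float(kminor), float(two_n - kminor)),
                    ))
                    variant_classes.append(label)
                    dist = abs(p - t.position if t.strand == "+" else t.position - p)
                    raw = (cadd_means[label] - config.cadd_distance_slope * dist
                           + rng.normal(0.0, config.cadd_noise_sd))
                    cadd_rows.append((t.chrom, int(p), "A", "G",
                                      float(raw), float(10.0 * raw)))
                    vid += 1
        # per-bin track records at bin resolution
        noise_n = rng.normal(0.0, config.nucleosome_noise_sd, size=n_bins)
        noise_g = rng.normal(0.0, config.gerp_noise_sd, size=n_bins)
        for col in range(n_bins):
            gstart, gend = _bin_genomic_interval(t.position, t.strand, col, grid)
            nuc_records.append((t.chrom, gstart, gend, nuc_target[col] + noise_n[col]))
            gerp_records.append((t.chrom, gstart, gend, gerp_target[col] + noise_g[col]))
            covered = int(round(bbs_target[col] * width))
            if covered > 0:
                gbgc.append(GenomicInterval(t.chrom, gstart, gstart + covered))

    def to_track(records: list[tuple], semantics: str) -> ScoreTrack:
        chroms, starts, ends, values = zip(*records)
        return ScoreTrack.from_intervals(chroms, starts, ends, values,
                                         semantics=semantics)

    nucleosome = to_track(nuc_records, "per_base_signal")
    gerp = to_track(gerp_records, "per_base_signal")
    cadd = pd.DataFrame(cadd_rows,
                        columns=["chrom", "pos", "ref", "alt", "raw", "scaled"])
    return SyntheticDataset(
        config=config, tss=tss, variants=variants,
        variant_classes=variant_classes, cgi=cgi, gbgc=gbgc,
        nucleosome=nucleosome, gerp=gerp, cadd=cadd,
        folds=folds, latent_inner=u, latent_outer=v,
        bbs_target=bbs_target, gerp_target=gerp_target,
    )


def truth_report(dataset: SyntheticDataset) -> pd.DataFrame:
    """Machine-readable table of the planted parameters.

    Includes the fold modifiers, the inner half-width, the coupling amplitudes,
    and the correlations actually achieved between the planted per-bin targets
    (the recovery ceiling for the split scan).
    """
    cfg = dataset.config
    j = cfg.grid.indices
    inner = np.abs(j) <= cfg.inner_half_width
    delta_expect = (dataset.folds[0] / dataset.folds[0].sum()
                    - dataset.folds[CLASS_ORDER.index("common")]
                    / dataset.folds[CLASS_ORDER.index("common")].sum())
    rows = [
        ("seed", cfg.seed),
        ("n_tss", cfg.n_tss),
        ("inner_half_width_bins", cfg.inner_half_width),
        ("inner_coupling", cfg.inner_coupling),
        ("outer_coupling", cfg.outer_coupling),
        ("nucleosome_coupling", cfg.nucleosome_coupling),
        ("achieved_r_inner",
         _safe_corr(dataset.bbs_target[inner], delta_expect[inner])),
        ("achieved_r_outer",
         _safe_corr(dataset.gerp_target[~inner], delta_expect[~inner])),
    ]
    for lo, hi, classes, factor in cfg.positional_modifiers:
        rows.append((f"fold_bins_{lo}_{hi}_{'+'.join(classes)}", factor))
    return pd.DataFrame(rows, columns=["parameter", "value"])


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def simulate_class_matrices(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, "object"], np.ndarray, np.ndarray]:
    """Per-class per-TSS bin-count matrices under the planted model.

    The same Poisson count model as :func:`generate_dataset`, skipping genomic
    coordinates and file dialects — the fast path for replicated simulations.
    Returns the matrices plus the two latent deviation vectors.
    """
    from .binning import BinMatrix

    rng = np.random.default_rng(config.seed) if rng is None else rng
    folds, u, v = _fold_matrix(config, rng)
    intensity = dict(config.class_intensity)
    ids = [f"tss{i:05d}" for i in range(config.n_tss)]
    matrices = {}
    for ci, label in enumerate(CLASS_ORDER):
        counts = simulate_bin_counts(
            config.n_tss, intensity[label], rng, fold=folds[ci], grid=config.grid
        )
        matrices[label] = BinMatrix(
            tss_ids=ids, counts=counts, signal="BVF", grid=config.grid, label=label
        )
    return matrices, u, v


def simulate_split_profiles(
    config: SyntheticConfig, rng: np.random.Generator | None = None
):
    """Planted gBGC, conservation and rare-common difference profiles.

    Produces the three inputs of the region-splitting scan exactly as the full
    pipeline would measure them: the gBGC base fraction is the planted target
    quantized to the bin width, the conservation profile carries the pooled
    per-TSS noise, and the difference profile is computed from simulated
    per-class count matrices via the paired test machinery.
    """
    from .binning import BinProfile
    from .inference import bvf_delta_test

    rng = np.random.default_rng(config.seed) if rng is None else rng
    grid = config.grid
    matrices, u, v = simulate_class_matrices(config, rng)
    delta_profile, _ = bvf_delta_test(matrices["rare"], matrices["common"])
    bbs_mean = (
        np.round(np.clip(config.bbs_base + config.bbs_coupling * u, 0, 1)
                 * grid.bin_width) / grid.bin_width
    )
    gerp_mean = (
        config.gerp_base + config.gerp_coupling * v
        + rng.normal(0.0, config.gerp_noise_sd / np.sqrt(config.n_tss), grid.n_bins)
    )
    n = np.full(grid.n_bins, float(config.n_tss))
    zeros = np.zeros(grid.n_bins)
    bbs = BinProfile(grid.indices, bbs_mean, zeros, n, "BBS", grid=grid)
    bgs = BinProfile(grid.indices, gerp_mean, zeros, n, "BGS", grid=grid)
    return bbs, bgs, delta_profile


def simulate_bin_counts(
    n_tss: int,
    mean_variants: float,
    rng: np.random.Generator,
    fold: np.ndarray | None = None,
    grid: BinGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Per-TSS per-bin Poisson variant counts, bypassing file I/O.

    The count model is the same as :func:`generate_dataset`'s (independent
    Poisson cells with intensity ``mean_variants / n_bins`` times the fold
    vector); this fast path serves the replicated calibration and recovery
    simulations.
    """
    lam = np.full(grid.n_bins, mean_variants / grid.n_bins)
    if fold is not None:
        lam = lam * np.asarray(fold, dtype=float)
    return rng.poisson(lam, size=(n_tss, grid.n_bins)).astype(float)
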