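"""End-to-end orchestration: selection -> binning -> inference -> TSV bundle.

``run_all`` sequences the full analysis on one set of input files and returns a
:class:`PipelineResult` whose every table can be serialized to TSV;
``report`` renders a human-readable summary from those tables alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binning, inference, selection, track_io
from .binning import BinGrid, BinMatrix, BinProfile

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "report"]

CLASS_ORDER = ("rare", "mid1", "mid2", "common")
STATUSES = ("CGI", "nCGI")


@dataclass
class PipelineConfig:
    """Run-level constants and input paths."""

    tss_path: str
    variant_path: str
    cgi_path: str
    gbgc_path: str
    nucleosome_path: str
    gerp_path: str
    cadd_path: str
    outdir: str = "results"
    min_tss_score: float = 20.0
    rare_threshold: float = selection.DEFAULT_RARE_THRESHOLD
    common_threshold: float = selection.DEFAULT_COMMON_THRESHOLD
    alpha: float = inference.DEFAULT_ALPHA
    track_mode: str = "pooled_base_mean"  # or "per_tss_mean"
    exclude_multi: bool = False
    genome_sizes: Mapping[str, int] | None = None
    grid: BinGrid = field(default_factory=BinGrid)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.track_mode not in ("pooled_base_mean", "per_tss_mean"):
            raise ValueError(f"unknown track_mode {self.track_mode!r}")


@dataclass
class PipelineResult:
    """All analysis outputs, keyed the way the TSV bundle is laid out."""

    config: PipelineConfig
    counts: dict[str, int]
    boundaries: selection.ClassBoundaries
    density: tuple[float, float]
    cgi_distance_skewness: tuple[float, float, float] | None
    profiles: dict[str, BinProfile]                 # "BVF/CGI/rare", "BNP/CGI", ...
    bin_tests: dict[str, inference.BinTestResult]   # "neutral/CGI/rare", ...
    delta_profiles: dict[str, BinProfile]           # per status
    delta_tests: dict[str, inference.BinTestResult]
    contrasts: dict[str, tuple[pd.DataFrame, float, float]]  # signal -> per-bin, X, p
    correlations: pd.DataFrame                      # BNP x BVF per class x status
    split: inference.RegionSplitResult | None
    anova: dict[str, pd.DataFrame]                  # per status
    cadd_pairwise: dict[str, pd.DataFrame]          # per class: CGI vs nCGI
    wilcoxon: pd.DataFrame                          # upstream vs downstream per class
    log_lines: list[str]

    def write(self, outdir: str | Path | None = None) -> Path:
        out = Path(outdir or self.config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key, profile in {**self.profiles, **self.delta_profiles}.items():
            track_io.write_profile_tsv(profile, out / f"profile_{_slug(key)}.tsv")
        for key, test in {**self.bin_tests, **self.delta_tests}.items():
            _write_df(test.to_frame(), out / f"test_{_slug(key)}.tsv")
        for key, (per_bin, x, p) in self.contrasts.items():
            df = per_bin.copy()
            df.attrs["fisher_X"] = x
            _write_df(df, out / f"contrast_{_slug(key)}.tsv",
                      extra_header=[f"fisher_X={x:.6g}", f"fisher_p={_fmt_p(p)}",
                                    "note=per-bin tests treated as independent"])
        _write_df(self.correlations, out / "correlations_bnp_bvf.tsv")
        if self.split is not None:
            _write_df(self.split.trace, out / "split_trace.tsv",
                      extra_header=[f"boundary_bins={self.split.boundary}",
                                    f"boundary_bp={self.split.boundary_bp}",
                                    f"r_inner={self.split.r_inner:.6g}",
                                    f"r_outer={self.split.r_outer:.6g}",
                                    f"weak_inner={int(self.split.weak_inner)}"])
        for status, df in self.anova.items():
            _write_df(df, out / f"anova_bcs_{status}.tsv")
        for label, df in self.cadd_pairwise.items():
            _write_df(df, out / f"pairwise_bcs_{_slug(label)}.tsv")
        _write_df(self.wilcoxon, out / "wilcoxon_updown.tsv")
        with open(out / "run_log.txt", "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        return out


def _slug(key: str) -> str:
    return key.replace("/", "_")


def _fmt_p(p: float) -> str:
    return f"< {inference.P_FLOOR:g}" if 0 < p < inference.P_FLOOR else f"{p:.6g}"


def _write_df(df: pd.DataFrame, path: Path,
              extra_header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in extra_header or ():
            fh.write(f"# {line}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False, na_rep="NA",
                  float_format="%.12g")


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; any stage error aborts naming the stage."""
    log: list[str] = [
        f"alpha={config.alpha}", f"min_tss_score={config.min_tss_score}",
        f"rare_threshold={config.rare_threshold}",
        f"common_threshold={config.common_threshold}",
        f"track_mode={config.track_mode}", f"exclude_multi={config.exclude_multi}",
    ]
    stage = "selection"
    try:
        tss = track_io.read_tss_table(config.tss_path, config.min_tss_score)
        raw_variants = track_io.read_variant_table(config.variant_path)
        cgi = track_io.read_bed(config.cgi_path)
        gbgc_iv = track_io.read_bed(config.gbgc_path)
        nucleosome = track_io.read_bedgraph(config.nucleosome_path)
        gerp = track_io.read_bedgraph(config.gerp_path)
        cadd = track_io.read_cadd_table(config.cadd_path)

        variants, tally = selection.filter_variants(raw_variants)
        mafs = np.array([selection.compute_maf(v.allele_ns) for v in variants])
        boundaries = selection.derive_class_boundaries(
            mafs, config.rare_threshold, config.common_threshold)
        classes = [selection.assign_class(m, boundaries) for m in mafs]
        log.append(f"tss_selected={len(tss)} variants_in={tally.n_input} "
                   f"variants_kept={tally.n_kept}")
        log.append(f"mid_boundary={boundaries.mid_boundary:.6g}")

        classified = [selection.classify_tss(t, cgi) for t in tss]
        if config.exclude_multi:
            kept = {t.id for t in selection.exclude_multi_tss(
                tss, half_window=config.grid.half_span)}
            classified = [c for c in classified if c.tss.id in kept]
            log.append(f"multi_tss_excluded_to={len(classified)}")
        groups = {s: [c.tss for c in classified if c.cgi_status == s]
                  for s in STATUSES}
        log.append("cgi_tss=%d ncgi_tss=%d" % (len(groups["CGI"]), len(groups["nCGI"])))

        cgi_dist = [c.distance_from_cgi_center for c in classified
                    if c.cgi_status == "CGI"]
        skew = None
        if len(cgi_dist) >= 8:
            skew = inference.dagostino_skewness(cgi_dist)
            log.append(f"cgi_center_skewness_p={skew[2]:.4g}")

        genome_sizes = dict(config.genome_sizes) if config.genome_sizes else \
            _infer_genome_sizes(tss, variants, config.grid)
        density = selection.density_contrast(variants, tss, genome_sizes,
                                             half_window=config.grid.half_span)
        log.append(f"density_in={density[0]:.6g} density_out={density[1]:.6g}")

        stage = "binning"
        matrices: dict[str, dict[str, BinMatrix]] = {}
        profiles: dict[str, BinProfile] = {}
        for status, members in groups.items():
            if not members:
                continue
            matrices[status] = binning.bin_variants_by_class(
                members, variants, classes, grid=config.grid)
            for label in CLASS_ORDER:
                if label in matrices[status]:
                    prof = binning.bvf_profile(matrices[status][label])
                    profiles[f"BVF/{status}/{label}"] = prof

        track_specs = {"BNP": nucleosome, "BGS": gerp}
        bbs_track = track_io.ScoreTrack.from_intervals(
            [iv.chrom for iv in gbgc_iv], [iv.start for iv in gbgc_iv],
            [iv.end for iv in gbgc_iv], semantics="base_membership")
        per_tss_values: dict[str, dict[str, np.ndarray]] = {s: {} for s in STATUSES}
        for status, members in groups.items():
            if not members:
                continue
            for signal, track in track_specs.items():
                profiles[f"{signal}/{status}"] = binning.track_profile(
                    members, track, grid=config.grid, mode=config.track_mode,
                    signal=signal, label=status)
                per_tss_values[status][signal] = binning.track_bin_matrix(
                    members, track, grid=config.grid, signal=signal).per_tss_means()
            profiles[f"BBS/{status}"] = binning.track_profile(
                members, bbs_track, grid=config.grid,
                mode="per_tss_base_fraction", signal="BBS", label=status)
            frac = np.zeros((len(members), config.grid.n_bins))
            for i, t in enumerate(members):
                w = binning._window_matrix(t, bbs_track, config.grid)
                frac[i] = np.isfinite(w).sum(axis=1) / config.grid.bin_width
            per_tss_values[status]["BBS"] = frac

        stage = "inference"
        bin_tests: dict[str, inference.BinTestResult] = {}
        for status in STATUSES:
            for label in CLASS_ORDER:
                mat = matrices.get(status, {}).get(label)
                if mat is not None and (mat.row_totals() > 0).sum() >= 2:
                    bin_tests[f"neutral/{status}/{label}"] = \
                        inference.neutral_bin_test(mat, alpha=config.alpha)

        delta_profiles: dict[str, BinProfile] = {}
        delta_tests: dict[str, inference.BinTestResult] = {}
        for status in STATUSES:
            mats = matrices.get(status, {})
            if "rare" in mats and "common" in mats:
                prof, test = inference.bvf_delta_test(
                    mats["rare"], mats["common"], alpha=config.alpha)
                delta_profiles[f"delta/{status}"] = prof
                delta_tests[f"delta/{status}"] = test

        contrasts: dict[str, tuple[pd.DataFrame, float, float]] = {}
        if groups["CGI"] and groups["nCGI"]:
            for signal in ("BNP", "BGS", "BBS"):
                contrasts[signal] = inference.signal_contrast(
                    per_tss_values["CGI"][signal], per_tss_values["nCGI"][signal],
                    alpha=config.alpha)

        corr_rows = []
        for status in STATUSES:
            bnp = profiles.get(f"BNP/{status}")
            if bnp is None:
                continue
            for label in CLASS_ORDER:
                bvf = profiles.get(f"BVF/{status}/{label}")
                if bvf is None:
                    continue
                try:
                    r, t_stat, p, n = inference.pearson_test(bnp.mean, bvf.mean)
                except ValueError:
                    continue
                corr_rows.append((status, label, r, t_stat, p, n))
        correlations = pd.DataFrame(
            corr_rows, columns=["cgi_status", "maf_class", "r", "t", "p", "n"])

        split = None
        if ("BBS/CGI" in profiles and "BGS/CGI" in profiles
                and "delta/CGI" in delta_profiles):
            try:
                split = inference.window_split(
                    profiles["BBS/CGI"], profiles["BGS/CGI"],
                    delta_profiles["delta/CGI"])
            except ValueError as degenerate:
                log.append(f"split_skipped={degenerate}")
            else:
                log.append(f"split_boundary_bins={split.boundary} "
                           f"r_inner={split.r_inner:.4g} "
                           f"r_outer={split.r_outer:.4g}")

        stage = "deleteriousness"
        scores = {(c, int(p)): float(r) for c, p, r in
                  zip(cadd["chrom"], cadd["pos"], cadd["raw"])}
        by_class = {label: [v for v, c in zip(variants, classes) if c == label]
                    for label in CLASS_ORDER}
        scores_by_class_status: dict[str, dict[str, list[np.ndarray]]] = {}
        for status, members in groups.items():
            if not members:
                continue
            scores_by_class_status[status] = {}
            for label in CLASS_ORDER:
                per_bin = binning.bin_variant_scores(
                    members, by_class[label], scores, grid=config.grid)
                scores_by_class_status[status][label] = per_bin
                profiles[f"BCS/{status}/{label}"] = binning.cadd_profile(
                    members, by_class[label], scores, grid=config.grid,
                    signal="BCS", label=f"{status}/{label}")

        anova = {
            status: inference.bcs_class_anova(per_class, alpha=config.alpha)
            for status, per_class in scores_by_class_status.items()
        }
        cadd_pairwise: dict[str, pd.DataFrame] = {}
        if len(scores_by_class_status) == 2:
            for label in CLASS_ORDER:
                cadd_pairwise[label] = inference.profile_ttest_pair(
                    scores_by_class_status["CGI"][label],
                    scores_by_class_status["nCGI"][label], alpha=config.alpha)

        wil_rows = []
        half = config.grid.n_bins // 2
        for status, per_class in scores_by_class_status.items():
            for label in CLASS_ORDER:
                per_bin = per_class[label]
                up = np.concatenate([b for b in per_bin[:half]] or [np.array([])])
                down = np.concatenate([b for b in per_bin[half:]] or [np.array([])])
                if up.size and down.size:
                    p = inference.wilcoxon_updown(up, down)
                    wil_rows.append((status, label, up.size, down.size, p))
        wilcoxon = pd.DataFrame(
            wil_rows, columns=["cgi_status", "maf_class", "n_up", "n_down", "p"])

        counts = {
            "n_tss": len(tss),
            "n_cgi_tss": len(groups["CGI"]),
            "n_ncgi_tss": len(groups["nCGI"]),
            "n_variants_input": tally.n_input,
            "n_variants_kept": tally.n_kept,
        }
        return PipelineResult(
            config=config, counts=counts, boundaries=boundaries, density=density,
            cgi_distance_skewness=skew, profiles=profiles, bin_tests=bin_tests,
            delta_profiles=delta_profiles, delta_tests=delta_tests,
            contrasts=contrasts, correlations=correlations, split=split,
            anova=anova, cadd_pairwise=cadd_pairwise, wilcoxon=wilcoxon,
            log_lines=log,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _infer_genome_sizes(tss, variants, grid) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for t in tss:
        sizes[t.chrom] = max(sizes.get(t.chrom, 0), t.position + grid.half_span)
    for v in variants:
        sizes[v.chrom] = max(sizes.get(v.chrom, 0), v.position + 1)
    return sizes


def _bin_ranges(bins: np.ndarray) -> str:
    """Compress significant bin indices into contiguous ranges like '+1..+4'."""
    if bins.size == 0:
        return "none"
    bins = np.sort(bins)
    parts, start, prev = [], bins[0], bins[0]
    for b in bins[1:]:
        if b == prev + 1 or (prev == -1 and b == 1):  # -1 and +1 are adjacent
            prev = b
            continue
        parts.append((start, prev))
        start = prev = b
    parts.append((start, prev))
    return ", ".join(f"{s:+d}" if s == e else f"{s:+d}..{e:+d}" for s, e in parts)


def report(result: PipelineResult) -> str:
    """Human-readable summary; every number comes from a result table."""
    lines = ["== TSS-flanking variant analysis =="]
    c = result.counts
    lines.append(f"TSSs: {c['n_tss']} (CGI {c['n_cgi_tss']}, nCGI {c['n_ncgi_tss']}); "
                 f"variants kept: {c['n_variants_kept']} of {c['n_variants_input']}")
    lines.append(f"MAF classes: rare <= {result.boundaries.rare_threshold:g} < mid1 "
                 f"<= {result.boundaries.mid_boundary:g} < mid2 <= "
                 f"{result.boundaries.common_threshold:g} < common")
    d_in, d_out = result.density
    lines.append(f"variant density: {d_in:.4g} inside windows vs {d_out:.4g} outside")
    if result.cgi_distance_skewness is not None:
        sk, z, p = result.cgi_distance_skewness
        lines.append(f"CGI-center distance skewness {sk:.3g} (z={z:.3g}, p={_fmt_p(p)})")
    lines.append("-- uniform-null bin tests --")
    for key, test in sorted(result.bin_tests.items()):
        sig = test.significant_bins()
        fold = _fold_estimate(result, key)
        extra = f"; downstream/upstream fold (bins 1..4): {fold:.3g}" if fold else ""
        lines.append(f"{key}: significant bins {_bin_ranges(sig)}{extra}")
    lines.append("-- rare-common difference --")
    for key, test in sorted(result.delta_tests.items()):
        lines.append(f"{key}: significant bins {_bin_ranges(test.significant_bins())}")
    if result.contrasts:
        lines.append("-- CGI vs nCGI whole-signal contrasts (Fisher) --")
        for signal, (_per_bin, x, p) in result.contrasts.items():
            lines.append(f"{signal}: X={x:.4g}, combined p {_fmt_p(p)}")
    if len(result.correlations):
        lines.append("-- nucleosome (BNP) x variant frequency (BVF) correlations --")
        for row in result.correlations.itertuples(index=False):
            lines.append(f"{row.cgi_status}/{row.maf_class}: r={row.r:.3f} "
                         f"(t={row.t:.3g}, p={_fmt_p(row.p)}, n={row.n})")
    if result.split is not None:
        s = result.split
        flag = " [weak inner signal]" if s.weak_inner else ""
        lines.append(f"-- region split -- boundary {s.boundary} bins "
                     f"({s.boundary_bp} bp); r_inner={s.r_inner:.3f}, "
                     f"r_outer={s.r_outer:.3f}{flag}")
    for status, df in result.anova.items():
        n_sig = int(df["significant"].sum())
        lines.append(f"BCS class ANOVA ({status}): {n_sig} significant bins")
    if len(result.wilcoxon):
        lines.append("-- deleteriousness upstream vs downstream (Wilcoxon) --")
        for row in result.wilcoxon.itertuples(index=False):
            lines.append(f"{row.cgi_status}/{row.maf_class}: p {_fmt_p(row.p)}")
    return "\n".join(lines)


def _fold_estimate(result: PipelineResult, key: str) -> float | None:
    """Mean BVF over bins +1..+4 divided by the mean over -4..-1."""
    prof = result.profiles.get(key.replace("neutral/", "BVF/"))
    if prof is None:
        return None
    j = prof.grid.indices
    down = prof.mean[(j >= 1) & (j <= 4)]
    up = prof.mean[(j >= -4) & (j <= -1)]
    if up.mean() <= 0:
        return None
    return float(down.mean() / up.mean())
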