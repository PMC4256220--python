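# Methods

## Coordinates, grid and orientation

All coordinates are 0-based; intervals are half-open `[start, end)`.  A TSS is
a single base; the table's `start` column is used as that base for both
strands.  Offsets are measured in the direction of transcription: for a
plus-strand TSS the offset of base `p` is `d = p − tss`, for a minus-strand TSS
`d = tss − p`, so positive offsets are always downstream (transcribed side).

The window `d ∈ [−5000, 5000)` is divided into 200 bins of 50 bp indexed
`j ∈ {−100..−1, +1..+100}`; bin `j > 0` covers `d ∈ [(j−1)·50, j·50)` and bin
`j < 0` covers `d ∈ [j·50, (j+1)·50)`.  There is no bin 0: a variant exactly at
the TSS (`d = 0`) falls in bin +1, since the downstream extrema start at the
TSS itself.  Strand-mirror symmetry (reflecting every coordinate through the
TSS and flipping the strand) leaves every profile exactly unchanged; this is
enforced by test.  TSSs closer than 5,000 bp to a chromosome end would create
truncated windows; the synthetic generator never places any, and the readers
assume full windows.

## Variant selection and MAF classes

Variants are kept when they are 1000 Genomes submissions (`1000GENOMES` among
submitters), single-nucleotide (`class == "single"`), bi-allelic
(`alleleFreqCount == 2`), with both allele counts positive and summing to more
than 1000 chromosomes.  MAF is the smaller of the two allele frequencies.

Classes partition `(0, 0.5]`:

| class  | range                        | boundary rationale                         |
|--------|------------------------------|--------------------------------------------|
| rare   | `(0, 4.59e-4]`               | lowest MAF observable in the reference panel (one heterozygote among ~1092 diploids) |
| mid1   | `(4.59e-4, median]`          | data-derived: median of the intermediate MAFs |
| mid2   | `(median, 0.01]`             | —                                          |
| common | `(0.01, 0.5]`                | canonical common-variant cutoff (strict)   |

The rare boundary is stored as the operational constant 4.59e-4; the idealized
arithmetic `1/(2·1092) = 4.5788e-4` sits just below it and still classifies as
rare.  Boundary inclusivity: rare includes its upper bound, common excludes
0.01, and the mid1/mid2 split keeps the median value in mid1 (so an odd
intermediate count gives mid1 the extra variant).  Both thresholds and the
panel size are configurable.

## The uniform-null bin test

Per TSS, bin counts are normalized by the window total,
`f(i,j) = vars(i,j)/V(i)` (TSSs with `V(i) = 0` are excluded — they carry no
positional information), making the neutral expectation exactly `1/200` per
bin and `Σ_j BVF(j) = 1`.

The default test is a **paired t-test against a simulated neutral model**: for
each retained TSS the same `V(i)` variants are redistributed uniformly over the
200 bins (two independent multinomial replicates, averaged; seeded and
deterministic), and `f(i,j) − f₀(i,j)` is tested against 0 bin by bin.  The
simulated arm carries the same zero-inflated, right-skewed sampling noise as
the data, so the skewness-induced distortion of the t statistic cancels
between the arms.  The alternative `null="analytic"` tests `f(i,j)` directly
against the constant `1/200`; for sparse windows (a handful of variants per
TSS) that one-sample form is anti-conservative in the extreme left
(depletion) tail that Bonferroni correction probes, because the per-TSS
frequencies are strongly right-skewed and the sample mean and sample SD are
negatively coupled.  Two null replicates per TSS are the default: one
replicate already restores calibration, the second recovers most of the power
lost to the noise in the simulated arm.  Calibration (family-wise error
≤ 0.005 over 200 uniform datasets of 2,000 TSSs with Poisson(10) variants) and
power (all four bins of a planted 1.7-fold enrichment significant at 5,000
TSSs) are computed by the acceptance suite, not assumed.

All 200 p-values of a family are Bonferroni corrected (`min(1, 200·p)`); the
study-wide significance level defaults to α = 0.001.  Bins with zero variance
get a missing p-value and are never counted as significant.

## Rare-minus-common differences

`delta(i,j) = f_rare(i,j) − f_common(i,j)` over TSSs carrying both classes,
tested against 0 with the same machinery.  The sign convention is
rare − common: positive where young variants are relatively more frequent.
Swapping the inputs negates every mean and leaves every p-value unchanged
(an exact antisymmetry, enforced by test).

## Track aggregation

Nucleosome and conservation signals are aggregated per bin as **pooled base
means**: the sum of all scored-base values in bin `j` across TSSs divided by
the number of scored bases.  Pooling avoids per-TSS divide-by-zero for sparse
tracks; the per-TSS alternative (`per_tss_mean`, mean of per-TSS bin means) is
a config switch, and per-TSS bin values are what the CGI-vs-nCGI per-bin
t-tests consume.  The gBGC signal is a **per-TSS base fraction**: the fraction
of the bin's 50 bases inside a gBGC tract, averaged over all TSSs, hence in
[0, 1].  Deleteriousness is a **pooled variant mean**: the mean raw CADD score
over all of a class's variants in the bin across TSSs.  Bins with no elements
are missing, and missingness propagates through downstream tests.

Whole-signal CGI-vs-nCGI contrasts run a two-sample t-test per bin and combine
the 200 p-values with Fisher's method (`X = −2 Σ ln p` vs `χ²` with 2k df).
Neighboring bins are not strictly independent, so the combined p-value is an
approximation; output tables carry a note to that effect.  p-values are
clipped at 1e-300 before the log, and values below that floor are reported as
`< 1e-300` in text output.

## Region splitting

For each candidate half-width `i` from 2 to 98 the scan computes
`r_in(i)` = Pearson correlation of the gBGC fraction with the rare-common
difference over bins `|j| ≤ i`, and `r_out(i)` = correlation of the
conservation score with the same difference over `|j| > i`.  The boundary `j*`
maximizes `|r_in · r_out|`; ties resolve to the smallest `i`.  Candidates
where either correlation is undefined (constant vector, fewer than 3 complete
pairs) are skipped; if every candidate is undefined the procedure raises, and
the pipeline records the split as degenerate instead of aborting.  Because
very small windows can produce spuriously large correlations from a handful of
points, results with `|r_in(j*)| < 0.2` are flagged `weak_inner`.  The full
trace (i, r_in, r_out, |product|) is returned and serialized.

## Other tests

* **Pearson**: `t = r·√(n−2)/√(1−r²)` against Student's t with n−2 df;
  missing pairs dropped; constant vectors rejected.
* **Per-bin class ANOVA**: one-way ANOVA of per-variant deleteriousness
  scores across the four classes, per bin, Bonferroni over 200; bins with
  fewer than two populated classes are missing.
* **Wilcoxon rank-sum** (upstream vs downstream deleteriousness): exact null
  distribution for combined n ≤ 20 — by complete enumeration of group
  assignments when ties are present — otherwise the normal approximation with
  tie correction (no continuity correction, so identical samples give p = 1).
* **D'Agostino skewness** (CGI-center distances): the 1970 transformation of
  sample skewness to a standard-normal deviate, implemented directly so that
  an exactly symmetric sample maps to z = 0, p = 1; requires n ≥ 8.

## CpG-island prediction

Dinucleotides score +17 for CG and −1 otherwise (anything involving N scores
−1).  Maximal positive-sum segments are extracted greedily in score order
(equivalently: take the best segment by Kadane's scan, recurse on both sides),
with ties resolved to the smallest start, then the smallest end.  Candidate
segments become islands when GC fraction ≥ 0.5, length > 200 bp, and
observed/expected CpG > 0.6 with `expected = (#C · #G)/length`.  The greedy
extraction is verified against an exhaustive all-segments oracle in the tests.
A TSS is inside an island when its position lies in `[start, end)`; the
distance from the island center is `position − ⌊(start+end)/2⌋`, sign-flipped
for minus-strand TSSs so positive means downstream of the center.

## The synthetic generator

The generator emulates the pipeline's real inputs — TSS confidence table,
dbSNP-style variant table, CGI and gBGC BEDs, nucleosome and conservation
bedGraphs, per-variant CADD table — with planted structure:

* **Layout**: TSSs evenly spaced (≥ 10 kb apart, jittered) on configurable
  chromosomes; ~53% receive a containing CGI (300–1,500 bp, jittered so the
  TSS sits roughly centrally); optional multi-TSS clusters for the exclusion
  filter.
* **Counts**: per class, per bin, Poisson with intensity
  `baseline/200 × fold(j, class)`.  Default baselines (rare 20, mid1 22,
  mid2 22, common 31 expected variants per window) mirror the real-data scale
  of ~96 variants per 10 kb TSS window split ~21/23/24/32% across classes.
  The default fold modifier plants the observed 1.7-fold rare-class
  enrichment on bins +1..+4.
* **Allele counts**: a minor count drawn uniformly from the integer range a
  class admits out of 2·1092 chromosomes, so every generated variant passes
  the inclusion filters and MAF recomputation round-trips exactly.
* **Split structure**: two latent per-bin deviation vectors (inner: `|j| ≤ 14`
  by default; outer: the complement) are shared between the rare-class
  intensity (amplitude 0.4) and, respectively, the gBGC bin fraction and the
  conservation mean.  The amplitude is deliberately stronger than the
  correlations reported for real data so that boundary recovery is reliable at
  desk-scale sample sizes; the correlations actually planted are written to
  the truth report.
* **Tracks**: nucleosome = smooth occupancy dip at the TSS + coupling × the
  rare-intensity deviation + per-TSS noise; conservation = planted target +
  noise; gBGC coverage is deterministic per bin (rounded fraction of 50
  bases), so its profile has no sampling noise.  Tracks are emitted at 50 bp
  (bin) resolution.
* **CADD**: class mean (1.5/1.2/0.9/0.6) − 1e-4 per bp distance decay + noise,
  giving both the class gradient and the toward-TSS increase.

What the generator does **not** emulate: linkage disequilibrium between
variants, sequence-level realism (CGI prediction is tested on constructed
strings, not generator output), sub-bin track structure, chromatin-state
heterogeneity between TSSs, truncated windows at chromosome ends, and
malformed input records.  Passing tests therefore demonstrate that the
statistics recover known structure under the count model they assume, not that
real data satisfies that model.

## Problem sizes and determinism

Replicated checks use 200 uniform datasets of 2,000 TSSs (Poisson(10) variants
each) for calibration, 5,000 TSSs for planted-effect and split-boundary
recovery (20 replicates), and one end-to-end file-based run at 600 TSSs; these
sizes give the tests stable verdicts while keeping the whole suite fast on a
single CPU.  Every random quantity flows from an explicit seed
(`numpy.random.default_rng`); regenerating a bundle with the same seed yields
byte-identical files, and rerunning the pipeline on the same inputs yields
byte-identical TSVs.

## Known limitations

* The Fisher combination treats per-bin tests as independent; spatially smooth
  signals make it anti-conservative for whole-signal contrasts.
* Pooled base means weight TSSs by their scored-base counts; with very uneven
  track coverage the per-TSS mode is preferable.
* The split scan fixes the inner region to be symmetric around the TSS and
  single; asymmetric or multiple gBGC domains are out of scope.
* The per-bin CGI-vs-nCGI t-tests use per-TSS bin values; pooled per-base
  values are a defensible alternative the package does not implement.
* dbSNP-dialect TSVs, BED and bedGraph are the only supported carriers; binary
  formats (bigWig/bigBed) and VCF are out of scope.
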