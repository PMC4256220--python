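# tssvar

Profiling the distribution of human genetic variants in the 10 kb region
flanking transcription start sites (TSSs), stratified by minor-allele-frequency
(MAF) class, and relating that distribution to nucleosome occupancy,
evolutionary conservation, GC-biased gene conversion (gBGC) and variant
deleteriousness.

## The problem

The first kilobases around a TSS are both heavily regulated and heavily
mutated.  Variants of different population frequencies have different ages:
rare alleles are young and track the mutational process, common alleles are old
and track fixation forces (drift, purifying selection, gBGC).  Comparing *where*
rare and common variants sit relative to the TSS therefore separates the forces
that create variation from the forces that filter it.  `tssvar` implements that
comparison as a reusable pipeline for anyone profiling per-base genomic signals
and point variants on a TSS-anchored metagene grid.

## The statistics

Each TSS window (±5,000 bp, oriented by transcription direction) is divided
into 200 bins of 50 bp indexed `j = -100..-1, +1..+100` (no bin 0; an offset of
0 falls in bin +1).  For TSS *i* with `V(i)` variants of a class in its window
and `vars(i,j)` of them in bin *j*:

* **BVF** (bin variant frequency): `f(i,j) = vars(i,j) / V(i)` averaged over
  TSSs, so `Σ_j BVF(j) = 1` and the uniform-null expectation is `1/200` per bin.
* **Uniform-null bin test**: per bin, a paired two-sided t-test of
  `f(i,j)` against frequencies obtained by redistributing each window's `V(i)`
  variants uniformly (a simulated neutral model); 200 p-values, Bonferroni
  corrected, α = 0.001.
* **BVF-delta**: per-TSS paired difference `f_rare(i,j) − f_common(i,j)`,
  tested against 0 the same way.  Positive values mark bins where young
  variants outnumber old ones relatively — a purifying-selection signature.
* **BNP / BGS / BBS / BCS**: bin averages of nucleosome occupancy, GERP
  conservation, gBGC tract base fraction, and CADD deleteriousness.  Whole-
  signal contrasts between CGI- and nCGI-TSSs combine 200 per-bin t-tests with
  Fisher's method (`X = −2 Σ ln p ~ χ²_{2k}`).
* **Region split**: for each half-width `i = 2..98`, correlate BBS with
  BVF-delta on bins `|j| ≤ i` and BGS with BVF-delta on `|j| > i`; the chosen
  boundary `j*` maximizes `|r_in · r_out|`, separating a gBGC-dominated inner
  region from a selection-dominated outer region.

TSSs are split by CpG-island (CGI) membership; a CGI predictor scoring
dinucleotides (+17 for CG, −1 otherwise) with maximal-segment extraction and
the usual GC ≥ 50% / length > 200 bp / obs-exp CpG > 0.6 criteria is included.

## Worked example

All inputs can be generated synthetically with planted, recoverable effects —
a 1.7-fold rare-variant enrichment over the first four downstream bins, a
nucleosome↔rare-variant coupling, and an inner/outer split structure with
half-width 14 bins (700 bp):

```sh
tssvar generate --seed 7 --n-tss 400 --outdir demo/bundle
tssvar run --tss demo/bundle/tss.tsv --variants demo/bundle/variants.tsv \
    --cgi demo/bundle/cgi.bed --gbgc demo/bundle/gbgc.bed \
    --nucleosome demo/bundle/nucleosome.bedgraph --gerp demo/bundle/gerp.bedgraph \
    --cadd demo/bundle/cadd.tsv --outdir demo/results
```

prints (abridged):

```
== TSS-flanking variant analysis ==
TSSs: 400 (CGI 223, nCGI 177); variants kept: 37789 of 37789
MAF classes: rare <= 0.000459 < mid1 <= 0.0018315 < mid2 <= 0.01 < common
variant density: 0.009447 inside windows vs 2.464e-06 outside
-- nucleosome (BNP) x variant frequency (BVF) correlations --
CGI/rare: r=0.723 (t=14.7, p=1.26245e-33, n=200)
CGI/common: r=0.065 (t=0.919, p=0.35902, n=200)
nCGI/rare: r=0.737 (t=15.3, p=1.6072e-35, n=200)
BCS class ANOVA (CGI): 200 significant bins
```

Reading the numbers: the four MAF classes are bounded by the lowest observable
panel frequency (~4.59×10⁻⁴), the median of the intermediate MAFs (here
0.0018), and the canonical 0.01.  Variant density concentrates inside the
windows because the generator only plants variants there.  The planted
nucleosome coupling appears as a strong rare-class correlation (r ≈ 0.72–0.74)
that vanishes for the common class, and the planted deleteriousness gradient
makes the per-bin class ANOVA significant everywhere.  The positional bin
tests at 400 TSSs are mostly quiet — the 1.7-fold peak needs thousands of
windows to clear a Bonferroni-corrected α = 0.001, which is exactly what the
reproduction script below demonstrates.  Full per-bin tables are written as
TSV files under `demo/results/`.

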