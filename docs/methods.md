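# Methods

This note documents the models, conventions, parameters and numerical
choices behind `methlink`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate frame and data model

All analysis is anchored on the transcription start site (TSS).  A CpG's
signed offset `d` is measured in the gene's transcription orientation:
`d = pos − tss` for '+'-strand genes and `d = tss − pos` for '−'-strand
genes, so negative offsets are always the promoter side and positive
offsets the gene-body side.  Internal positions are 1-based; BED I/O is
0-based half-open; GFF3 input is converted from its 1-based inclusive
convention.  A CpG within ±10 kb of several TSSs is assigned to each gene
(multi-assignment): metagene profiles stack contributions per gene, and a
marker CpG can legitimately annotate two genes.  CpGs assigned to no gene
are intergenic and excluded.

Methylation level is `m = n_meth / (n_meth + n_unmeth)`, recomputed from
counts; the percentage column of a coverage file is treated as derived and
rounded (a deviation above 0.5 points triggers a warning, and counts win).
At zero coverage `m` is undefined (NaN), never silently 0.

Plus- and minus-strand calls of a symmetric CpG are kept distinct by
default; `destrand` merges the '−' call onto the '+' cytosine (position − 1)
by summing counts.  Merging halves the number of tests and doubles
coverage, so it is an explicit toggle rather than a silent default.

## Profiles, intervals, island classes

* Density profiles count assignments per offset bin and divide by the
  bin's inclusive width (`d_hi − d_lo + 1`).  Bins are aligned to the
  window edge (bin 0 starts at −10 kb); with 1-nt bins the bin counts sum
  exactly to the assignment count.  Whole-window "CpGs per nucleotide"
  figures use the 20,000-nt span of the ±10 kb frame (`per_nt_density`),
  matching how such censuses are conventionally printed.
* Methylation profiles average `m` over (assigned site, sample) pairs,
  unweighted, with a configurable coverage floor (default 10 reads, the
  same floor the differential filter uses).
* The methylation-interval histogram places each site by its across-sample
  unweighted mean level into ten equal-width intervals, top-closed
  ([90, 100] includes 100%).  Unweighted (rather than read-pooled) site
  means weight samples equally and are robust to coverage imbalance.
* CpG-island classification strata are [−10,−2) kb, [−2,0) kb, [0,+2] kb
  and (+2,+10] kb; an island joins a stratum through the offsets of its
  CpGs, not its interval ends, because the analysis is CpG-resolved.
  Classes: hypomethylated ≤ 44%, hypermethylated > 97%, moderate between.
  The promoter-CGI census counts islands with CpGs at [−2 kb, 0) of a TSS.

## Expression deciles and correlations

Genes are ranked ascending by mean RPKM over all samples (groups pooled;
the decile analysis is not group-stratified) with ties broken by gene id;
rank *k* of *n* maps to decile `ceil(10k/n)`, which balances decile sizes
to within one gene.  Window methylation per gene is the unweighted
(site, sample) mean within the offset window; genes with no covered CpG in
the window are excluded from correlations, not imputed — imputation would
manufacture correlation.  Correlations are gene-wise on (decile score,
window methylation) pairs, with the decile treated as numeric 1..10;
Pearson and Spearman statistics and two-sided p-values come from
`scipy.stats`.  Zero variance in either variable is flagged as undefined.

## Differential methylation

The filter cascade runs in a fixed order: (1) drop (site, sample) records
with coverage < 10; (2) per sample, drop records above that sample's
99.9th-percentile coverage (linear-interpolation quantile on the
post-step-1 coverage vector) as a PCR-duplicate guard; (3) keep sites
present in ≥ 3 surviving samples in each group.  Each step's removal count
is reported and the counts are conserved.

The test is a binomial logistic regression of methylated count on a
two-level group factor, assessed by likelihood ratio.  Because the factor
is saturated, the deviance has a closed form on the pooled counts
(`G = 2[ll(M1,U1,p̂1) + ll(M2,U2,p̂2) − ll(M,U,p̂)]`, χ²(1)), which is what
the implementation computes, vectorized over all sites; an independent
golden-section likelihood maximizer in the test suite cross-checks it to
1e-6.  The deviance is finite under complete separation, and identical
groups give G = 0, p = 1 exactly.  The group difference reported is
100·(pooled p̂₁ − pooled p̂₂) — pooled counts are the model's sufficient
statistics — with a mean-of-sample-proportions option.  q-values are
Benjamini–Hochberg (the standard, monotone choice).  Calls use strict
cuts: q < 0.01 and |difference| > 25 points.

The binomial model ignores replicate overdispersion.  On overdispersed
data its p-values are anti-conservative; the type-I error test therefore
asserts calibration only for binomial (ρ = 0) data, and the behaviour
under ρ > 0 is measured and reported, not asserted.  Overdispersion-robust
(beta-binomial) testing is deliberately out of scope.

## DM × DE integration

DM CpGs are restricted to −1 kb..+10 kb of a TSS, the region with a
plausible cis effect.  Genes must pass |fold change| > 2 and FDR < 0.1.
The FDR default is 0.1 rather than the DE screen's own 0.05 because
published marker tables of this design include rows with expression FDR up
to 9.8×10⁻²; both cuts are configuration.  Each (site, gene) pair gets a
Pearson R across samples between methylation % at the site and the gene's
RPKM — linear RPKM by default (the minimal assumption; a log2 toggle
exists), undefined below 3 common samples or at zero variance.  The
concordance flag checks that sign(meth_diff × R) equals sign(fold change).

## Synthetic-data generator

The generator produces truth-annotated data with the statistical structure
the analysis assumes, at the study's conditions: 4 samples per group, a
single chromosome, genes on alternating strands with TSSs ≥ 25 kb apart
(non-overlapping ±10 kb windows plus spacing).

| parameter | default | what it emulates |
|---|---|---|
| `baseline_meth` | 0.58 | far-from-TSS methylation plateau (~58%) |
| `tss_dip_meth` | 0.13 | methylation minimum at the TSS (~12–15%) |
| `dip_halfwidth_nt` | 1000 | width of the linear dip |
| `cpg_rate_tss` / `cpg_rate_background` | 0.015 / 0.007 | ~2-fold CpG enrichment within ±1 kb |
| `coverage_mean`, `coverage_dispersion` | 30, 8 | negative-binomial read depth, RRBS-like spread |
| `overdispersion_rho` | 0.05 | beta-binomial replicate correlation |
| `n_dm_sites`, `dm_shift` | 100, 0.35 | injected >25-point group shifts |
| `promoter_coupling` / `genebody_coupling` | −0.2 / +0.15 | methylation–expression correlations |
| `cgi_gene_fraction`, `cgi_length_nt` | 0.15, 800 | one CGI in [0,+2 kb] of ~15% of genes |

The true methylation profile is piecewise linear,
`mu(d) = dip + (baseline − dip)·min(1, |d|/halfwidth)`, clipped to
[0.02, 0.98] — the simplest shape reproducing the observed metagene curve's
three anchors (baseline, dip depth, dip width).  Counts are beta-binomial:
per (site, sample) the success probability is Beta-distributed with mean
`mu` and variance `mu(1−mu)·ρ`; coverage is `1 + NB(mean 29, size 8)`.
DM truth sites are drawn from the −1..+10 kb region (at most one per gene
while genes last) and group 2's `mu` is shifted by ±0.35, the direction
chosen so the full shift survives clipping; every truth site therefore has
a ≥ 25-point true difference.

Expression is log-normal:
`log2 RPKM = 4 + 2·(c_p·z_p + c_g·z_g + e·η) + 0.3·ε`, where `z_p`/`z_g`
are across-gene z-scores of the *realized* promoter (±1 kb) and gene-body
(+3..+10 kb) mean methylation, `e = √(1 − c_p² − c_g²)`, `η` is gene-level
noise shared across samples and `ε` per-sample noise.  The couplings are
placed on gene-level z-scores (rather than literally per sample) so that
the gene-level correlation the analysis measures equals the configured
coupling; with per-gene noise only in `ε`, sample averaging would inflate
the recovered correlation well above the configured value.  Half of the
DM-truth genes additionally receive a 2^1.5 ≈ 2.8-fold between-group
expression shift whose direction is sign(coupling)·sign(methylation
difference).  The DE table is a two-sample t-test on log2 RPKM with BH
FDR — a stand-in for an external DE caller; the pipeline consumes any
DE table with the same columns.

What the generator does **not** emulate: sequence context (no real CpG
spacing or CGI sequence composition), bisulfite conversion errors,
chromosome structure (single synthetic chromosome by default), read-level
artifacts, and any dependence of coverage on CpG density.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not fidelity to any particular genome.

## Measured operating characteristics

Under the generator's defaults (1000 genes, ρ = 0.05, 30× coverage,
4 vs 4), measured over seeds by `scripts/acceptance.py` and the test
suite:

* the ±1 kb Pearson correlation is negative and the +3..+10 kb one
  positive in 10/10 seeds, with mean |r − coupling| ≈ 0.03;
* decile-1 promoter methylation exceeds decile-10 (the published
  direction of the expression–methylation gradient);
* sensitivity for the injected 35-point shifts is ~0.85 with a false-call
  rate of ~1.3%.  This is the arithmetic of the noise budget, not a code
  defect: the per-sample proportion variance `mu(1−mu)(ρ + (1−ρ)/cov)`
  puts the 4-vs-4 group-difference SD near 10 points, so a 35-point shift
  clears the strict 25-point cut ~85% of the time, and overdispersion
  pushes ~1.3% of null sites over both cuts.  With ρ = 0 the same
  machinery achieves ≥ 90% sensitivity at ≤ 0.1% false calls (asserted in
  the unit suite), and the type-I error is calibrated at the 5% level.

## Problem sizes

The test suite simulates 40–1000 genes per run (up to ~156k CpG sites ×
8 samples ≈ 1.25M call records); the acceptance script uses 1000 genes,
10 seeds for correlation recovery and 5 for DM operating characteristics.
These sizes give stable statistics (correlation SE ≈ 0.03 at n = 1000
genes) while keeping a full run in tens of seconds.

## Known limitations

* The binomial LRT is anti-conservative under replicate overdispersion
  (see above); q-values should be read accordingly on real data.
* Multi-assignment means profile counts are per (site, gene) pair; a CpG
  near two TSSs is counted twice by design.
* The 99.9th-percentile rule with linear interpolation always trims a
  sample's strict maximum coverage record when all coverages are distinct;
  any consistent quantile definition behaves this way at the extreme.
* CGI inputs are consumed as annotation; no de novo island prediction.
* No covariate adjustment, tiling-window DM regions, or read-level
  simulation.
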