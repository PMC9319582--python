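# methlink

TSS-anchored CpG methylation profiling, per-CpG differential-methylation
testing, and methylation–expression integration for reduced-representation
bisulfite sequencing (RRBS) data, with a seeded synthetic-data generator so
the whole analysis runs and is testable without any external downloads.

## The problem

RRBS assays such as Methyl-MiniSeq report, for every covered cytosine, the
number of sequencing reads calling C (methylated) and T (unmethylated after
bisulfite conversion).  Given such call tables for two groups of samples —
for example fertile diploid (2N) versus sterile triploid (3N) female rainbow
trout, a model of muscle atrophy during sexual maturation — the questions
this package answers are:

1. **Where are the CpGs and how methylated are they relative to gene
   transcription start sites (TSS)?**  Genomes show CpG enrichment but
   methylation depletion around the TSS; the package computes signed-offset
   (±10 kb, strand-aware) density and methylation profiles, methylation-level
   histograms per offset bin, and a census and hypo/moderate/hyper
   classification of CpG-island (CGI) methylation by genic region.
2. **Does methylation track expression?**  Genes are ranked into RPKM
   deciles; window methylation (e.g. ±1 kb promoter, +3..+10 kb gene body)
   is correlated against the decile score with Pearson and Spearman
   statistics, and summarized per decile with standard errors.
3. **Which individual CpGs differ between groups, and which of them sit in
   differentially expressed genes?**  Per CpG, after a coverage/presence
   filter cascade, a binomial logistic regression with a group factor is
   tested by likelihood ratio; Benjamini–Hochberg q-values and a
   methylation-difference cut yield hyper/hypo calls, which are joined with a
   differential-expression table into an epigenetic-marker table with a
   per-sample methylation/expression correlation R for every marker.

## The statistics at the core

For a CpG site let `m_ij`, `u_ij` be methylated/unmethylated read counts in
sample *j* of group *i*.  The methylation level is `m/(m+u)` (undefined at
zero coverage).  The differential test models `m ~ Binomial(m+u, p)` with
`logit(p) = b0 + b1 * group`.  The group factor is saturated, so the MLE
under the alternative is each group's pooled proportion and under the null
the overall pooled proportion; the likelihood-ratio statistic is the
deviance (G) statistic of the pooled 2×2 table, referred to χ²(1).  It stays
finite under complete separation.  Calls require q < 0.01 (BH) **and** a
group difference of more than 25 percentage points.  Filters follow standard
RRBS practice: coverage ≥ 10 reads, below each sample's 99.9th coverage
percentile, and presence in ≥ 3 of 4 samples per group.

The synthetic generator emulates the study conditions: CpG placement at
~2-fold TSS enrichment, a piecewise-linear methylation profile
`mu(d) = dip + (baseline − dip) · min(1, |d|/1 kb)` (baseline 58%, dip 13%),
beta-binomial counts with replicate correlation ρ = 0.05 over negative-
binomial coverage (mean 30×), injected 35-point group shifts at known sites,
and log-normal RPKM coupled to realized promoter (−0.2) and gene-body
(+0.15) methylation z-scores.  See `docs/methods.md` for every assumption.

## Worked example

```python
import methlink as ml
from methlink.profiling import flag_islands

params = ml.SimulationParams(n_genes=300, seed=42)
genes, islands, calls, expr, de, truth = ml.simulate_dataset(params)

sites = calls[["chrom", "pos"]].drop_duplicates()
asn = flag_islands(ml.assign_genic(sites, genes), islands)
noni = asn[~asn["in_island"]]

deciles = ml.compute_deciles(expr)
wm = ml.window_methylation(noni, calls, -1000, 1000)
wc = ml.correlate_meth_expression(deciles, wm, region="+/-1kb")
print(f"+/-1 kb: Pearson r = {wc.pearson_r:.3f}, Spearman rho = {wc.spearman_rho:.3f}")

kept, report = ml.filter_calls(calls, params.groups)
res, counts = ml.call_dm(ml.dm_test_frame(kept, params.groups))
print(f"DM calls at q<0.01 & |diff|>25: {counts}")
hit = truth.dm_sites.merge(res, on=["chrom", "pos"])
print(f"injected shifts recovered: {(hit['call'] != 'ns').sum()} of {len(hit)}")
```

prints

```
+/-1 kb: Pearson r = -0.103, Spearman rho = -0.096
DM calls at q<0.01 & |diff|>25: {'hyper': 374, 'hypo': 376, 'ns': 46204}
injected shifts recovered: 80 of 100
```

The negative promoter correlation recovers the injected −0.2 coupling
(attenuated at this small gene count); 80 of the 100 injected 35-point
shifts clear both the q < 0.01 and the >25-point cuts — the remainder fall
short of the difference cut once replicate overdispersion is sampled, a
documented property of the binomial model on overdispersed data.

The same analysis is available as a CLI over files (Bismark coverage, BED6,
GFF3, TSV):

```bash
methlink run --seed 7 --out-dir out/       # simulate + full analysis
methlink dmtest --config cfg.yaml          # one stage from saved files
```

Every run writes a `manifest.json` of SHA-256 digests; fixed-seed runs are
digest-identical.

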