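# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `crossmeth`.

## Study design assumed by the pipeline

The pipeline targets a cross-sectional time course: a cohort of females is
split across three sampling time points (different individuals at each
time point — no within-individual repeated measures), each female
contributes one sample per tissue, and covariates are a two-level
temperature environment and a family identifier.  Methylation is measured
by RRBS-style per-CpG counts (methylated reads / total reads); genome-wide
expression comes from pooled RNA counts (two pools of three females per
time point and tissue) and candidate-gene expression from per-female
qPCR-style normalized values.  Because time points are between-individual,
every "temporal change" below is a difference of group summaries, and the
candidate-gene analysis uses an explicit all-pairs averaging scheme
rather than within-individual differences.

## Filtering and QC

Sites are kept when coverage is at least `min_cov` (default 10) in every
sample of the tissue; after computing proportions, sites that are exactly
0 in all samples or exactly 1 in all samples are removed (they cannot
change over time).  Cross-tissue analyses intersect the two tissues'
surviving site sets.

QC reports per-sample means and variances of the proportion vector
(population variance, divide-by-n, as a descriptive statistic) and tests
homogeneity across samples with rank-based k-sample tests: Kruskal-Wallis
for location, Fligner-Killeen for scale.  Samples from one tissue
typically differ significantly in both, which is the motivation for
z-scoring before cross-tissue comparison.  When all samples are
numerically identical the rank tests are degenerate; the implementation
reports statistic 0 and p = 1 instead of NaN.

## Differential methylation

**Pairwise contrasts (Δ₁,₂, Δ₂,₃).**  Counts are pooled within each
time-point group (sum methylated / sum coverage — the convention of
methylKit-style callers, not the mean of per-sample proportions).  The
test is the binomial likelihood ratio between the two group proportions
and the common pooled proportion, 1 df, p from the χ² upper tail.  The
methylation difference is reported in percentage points, later minus
earlier, so hypermethylation over time is positive.

Replicated bisulfite counts are almost always overdispersed relative to
the binomial (the generator itself produces beta-binomial counts), and
the plain likelihood-ratio test is then anti-conservative.  By default
the statistic is therefore divided by a per-site quasi-binomial scale
factor — the Pearson χ² of per-sample counts around their group
proportions over its residual degrees of freedom, floored at 1.  The
plain test is available via `overdispersion_correction=False`.  Measured
on the generator's default cohort (20,000 sites, 25 pp effects, coverage
mean 30), the correction moves the caller's empirical FDR from ~0.08 to
~0.02–0.05 and raises the cross-tissue concordance over called DMS from
~0.89 to ~0.94, at the cost of sensitivity (~0.92 → ~0.70).  The per-site
scale estimate has only ~10 residual df, which is the main source of the
sensitivity loss; this trade-off is intrinsic to quasi-likelihood
corrections at this replication level.

A site is called a DMS when |Δmethylation| ≥ 15 pp **and** the
BH-adjusted p (q-value) is ≤ 0.01, both thresholds configurable.  BH is
applied within each (tissue, contrast) run over all tested sites.
Pairwise contrasts deliberately ignore the temperature covariate.

**Omnibus time effect.**  Per site, a logit-link binomial regression is
fitted by iteratively reweighted least squares: full model intercept +
two time-point indicators + temperature indicator; null model intercept +
temperature.  The LRT has 2 df; significance at q ≤ 0.01.  IRLS uses at
most 50 iterations, relative log-likelihood tolerance 1e-8, step halving
on likelihood decrease, and clips the linear predictor at ±30 so complete
separation yields a finite deviance (the record is flagged unconverged
when the loop exhausts its budget).  With the temperature column removed
the fit reduces exactly to the closed-form three-group pooled test, which
the test suite verifies.  The omnibus test is left on the plain
likelihood scale: it feeds the quadrant analysis, where trimming and the
downstream Fisher test dominate error control.

**Tissue classification.**  Over the shared site set, a DMS in both
tissues is *tissue-general*, in exactly one *rbc_specific* /
*liver_specific*; sites significant in neither are omitted.

## Concordance of temporal change

Within a tissue, each site's proportions are standardized across samples
(site-wise mean, n−1 standard deviation); zero-variance sites are dropped
with a warning.  The per-site change for a contrast is the difference of
time-point means of z.  Concordance between tissues is the Pearson
correlation of these changes over the union of sites called DMS in at
least one tissue, with df = n − 2 and a two-sided t-based p; the same
computation is run restricted to promoter-assigned and TSS-assigned
sites.

The standardization scope is genuinely ambiguous in this design (site-
wise vs sample-wise vs grand); site-wise is the default because the
object of interest is per-site *change*, and the alternatives are
selectable (`standardize: site|sample|grand`).  Site-wise z-scores are
invariant to per-site affine rescaling of proportions, so sample-level
mean/variance heterogeneity flagged by QC does not leak into the
correlation.

## Region annotation

From gene-level models (GFF3; one TSS per gene at the annotated gene
start, no isoform resolution): TSS region = 300 bp upstream to 50 bp
downstream of the start site (a 350 bp span); promoter = 2000/200; gene
body = the full transcript span (exons and introns); 10 kb flanks
adjacent to the gene body.  "Upstream" is strand-aware (larger
coordinates for minus-strand genes); intervals are truncated at
coordinate 1.  Coordinates are 1-based inclusive internally; BED exports
are 0-based half-open.  A CpG keeps *all* of its (gene, region)
memberships — the categories overlap by construction (TSS ⊂ promoter,
promoter ∩ up10kb ≠ ∅) — with an optional priority mode (TSS > promoter >
gene body > flanks) off by default.

## Expression stand-in

The differential-expression stage is a deliberately compact
stand-in for a full RNA-seq pipeline: median-of-ratios size factors
(geometric-mean reference, factors re-centred to geometric mean 1); per
gene a method-of-moments NB2 dispersion from size-factor-normalized
counts — pooled within-time-group variance against the grand mean,
floored at 1e-8 — and a likelihood-ratio test of time-point group means
(fitted by 1-D MLE with size-factor offsets, Brent root-finding on the
score) against a common mean, 2 df.  log2 fold changes use a 0.5
pseudocount: log2((mean_b + 0.5)/(mean_a + 0.5)).  With two pools per
time point the dispersion estimate is noisy and the test is somewhat
anti-conservative near the null; it is not a calibrated DE method and the
integration stage accepts an externally produced DE table
(gene_id, p_time, q_time, log2fc_12, log2fc_23) in its place.  Genes are
carried forward when q_time < 0.05 and, when a selection-line p-value
column exists, BH-adjusted line p > 0.05.

## Integration

**Candidate genes.**  For a contrast, every later-time female's value is
differenced against every earlier-time female's value; each female keeps
the mean of her pairwise differences (later-minus-earlier orientation
throughout), giving one vector of length n_earlier + n_later per
quantity.  The mean of this vector equals the difference of time-point
means exactly.  Methylation (per CpG in the gene's TSS/promoter) and
expression vectors are correlated (Pearson); zero-variance vectors are
flagged undefined and excluded from the BH adjustment, which runs across
all (gene, site) tests of a contrast.

**Quadrants and enrichment.**  For each omnibus-significant CpG and each
time-responsive gene whose region contains it, the association's
coordinates are (Δmethylation in raw percentage points — mean proportion
×100 per time point, then differenced; *not* z-scores, which are used
only for concordance) and the gene's log2 fold change for the contrast.
Associations with |Δmeth| < 5 pp or |log2FC| < 0.5 are trimmed; the rest
are assigned Q1 (hypo, up), Q2 (hyper, up), Q3 (hyper, down), Q4 (hypo,
down).  A site contributes once per region category it belongs to.  The
enrichment test is Fisher's exact test (two-sided by default; one-sided
by flag) on the 2×2 table (TSS vs 10 kb-downstream control region) ×
(Q1∪Q3 vs Q2∪Q4); the reported odds ratio is the sample odds ratio, with
a 0.5 continuity correction (flagged) only when a cell is zero.  The 10 kb
downstream region is the control because no methylation–expression
relationship is expected there.

## Synthetic-data generator

The generator emulates the assumed design: 18 females (6 per time point,
temperature balanced 3/3 within time point, 6 families), two methylation
tissues, three expression tissues, one chromosome with non-overlapping
genes on both strands and CpG sites placed uniformly plus a guaranteed
quota per region per gene.

Methylation model (logit scale): site baseline ~ Normal(0, 1.5) —
symmetric around 0.5 with mass near both extremes, RRBS-like; a fraction
(default 0.1) of sites is temporal, each with a per-contrast shift of
±`effect_pp` (default 25 pp, random sign per contrast, clipped so
proportions stay in [0.02, 0.98]); a temporal site realizes its shift in
both tissues with probability g (`fraction_general`, default 0.3 — of the
order of the tissue-general fraction detectable in real cohorts) or in
one random tissue otherwise.  Per-sample shifts (SD 0.15) and family
effects (SD 0.1) are added on the logit scale; the temperature
environment is generated but has zero true effect by default, so the
omnibus covariate is exercised without confounding.  Coverage is negative
binomial (mean 30, size 10, floored at 1); methylated counts are
beta-binomial with intra-site correlation rho = 0.02, matching the
replicate overdispersion seen in real bisulfite data.

Expression: gene base means are log-normal around 100; a fraction
(default 0.2) of genes gets ±1 log2 time shifts; when coupling is enabled
(`coupling_k`), genes with a temporal TSS CpG (affected in the source
tissue, default RBC) instead receive per-contrast shifts of
−k × Δmethylation(pp) + Normal(0, 0.3) — the negative TSS-specific
relationship the quadrant analysis is designed to detect.  Pooled counts
are NB2 (dispersion 0.05) at 3-female aggregate means with log-normal
per-pool depth factors; candidate genes additionally get per-female
log-normal expression values to exercise the all-pairs averaging path.
A lighter association-level generator (`simulate_associations`) draws
(Δmeth, log2FC) pairs directly for the enrichment test's calibration and
power replicates.

What the generator does **not** emulate: sequence context (no reads, no
bisulfite-conversion error), linked sites (CpGs are independent given the
sample effects), selection lines, within-individual autocorrelation, and
isoform structure.  Passing recovery tests therefore show that the
statistics recover the generating model's structure at realistic noise
levels — not that the pipeline is robust to artifacts these omissions
hide.

## Evaluation sizes and outcomes

Recovery evaluations use 20,000 simulated sites (of which ~14,500 survive
the 10×-everywhere filter, mirroring the attrition real cohorts show),
5,000 sites for null calibration, 500 association-level replicates for
the enrichment null and 100 for its power.  Under fully tissue-general
effects the concordance r over called DMS exceeds 0.9, under fully
tissue-specific effects it is ~0; the caller's empirical FDR stays below
0.05 and the enrichment test rejects in 2–8% of null replicates and in
effectively all coupled replicates.  The caller's sensitivity at 25 pp
effects, coverage 30 and 6-vs-6 samples is ~0.70 with the scale
correction: at this noise level the pooled group difference has a
standard deviation of ~5–7 pp, and the BH cutoff at q ≤ 0.01 requires an
observed difference of roughly 20 pp, so substantially higher sensitivity
is not reachable by any correctly calibrated test under these conditions
— only by forgoing error control (the plain test reaches ~0.92 at
FDR ~0.08).

## Known limitations

* Between-individual time contrasts cannot separate within-individual
  change from cohort composition; the pipeline inherits this from the
  design it models.
* BH is used wherever a q-value is required; SLIM-style q-value
  estimators used by some callers would shift DMS counts.
* The omnibus IRLS test has no overdispersion correction; its calls feed
  a trimmed, Fisher-tested downstream analysis rather than being
  interpreted as calibrated discoveries.
* The NB expression test is a stand-in, not a substitute for a dedicated
  DE framework; supply an external DE table for real data.
* One TSS per gene (the annotated gene start); multi-isoform genes with
  distinct starts are not resolved.
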