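# crossmeth

Tools for asking two questions about temporal DNA methylation in a
cross-sectionally sampled cohort:

1. **Are temporal methylation changes tissue-general?**  When CpG
   methylation changes between sampling time points in an accessible
   tissue (nucleated red blood cells, RBCs), does it change in parallel in
   an inaccessible tissue (liver)?  If so, blood is a usable biomarker for
   methylation dynamics in organs that cannot be sampled repeatedly.
2. **Do methylation changes near transcription start sites track gene
   expression?**  Across defined genomic regions (TSS, promoter, gene
   body, 10 kb flanks), is an increase in CpG methylation associated with
   a decrease in the expression of the annotated gene in target tissues
   (liver, ovary, hypothalamus)?

The inputs are RRBS-style per-CpG count tables (Bismark coverage files or
wide TSV), sample metadata (female, tissue, time point 1–3, temperature
environment, family, pool), gene models (GFF3), pooled RNA counts and
per-female candidate-gene expression.  A seeded synthetic-data generator
emits the whole bundle with known ground truth, so every stage is testable
end to end.

## Methods at a glance

* **Filtering** — keep CpGs with coverage ≥ 10× in every sample of a
  tissue; drop sites with methylation proportion 0 or 1 in all samples;
  cross-tissue analyses use the site intersection.
* **Differential methylation** — per site, binomial likelihood-ratio
  tests on pooled counts: pairwise contrasts Δ₁,₂ and Δ₂,₃ (1 df, with a
  default-on quasi-binomial scale correction for replicate
  overdispersion; a DMS needs |Δmethylation| ≥ 15 pp and BH q ≤ 0.01),
  and an omnibus time-point model comparison with temperature as
  covariate (logit IRLS, 2 df, q ≤ 0.01).  DMS significant in both
  tissues are *tissue-general*, in one tissue *tissue-specific*.
* **Concordance** — per-site z-scores of methylation proportions across a
  tissue's samples; change = difference of time-point means of z; Pearson
  r (df = n − 2) between tissues over the DMS union, also restricted to
  promoter or TSS sites.
* **Regions** — strand-aware intervals per gene: TSS (300 bp upstream –
  50 bp downstream of the start site), promoter (2000/200), gene body,
  10 kb up-/downstream flanks; sites may belong to several regions and
  genes.
* **Expression** — a compact negative-binomial time-effect LRT on pooled
  counts (median-of-ratios size factors, moment dispersion), log2 fold
  changes per contrast; genes with time effect q < 0.05 (and no
  selection-line effect, when recorded) are carried forward.
* **Integration** — candidate genes: per-female average pairwise change
  in methylation vs expression, Pearson + BH.  Genome-wide: (site, gene,
  region) associations between omnibus-significant CpGs and
  time-responsive genes, trimmed at |Δmeth| ≥ 5 pp and |log2FC| ≥ 0.5,
  assigned to quadrants Q1 (hypo/up), Q2 (hyper/up), Q3 (hyper/down),
  Q4 (hypo/down); Fisher's exact test compares the Q1∪Q3 fraction in the
  TSS region against the 10 kb-downstream control region.

## Worked example

Run the full pipeline on a simulated cohort (18 females × 3 time points ×
2 tissues, 5000 CpGs, 200 genes) and print the headline statistics:

```bash
crossmeth run-all --seed 3 --out runs/demo
```

Output (abridged):

```
concordance d12/all_dms: r=0.420 df=276 p=2.49e-13
concordance d12/promoter: r=0.436 df=27 p=0.0182
concordance d12/TSS: r=0.299 df=16 p=0.229
enrichment RBC-ovary/d12: OR=0.40 p=1
...
```

With the generator's default mix (30% of temporal sites tissue-general,
the rest tissue-specific, no methylation–expression coupling), the
cross-tissue correlation over called DMS is positive but moderate
(r ≈ 0.42 here; it rises above 0.9 when all temporal sites are
tissue-general) and the TSS enrichment test is null, as expected without
coupling.  Each stage writes a TSV checkpoint (DMS tables, z-score
changes, quadrant associations, enrichment 2×2 tables) under `runs/demo/`
with a provenance header; identical config and seed reproduce identical
bytes.

The same stages are callable as a library (`crossmeth.dms`,
`crossmeth.concordance`, `crossmeth.integrate`, ...) or as individual CLI
subcommands (`simulate`, `filter`, `annotate`, `dms`, `concordance`,
`de`, `run-all`) on the TSV checkpoints.

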