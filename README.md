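# riskscreen

Pooled CRISPR screens are one of the most direct ways to find the target
genes of GWAS risk loci: instead of inferring regulation from chromatin
contacts or eQTLs, each candidate gene is activated (CRISPRa) or suppressed
(CRISPRko/CRISPRi) and the phenotype is read out directly. `riskscreen`
implements the full analytical chain for this design, aimed at breast-cancer
risk loci but generic in structure:

* **Screen statistics** — size-factor normalization against negative-control
  sgRNAs, per-sgRNA log2 fold changes of an endpoint sample against its
  reference (the plasmid DNA pool for proliferation and xenograft screens,
  the paired DMSO arm for PARP-inhibitor synthetic-lethality screens), and a
  gene-level test with an empirical null resampled from the negative
  controls, BH-adjusted per screen.
* **Directional hit classification** — the threshold |log2FC| > 1 and
  −log10(FDR) > 1 in ≥ 1 cell line, with directionality rules that assign
  oncogene, tumor-suppressor and DNA-damage-response (DDR) calls across
  modalities and assays, a supporting-only role for activation-induced
  growth inhibition, exclusion of 3D depletion, and a confound flag for
  genes sharing a bidirectional promoter with an essential gene.
* **Category enrichment** — Fisher's exact test of hit over-representation
  per prediction class (high/moderate-confidence in-silico predictions,
  TWAS/eQTL genes, background), with a known-driver downgrade sensitivity
  analysis.
* **Candidate-enhancer construction** — ATAC peaks marked by H3K27ac are
  reduced to 1-kb windows (peak center ± 500 bp), windows without a credible
  causal variant (CCV) are dropped, overlapping survivors are merged, and
  each enhancer is tiled with one perturbation position per 100 bp.
* **Single-cell enhancer-perturbation analysis (CRISPRqtl)** — cell QC
  (guide-UMI read floor, ≥ 2 guide UMIs/cell, mitochondrial and
  gene-detection filters), perturbation grouping at high MOI, a
  covariate-stratified permutation test per enhancer–gene pair in the 2-Mb
  cis window, and pair calling at p ≤ 0.1 with negative z.
* **Synthetic data** — every input (sgRNA library, negative-binomial screen
  counts with planted directional/context-dependent effects, peak/CCV
  geometry, MOI≈5 single-cell data with planted knockdowns) can be simulated
  with known ground truth, so the whole chain is testable end to end.

## The statistics in brief

For a screen contrast, guide abundances are scaled by the per-sample median
negative-control count; the gene statistic is the median over its sgRNAs of
log2((endpoint + c)/(reference + c)). Its null is the distribution of
medians of same-size draws from the negative-control guide LFCs, with
add-one empirical p-values `p = (1 + #{null ≥ obs}) / (1 + N)` in both
directions, two-sided `p = min(1, 2·min(p_enr, p_dep))`, BH-adjusted across
genes. For an enhancer–gene pair, the statistic is the difference in
library-size-normalized log1p mean expression between perturbed and
unperturbed cells; its null permutes the perturbation label within strata of
sequencing depth × mitochondrial fraction × guide count, and
`z = (obs − mean(null))/sd(null)`.

## Worked example

`examples/04_single_cell_pairs.py` simulates a 1500-cell CRISPRi experiment
over ten candidate enhancers with a planted 50% knockdown of `G0050` by
`ENH_0001`, and prints:

```
cell QC: 1500 -> 1415 cells (18 lacked guide support, 67 high-mito, 0 too few genes)

planted pair (50% knockdown):
enhancer_id gene_id          z        p  n_perturbed  called
   ENH_0001   G0050 -18.530795 0.001996          468    True

131 of 2500 evaluable pairs called (null pairs are called at ~5%: half of the
p <= 0.1 threshold, since calls also need z < 0)
TSS positive controls knocked down their own gene: 5/5
```

The planted pair is recovered with a strongly negative z at the permutation
p floor; unplanted pairs are called at the nominal background rate, and every
TSS-targeting positive control suppresses its own gene. The other examples
cover screen scoring (`01`), classification rules (`02`), enhancer
construction (`03`) and the end-to-end pipeline (`05`). A thin CLI wraps the
same functions (`riskscreen simulate|screen|classify|enrich|enhancers|qtl|run|validate`).

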