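# Methods

This note documents the models behind `riskscreen`: what each stage assumes,
which parameters matter, what the simulators do and do not emulate, and the
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Screen count model

Pooled screen counts are simulated as Gamma–Poisson (negative binomial)
draws around a deterministic expectation. The plasmid pool assigns each
sgRNA a relative representation drawn lognormal(0, σ); a sample's expected
count for guide *g* is

    depth · rel_g · 2^lfc_g / mean(rel)

where `lfc_g` is the planted fitness effect applicable to that sample's
(modality, assay, arm). Neutral guides therefore keep the design depth, and
a planted effect of +2 quadruples a guide's expected endpoint/pool ratio —
the contract the recovery tests check. Variance is `m + φ·m²` with shared
dispersion φ (φ = 0 gives Poisson).

Defaults: depth 500 reads/sgRNA, φ = 0.05, pool σ = 0.25, coverage 1000
cells/sgRNA. The emulated study reports coverage but neither sequencing
depth nor overdispersion, so depth and φ are this package's own choices at
the scale typical of well-covered screens; both are plain config fields.

Sample layout per (cell line, modality, assay): 2D and 3D produce one
endpoint each against the shared DNA pool; the xenograft arm first applies a
founder bottleneck (multinomial subsample of 10% of infected cells, a
configurable engraftment model) and runs in the MEK-activated context, so
context-dependent effects keyed to that arm appear only there; the
synthetic-lethality assay produces paired DMSO and drug arms that share the
2D growth effects, with the DDR effect applied only in the drug arm — its
contrast is drug vs DMSO, which cancels proliferation phenotypes.

Planted effect signatures: oncogenes gain fitness under activation in all
proliferation assays; tumor suppressors gain fitness under suppression and
lose 2D fitness under activation (the supporting-only signature); essentials
lose fitness under ko/i everywhere and show nothing under activation; DDR
genes deplete only in the drug arm. Under CRISPRi, guides against a gene
that shares a bidirectional promoter also carry the partner's effect — this
reproduces the promoter confound (a tumor suppressor that "dies" under
CRISPRi because its promoter partner is essential) that the classifier must
flag rather than miscall.

## Gene-level test

The gene statistic is the median sgRNA log2 fold change, tested against an
empirical null of medians of same-size with-replacement draws from the
negative-control guide LFCs. p-values use the add-one rule and count ties as
extreme, so they are never zero and never anti-conservative. The two-sided
p is `min(1, 2·min(p_enr, p_dep))`, BH-adjusted per screen — the scale that
the −log10(FDR) > 1 hit threshold consumes.

Numerical choices worth knowing:

* **Per-gene nulls.** Each gene draws its own resampled null. A single
  shared null realization would correlate p-values across genes and visibly
  distort their joint distribution (the pooled KS statistic picks up the
  shared null's finite-sample error, ~N⁻¹ᐟ²); independent nulls restore
  calibration at the cost of proportional compute.
* **p floor vs FDR.** The resampled p cannot go below 2/(N+1). After BH
  over G genes with t truly significant ones, the adjusted floor is about
  `2G/(N·t)`; with few true hits per screen this can sit just above the 0.1
  threshold. The pipeline default N = 2500 keeps the floor comfortably
  below it for the simulated study sizes.
* **Normalization scale.** Negative-control-median size factors are
  anchored so the median scaled control abundance is a fixed constant (100)
  in every sample. The anchor makes gene results exactly invariant to
  rescaling any sample's counts and keeps the 0.5 pseudocount small
  relative to typical abundances.
* **Exact mode.** For control pools small enough to enumerate, the null is
  computed by full with-replacement enumeration; the resampled p converges
  to the enumerated tail fraction as N grows (the add-one terms differ at
  small enumeration sizes, which is expected).

Screen QC checks the control contract: suppression screens must deplete
core-essential genes (median essential LFC < 0) while activation screens
need not; negative-control pseudo-genes (consecutive controls grouped in
fives) must sit within ±0.2 of zero.

## Classification

Classification is a pure function of the per-screen direction table.
Establishing rules: oncogene = activation + enrichment in 2D/3D/in-vivo;
tumor suppressor = suppression + enrichment in 2D/3D/in-vivo; DDR =
depletion in the drug-vs-DMSO contrast under any modality. Supporting-only:
activation-induced 2D depletion (a config switch restores it as
establishing, for users who prefer the literal definition) and drug-arm
enrichment (resistance). Excluded entirely: 3D depletion, because
immortalized lines cannot grow in 3D without an oncogenic insult, making
3D dropout uninformative. In-vivo enrichment is treated exactly like
proliferation enrichment, with the same thresholds. A gene may carry
several calls; lowering either threshold can only add calls, never remove
them. The bidirectional-promoter flag marks genes whose ko and i directions
oppose each other while their promoter partner is essential; calls are
flagged, never removed.

Genes in the control classes (essentials, known-driver positive controls)
are excluded from candidate summaries and from enrichment margins but kept
in QC. Enrichment uses scipy's two-sided Fisher exact test (the
minimum-likelihood convention; sidedness was not specified by the design, so
the conventional choice is used) with fold enrichment defined as the ratio
of hit rates. The driver-downgrade analysis demotes named genes from the
high- to the moderate-confidence category and re-tests; it is pure
bookkeeping on a copied annotation. For discrete exact tests "uniform under
permutation" can only mean sub-uniform: the calibration property tested is
that P(p ≤ α) never exceeds α beyond binomial error.

## Candidate enhancers

All coordinates are 0-based half-open; peak center is floor((start+end)/2)
(the convention for even-width peaks was unspecified). CCVs are treated as
single reference positions. The construction intersects 1-kb windows with
CCVs *before* merging — the order under which closely spaced CCVs produce
one long merged enhancer — with a flag for merge-then-intersect. Only
strictly overlapping windows merge (bookended windows stay separate, which
the brute-force oracle tests pin down). Tiling positions run from
start + spacing/2 every spacing bp while inside the interval; intervals
shorter than the spacing get one central position. No sequence or PAM
feasibility is modeled; positions are abstract design coordinates.

## Single-cell model and pair test

Cells receive Poisson(MOI) guides (default MOI 5) drawn uniformly from the
guide library (enhancer tiling + non-targeting + TSS-targeting positive
controls). Expression is Poisson around gene baselines (lognormal program,
σ = 0.8) scaled by a lognormal cell size factor; carrying ≥ 1 guide against
enhancer E multiplies E's target-gene mean by (1 + planted change) once,
regardless of guide multiplicity, and TSS guides apply a 90% knockdown to
their own gene. Ambient guide detections (low UMI, 1–2 reads) are planted so
the read-floor filter has real work; they have no biological effect.
Mitochondrial fraction is simulated as a per-cell covariate (Beta with mean
0.05, plus a 5% high-mito subpopulation) rather than derived from MT genes —
the QC contract needs the covariate, not the gene set. A 5% low-quality
subpopulation with ~10× fewer UMIs exercises the detection filter.

QC order matters and is fixed: guide UMIs with < 3 supporting reads are
discarded first, then cells need ≥ 2 surviving guide UMIs, mitochondrial
fraction ≤ 0.2, and ≥ 200 detected genes. The mitochondrial threshold is
deliberately prominent in config because "high mitochondrial content" was
never quantified in the emulated protocol. The filter is idempotent and the
log counts removals per criterion. (Note the detection floor is meant for
genome-scale panels; simulated panels smaller than the floor must lower it,
as the desk-scale pipeline config does.)

The pair test permutes the perturbation indicator within strata of
library-size quartile × mitochondrial half × guide-count half (4×2×2),
preserving stratum margins by construction, so depth- or load-correlated
confounding cannot create signal. The statistic is the perturbed-minus-
unperturbed difference of mean log1p(10⁴·count/total); z standardizes it
against the permutation null and p uses the add-one rule on |null| ≥ |obs|.
Degenerate nulls (constant expression) give z = 0, p = 1. Controls for an
enhancer are all QC-passing cells not perturbed for it; cells carrying only
non-targeting guides are eligible controls everywhere. The cis window is a
2-Mb halfwidth around the enhancer midpoint (the emulated description
alternates between "2 Mb from the sgRNA" and a "2-Mb window"; the halfwidth
reading is the default and the total-width variant is one config value
away). No multiple-testing correction is applied to pair p-values — pairs
are called at raw p ≤ 0.1 with z < 0, matching the interface this analysis
chain feeds — so ~5% of null pairs are called by construction; a BH option
exists but is off by default. The TSS positive-control report uses a p
bound of 0.05 by default: a permutation test with N permutations cannot
certify p < 10⁻⁴ unless N > 10⁴, so the bound is stated in the report
rather than hard-coded to a resolution the test cannot reach.

## Pipeline and reproducibility

All randomness flows from named per-stage seeds in one config document; no
global seed state. `manifest.json` holds the package version, a hash of the
analysis-relevant config (output path excluded) and sha256 checksums of
every artifact; timestamps and narrative record counts (cells removed per
rule, windows dropped, genes skipped) go to `run.log` so the manifest is
byte-identical across reruns. Externally computed gene-result or
pair-result tables in the documented TSV schemas can be supplied through the
`inputs` block and flow through classification and pair calling unchanged,
so the in-repo statistics are replaceable without touching downstream code.
The desk-scale default configuration (a few hundred candidate genes, two
cell lines, ~1500 cells) is sized so a full run takes seconds; composition
ratios, planted effect sizes, thresholds and QC rules keep the study-scale
values.

## What the simulators do not emulate

Guide-level heterogeneity in cutting/silencing efficiency, off-target
effects beyond the bidirectional-promoter device, read-level artifacts
(FASTQ, mapping, PCR jackpots beyond NB dispersion), batch effects between
lanes, UMI collisions, and real mitochondrial transcript biology. Passing
tests therefore demonstrate that the statistics are calibrated and the rules
faithfully implemented under the stated generative model — not that the
model captures every failure mode of real screens. The planted-recovery
operating points (|log2FC| = 2 with 5 sgRNAs/gene; 50% knockdown with
hundreds of perturbed cells) are strong-signal regimes; weaker effects will
show intermediate sensitivity.
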