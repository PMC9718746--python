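# Methods

## Per-cell karyotype calling

A cell is assigned to the 48,XYYY lineage when its UMI total over the Y gene
panel reaches `min_y_umi`, otherwise to 45,X. The default `min_y_umi = 1`
implements strict presence-vs-complete-absence; raising it to 2–3 trades
sensitivity for robustness when ambient Y contamination is suspected. Every
cell receives a call — there is no ambiguous class. Uncertainty is handled at
the population level instead: the zero-Y dropout rate `q` (probability that a
truly Y-bearing cell shows no Y-panel UMI) is estimated as the zero-Y fraction
of a reference in which every cell carries Y, with a Clopper–Pearson 95% CI,
and the mosaic fraction is corrected as `f_hat = min(1, f_obs / (1 - q))`.

The panel excludes pseudoautosomal (PAR1/PAR2) genes: PAR transcripts cannot
be assigned to the X or Y copy, so counting them would mis-call 45,X cells.
PAR membership is decided by ≥1 bp overlap with the GRCh38 PAR intervals
(1-based inclusive, packaged in `ymosaic/data/par_grch38.yaml`); X/Y genes
lacking coordinates are rejected rather than silently treated as non-PAR.

The correction model assumes false positives are negligible (no ambient Y) and
that the reference's Y expression matches the case's Y-bearing lineage. The
second assumption matters: a 48,XYYY cell expresses ~3× the Y output of a
normal male cell, so its dropout rate is lower. Calibrating `q` on a healthy
male reference therefore over-corrects; where possible the reference should
be dosage-matched (the test suite uses an all-XYYY simulation with the same
expression model). With realistic Y panels (~12 genes totalling tens of UMIs
per cell) `q` is near zero and the correction is a no-op; it becomes material
only for sparse panels or shallow sequencing.

## Composition test

For cell type `c`, the two-sided statistic is `T_c = |p_c - p̄|` (type's XYYY
fraction vs pooled). The null redistributes the observed genotype multiset
uniformly over cells while preserving each type's size; the per-type XYYY
counts under this null follow a multivariate hypergeometric distribution,
which is sampled directly (vectorized) rather than by materializing label
shuffles — the two procedures are distributionally identical. Implementation
details chosen for exactness:

- Statistics are compared in integer arithmetic (`|x_c·N - X·n_c|`, a positive
  rescaling of `T_c`) so permutation ties are counted exactly, with ties
  counted as extreme (conservative).
- `p = (b + 1) / (n_perm + 1)` (add-one estimator), so `p ≥ 1/(n_perm+1)` and
  the test is valid at finite `n_perm`.
- Benjamini–Hochberg step-up across cell types (via statsmodels), significance
  at FDR < 0.05 by default. Types with < 20 cells are flagged `low_n` but kept.

An exhaustive enumeration over all `C(N, X)` genotype assignments serves as
the exact oracle for instances of ≤ 12 cells, and the Monte Carlo p-values are
tested against it. Note the permutation p-values are *discrete*: with `n_c`
cells per type the two-sided tail mass jumps in steps of roughly twice the
central hypergeometric pmf, so their null distribution is super-uniform
(valid, slightly conservative) rather than exactly uniform — the test suite
checks validity at multiple levels plus empirical type-I control, not
KS-closeness to the continuous uniform, which discreteness rules out at these
sample sizes.

## Dosage ratios

Expression dosage is summarized as the pseudobulk ratio
`r = Σ_cells y-panel UMIs / Σ_cells x-panel UMIs`. Summing before dividing
makes `r` insensitive to per-cell zeros and invariant to uniform library-size
scaling; per-cell ratios (with pseudocount 1) are available for plotting only.
Comparison against reference donors is by empirical rank — the case is
"elevated" when it exceeds every reference — because a handful of reference
donors does not support a meaningful parametric test. In simulation, the
donor-to-donor variability of the random gene catalogue (a 12-gene Y panel
with log-normal weights) makes raw cross-donor ratios noisy; the dosage fold
attributable to Y copy number is isolated by comparing against a
catalogue-matched single-Y profile (same seed and weights, dosage multiplier
1), which recovers ≈3× with three Y copies.

## Differential expression

Counts are log-normalized per cell (`ln(1 + c/total · 10⁴)`, scale factor
10,000). Within each cell type, genes detected in ≥ 10% of either genotype
group are tested with a two-sided Wilcoxon rank-sum (tie-corrected normal
approximation; the standalone `rank_sum_test` switches to the exact null for
small tie-free samples and is validated against brute-force enumeration).
Bonferroni multiplies by the number of genes actually tested in that
comparison, not the whole catalogue. Log2 fold changes are computed on
de-logged group means with pseudocount 1. Comparisons where either genotype
group has < 20 cells are skipped with a warning. No fold-change threshold is
applied by default — significance is by adjusted p < 0.05 alone. Both
per-cell-type and aggregate (all cells pooled) modes are supported, since
either reading of "DE between the lineages across major immune populations"
is defensible; per-type is the default because lineage composition differs by
type and pooling would confound type effects with lineage effects.

Flagging uses a small curated list of hematological-malignancy genes
(`ymosaic/data/malignancy_genes.tsv`; TCL1A plus recurrent clonal
hematopoiesis / leukemia / lymphoma drivers). The list is a configuration
input, not a claim of completeness.

## ddPCR estimator

With Poisson partitioning, the per-droplet concentration is
`λ = -ln(1 - n⁺/n)`; the CI maps the Clopper–Pearson binomial CI through the
same transform. Wells are pooled by summing droplets per channel before
inversion (merged-well estimator, lower variance than averaging per-well λ).
The mosaic fraction is `f = (λ_AMELY / k) / λ_AMELX` with `k = 3` AMELY
copies per 48,XYYY genome and one AMELX copy per genome in both lineages;
`k = 1` reproduces naive per-allele fractions. `f` is clamped to [0,1] with
the clamping logged; all-positive channels raise a saturation error rather
than returning an unbounded λ. The fraction CI combines the channel CIs
conservatively (`[λY_lo/λX_hi, λY_hi/λX_lo] / k`).

## Synthetic-data generator

The generator emulates a mosaic PBMC sample: eight immune cell types with
realistic proportions; per-type 48,XYYY fractions defaulting to the observed
pattern (T cells ≈ 0.60 XYYY, B cells 0.30, classical monocytes 0.34, others
near 0.5; proportion-weighted global fraction 0.484); log-normal library
sizes (median 7400 UMIs, log-sd 0.35); log-normal relative gene weights
(log-sd 1.2); gamma-Poisson (negative binomial) counts with dispersion 0.3,
so dropout arises from low means rather than a separate zero-inflation knob.
Y-gene means are 0 in 45,X cells and `y_dosage_multiplier` (default 3) × a
single-copy baseline in 48,XYYY cells; X, PAR, mitochondrial and autosomal
means are lineage-invariant (both lineages carry one X; PAR genes are treated
as lineage-invariant for simplicity although a 48,XYYY cell carries extra PAR
copies — the package never uses PAR expression, so this does not affect any
estimator under test). Optional knobs, all recorded in the ground truth:
ambient Y contamination (additive Poisson spread over the Y panel — breaks
the complete-absence rule deliberately), planted low-quality cells (library
size forced to ~120 UMIs, default 64 of 3000 cells so that default QC keeps
2936), planted lineage-differential autosomal genes (`n_de_genes`, default 0,
4-fold by default, alternating direction), and `y_base_mean` to pin the
per-Y-gene single-copy mean — e.g. 0.0658 puts the three-copy lineage's
zero-Y probability near 0.1 (closed-form NB zero-probability with 12 Y genes,
dispersion 0.3), the moderate-dropout regime used in the recovery tests.

The ddPCR simulator draws per-well positives as
`Binomial(n_droplets, 1 - exp(-λ_channel))` with `λ_AMELX = λ_gdna` and
`λ_AMELY = λ_gdna · 3f`.

What the generator does **not** emulate: batch effects, doublets, cell-cycle
structure, UMI saturation, realistic gene–gene correlation, XIST biology, or
a whole-transcriptome catalogue (defaults use ~1,070 genes: 1,000 autosomal,
40 X, 12 Y, 6 PAR, 10 MT — sized so replicated studies run in seconds).
Passing tests therefore demonstrate correctness of the estimators under the
stated count model, not robustness to every artifact of real droplet data;
the ambient-Y knob exists precisely to probe the assay's known failure mode.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `numpy.random.SeedSequence`, and
rerunning with the same config reproduces `summary.json` byte for byte. The
replicated validation studies use: 200 replicates × 2,000 cells for
composition type-I error, 100 × 1,000 cells for power, 50 × 3,000 cells (plus
2,000-cell matched references) for mosaic-fraction recovery, 100 + 100
replicates × 400 cells for DE error control and spike-in recovery, 5,000
cells for dosage scaling, and 8 × 20,000 droplets for ddPCR recovery — sizes
chosen so the full suite completes in well under a minute per study on one
core while leaving Monte Carlo noise far below the tested tolerances.

## Known limitations

- Genotyping is binary by design; 46,XY or 47,XYY subclones would be folded
  into the 48,XYYY call (presence of Y), and copy-number inference from
  expression magnitude is out of scope.
- The dropout correction ignores false positives; with ambient contamination
  both error types exist and `min_y_umi ≥ 2` plus an explicit two-error model
  would be needed.
- Rank-sum DE on single cells treats cells as independent replicates
  (no pseudoreplication correction), matching standard single-cell practice.
- QC thresholds (min 200 genes, 500 UMIs, ≤10% mitochondrial) are
  conventional defaults, exposed in config.
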