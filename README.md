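# ymosaic

Single-cell quantification of sex-chromosome mosaicism from droplet scRNA-seq,
with digital-droplet-PCR cross-validation.

## The problem

An individual can carry two karyotypically distinct blood lineages — here
**45,X** (no Y chromosome) and **48,XYYY** (one X, three Y). Bulk cytogenetics
gives one overall mosaic ratio; it cannot say whether the two lineages are
evenly represented across immune cell types, which matters for hematological
risk assessment. Droplet scRNA-seq can: every cell with any Y-linked
transcript must carry a Y chromosome, and a cell with a Y chromosome almost
always shows some Y-linked expression, so presence/absence of Y-panel UMIs is
a per-cell karyotype assay.

`ymosaic` implements that assay end to end for analysts working with 10x-style
UMI matrices:

1. **Genotyping** — cell *i* is called 48,XYYY iff its UMI total over the
   non-pseudoautosomal Y gene panel satisfies `y_i >= min_y_umi` (default 1),
   else 45,X. The observed mosaic fraction `f_obs = n_XYYY / n` underestimates
   the truth by the zero-Y dropout rate `q` of truly Y-bearing cells, which is
   estimated from an all-Y-bearing reference profile and corrected as
   `f_hat = min(1, f_obs / (1 - q))`, with a bootstrap CI.
2. **Composition** — per cell type *c* with `n_c` cells and XYYY fraction
   `p_c`, the two-sided statistic `T_c = |p_c - p̄|` is referred to a Monte
   Carlo permutation null that reshuffles the genotype multiset across cells
   while preserving type sizes; `p = (b + 1) / (n_perm + 1)` with
   Benjamini–Hochberg FDR across cell types. An exhaustive-enumeration oracle
   covers small instances exactly.
3. **Dosage** — pseudobulk ratio `r = Σ y-UMIs / Σ x-UMIs` per cell group; a
   three-Y lineage should run ≈3× the ratio of a single-Y (normal male)
   profile.
4. **Differential expression** — per cell type, 45,X vs 48,XYYY on
   log-normalized counts (`ln(1 + c/total·10⁴)`), two-sided Wilcoxon rank-sum
   with Bonferroni adjustment over tested genes, plus flagging against a
   curated list of hematological-malignancy genes (TCL1A et al.).
5. **ddPCR cross-check** — from AMELX/AMELY droplet counts, Poisson-corrected
   concentrations `λ = -ln(1 - n⁺/n)` give
   `f_ddpcr = (λ_AMELY / 3) / λ_AMELX` (three AMELY copies per 48,XYYY
   genome), an orthogonal DNA-level estimate of the same fraction.
6. **Synthetic data** — a gamma-Poisson UMI simulator with two lineages,
   eight immune cell types, log-normal libraries, Y-dosage scaling, optional
   ambient Y contamination and planted low-quality/DE cells, plus a ddPCR
   droplet simulator; every downstream stage is testable against known truth
   without access to patient data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (outputs land under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_genotype_cells.py
python analysis/03_test_composition.py
python analysis/04_dosage_ratios.py
python analysis/05_differential_expression.py
python analysis/06_ddpcr_crosscheck.py
```

`02_genotype_cells.py` prints:

```
QC: kept 2936/3000 cells (median 864 genes, 7490 UMIs per cell)
45,X: 1534 cells (52.25%), 48,XYYY: 1402 cells (47.75%)
zero-Y dropout rate q = 0.0000; corrected fraction f_hat = 0.4775 (95% CI [0.459, 0.495])
```

— a near-balanced mosaic overall. `03_test_composition.py` shows the balance
breaks down inside cell types:

```
pooled 48,XYYY fraction: 0.4775
              cell_type  n_cells  n_xyyy  fraction  p_value  q_value  significant
                B cells      363      93  0.256198 0.000100 0.000200         True
           CD4+ T cells      870     504  0.579310 0.000100 0.000200         True
           CD8+ T cells      452     280  0.619469 0.000100 0.000200         True
    Classical monocytes      584     210  0.359589 0.000100 0.000200         True
        ...
4/8 cell types deviate from the pooled fraction at FDR < 0.05
```

T cells are dominated by the triple-Y lineage while B cells and monocytes are
dominated by 45,X — exactly the skew the simulator planted. The dosage stage
reports a Y/X fold of `2.965` versus a catalogue-matched single-Y profile
(three Y copies ≈ 3× Y output), and the ddPCR cross-check agrees with the
expression-based fraction at the DNA level:

```
f_ddpcr (3 Y copies/cell) = 0.4739 (95% CI 0.4669-0.4810)
scRNA-seq corrected fraction = 0.4775; |difference| = 0.0036
```

The same stages are available as a CLI (`ymosaic simulate|genotype|
composition|dosage|de|ddpcr|run|validate`); `ymosaic run --config config.yaml`
executes the full pipeline from one YAML file and writes per-stage TSV/JSON
plus a consolidated `summary.json`, all stamped with tool version, config hash
and seed.

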