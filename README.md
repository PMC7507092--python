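# thymoatlas

Chromatin-accessibility analysis of human T-cell development and T-cell acute
lymphoblastic leukemia (T-ALL), built as a tested, reusable pipeline with a
synthetic data generator carrying full ground truth.

## The scientific problem

During thymocyte maturation — DN2 → DN3 → ISP → DP(CD3−) → DP(CD3+) →
SP(CD4+)/SP(CD8+) — chromatin condenses progressively: the number of open
chromatin regions (OCRs, ATAC-seq peaks with read count ≥ 10) shrinks
monotonically. Pediatric T-ALL blasts are arrested somewhere along this
trajectory, and their arrest stage can be read from chromatin rather than
surface markers. The pipeline implements the computational machinery for this
question:

- **Peak atlas** (`peak_atlas`): BED-convention interval bookkeeping — peak
  merging, TSS/distal classification (±1 kb closed window, ≥1 bp overlap),
  accessible-peak counting, shared/cohort-specific peak partitions, and a
  length-preserving within-chromosome shuffle null for peak/annotation overlap.
- **Normalization and patterns** (`counts_norm`): median-of-ratios size
  factors; a closed-form negative-binomial variance-stabilizing transform
  (VST), `v(x) = (2/ln 2)·asinh(√(αx))`; the four-way accessibility-pattern
  rules (increasing / decreasing / fluctuating / steady, SD threshold 12,
  step threshold 24 on normalized stage means); PCA with out-of-sample
  projection and loading-based peak-importance ranking.
- **Differential testing** (`differential`): a simplified DESeq2-style NB Wald
  test — per-feature GLM with log link and known dispersion α (method of
  moments, shrunk 50/50 toward an `a₀ + a₁/μ` trend), supporting a fold-change
  threshold null (`|log2FC| > 0.5` tested directly, not filtered post hoc),
  with BH/Bonferroni adjustment.
- **Signature and deconvolution** (`signature_deconvolution`): one-vs-all
  collection of the top-LFC significant peaks per merged developmental group
  (DN2, DN3&ISP, DP, SPCD4, SPCD8), a sweep of the per-group count `n_base`
  minimizing the signature matrix condition number κ = σ_max/σ_min, CIBERSORT-
  style deconvolution (non-negative least squares on z-scored profiles; ν-SVR
  optional) returning stage fractions with correlation/RMSE fit quality, and
  leave-one-out cross-validation scored by correct rate and Cohen's kappa.
- **Motif enrichment** (`motif_enrichment`): footprint-aware TF-motif
  testing — occurrences kept only inside footprints with score > 25, motifs
  restricted to expressed TFs (FPKM > 0.5), redundant motifs (> 90% shared
  locations) collapsed, per (motif, group) 2×2 Fisher exact tests
  (motif vs all other motifs, group vs all other groups; OR = ad/bc), and
  top-TF ranking by odds-ratio spread.
- **ATAC/RNA integration** (`integration`): per-patient differential calls
  joined through TSS-distance (≤ 10 kb) peak–gene annotation, sign quadrants
  Q1 (RNA↑, ATAC↑) … Q4 (RNA↓, ATAC↑), and recurrence counted once per
  gene–patient pair per quadrant.
- **Synthetic cohorts** (`synthetic_data`): seven sorted stages × donors of NB
  peak counts with a configured pattern mix and monotone condensation;
  leukemia patients as known Dirichlet mixtures of stage profiles plus
  leukemia-specific peaks; footprinted motif occurrences with designated
  odds enrichment; RNA counts coupled to nearby peaks with designated
  dysregulated (gene, patient, quadrant) pairs. Every downstream claim is
  checked against this stored truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_signature_deconvolution.py --seed 1
python analysis/05_integration.py --seed 1
```

Output of `03_signature_deconvolution.py` (seed 1):

```
sweep chose n_base=40: 200 signature peaks, condition number 21.0
LOO cross-validation: 100% correct (35/35), Cohen's kappa 1.00
leukemia deconvolution: mean |fraction error| vs truth = 0.057
mean early-stage (DN2 + DN3.ISP) contribution: 52%
```

meaning: the sweep selected 40 peaks per group (200 after deduplication); every
one of the 35 sorted samples was re-assigned to its own merged stage when held
out; recovered leukemia stage fractions deviate from the generator's true
mixture weights by 0.057 on average; and the mean early-stage share of the
simulated leukemias is 52%. `05_integration.py` then reports the designated
DAB1-style gene as up-dysregulated (Q1) in 15/19 patients (79%) and the
CDKN2A-style silenced gene in quadrant Q3 in 17/19.

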