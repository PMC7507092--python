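# Methods

This note documents the models, numerical choices and limitations behind
`thymoatlas`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`.

## Coordinate and counting conventions

All intervals are 0-based half-open (`[start, end)`, BED convention). The
±1 kb TSS window is the *closed* genomic span `[tss − 1000, tss + 1000]`, and a
peak is TSS-proximal if it overlaps that span by at least one base; overlap
rather than midpoint or summit containment is the most common convention and
the boundary cases are pinned by tests. A peak is "accessible" in a sample
when its read count is ≥ 10 (boundary inclusive). Cohort presence for the
shared/specific peak partition means accessible in at least one sample of the
cohort.

## Size factors and the VST

Sequencing depth is corrected by median-of-ratios size factors: for sample *s*,
`f_s = median_f(count_fs / geomean_f)` over features with nonzero counts in all
samples. Factors are rescaled to unit geometric mean so that re-normalizing a
normalized matrix returns factors of exactly 1; when an external reference
profile is supplied (cross-validation folds) the raw ratios are kept so that
training and held-out samples share one scale. A `pseudo_reference` fallback
(geometric mean over nonzero entries) handles matrices without a common
nonzero feature.

The variance-stabilizing transform is the closed form for NB counts with
variance `v(μ) = μ + αμ²`:

    vst(x; α) = (2 / ln 2) · asinh(√(αx)),      vst(x; 0) = (2 / ln 2) · √x

which is finite at zero, monotone, behaves as a square-root transform at small
means, and approaches log2 differences at large counts. A single genome-wide α
(trimmed-mean of per-feature moment estimates) is used; per-feature VST is out
of scope. The transform has an exact inverse, which the deconvolution solver
uses (below).

## Accessibility patterns

Peaks are classified on their normalized stage means with the sample (n−1)
standard deviation. SD < 12 → steady. Otherwise: monotone non-decreasing with
at least one strict step → increasing; monotone non-increasing with a strict
step → decreasing; all consecutive steps within ±24 → steady; anything else →
fluctuating. The monotone classes take precedence because the quoted rules
overlap for monotone profiles with small steps; ties at SD = 12 go to the
SD ≥ 12 branch. A literal straight-line re-implementation of these rules
agrees with the vectorized version on 100% of 1,000 random profiles (test
suite). Applied to noisy per-donor data rather than true means, monotonicity
is brittle: on the default synthetic cohort about 84% of realized calls match
the generating pattern, with decreasing→fluctuating the dominant confusion.
This mirrors what the rules would do on real replicate noise and is why the
generator's *truth* labels, not re-derived calls, anchor the mix checks.

## Differential testing

The NB Wald test is deliberately a simplified DESeq2: no Cox–Reid adjustment,
no outlier handling, no independent filtering. Dispersion is method-of-moments
(`max(0, (pooled within-group variance − mean)/mean²)` on normalized counts)
averaged 50/50 with a fitted `a₀ + a₁/μ` trend; features with zero observed
variance keep α = 0. For a two-group design the GLM MLE decouples into two
intercept-only fits, solved by Newton iterations per group (vectorized across
features). Fitted group means are floored at 0.5 normalized counts: without
the floor, a group with all-zero counts drives its log-mean to −∞ with
unbounded standard error, making exactly the clearest contrasts (a peak absent
from one cohort) untestable. The Wald SE is `√(1/I_A + 1/I_B)` from the
per-group Fisher information at the (floored) fit. With `lfc_null > 0` the
statistic is `(|lfc| − lfc_null)/SE` against a standard normal — DESeq2's
threshold-null semantics, chosen over a post-hoc |lfc| filter. Calibration on
null NB data (2,000 features, 6 vs 6, α = 0.1) gives a raw-p rejection rate of
≈ 0.05–0.06 at nominal 0.05, and an injected log2 fold change of 2 is
recovered within ±0.3.

Per-patient contrasts (1–2 replicates vs a reference cohort) average the
replicates and reuse dispersions estimated from the reference cohort pooled
within its stages; a single patient cannot inform dispersion.

## Signature construction and deconvolution

One-vs-all testing (FDR 0.3, no fold-change threshold) on the five merged
groups (DN3+ISP and the two DP populations merged) collects, per group, the
`n_base` significant peaks with the largest *positive* log2 fold change —
signature peaks must be hyper-accessible in their group to serve as reference
profiles. The union is de-duplicated; reference values are per-group VST
means. A group with no significant peaks falls back to its top-LFC peaks (with
a warning) so that permuted-label cross-validation degrades to chance instead
of failing. `n_base` is chosen by sweeping a range and minimizing the matrix
2-norm condition number κ = σ_max/σ_min — the conditioning objective of
CIBERSORT-style signature optimization. Cohen's kappa, the chance-corrected
agreement `(p_o − p_e)/(1 − p_e)`, is a different κ and is reported for
cross-validation confusion matrices; both are exposed.

Deconvolution: mixing is linear on the *count* scale, while the VST is
concave, so solving least squares directly on VST profiles is biased (≈ 0.09
mean absolute fraction error even without noise). The solver therefore maps
signature and mixture back through the exact inverse VST, z-scores (signature
by its global mean/SD, mixture by its own — making the result invariant to
rescaling of the underlying mixture counts), and solves non-negative least
squares with a free-sign intercept column; weights are clipped and
renormalized to the simplex. Noise-free linear mixtures are recovered exactly;
at NB α = 0.1 the median mean-absolute error over 20 seeded cohorts (5 groups,
1,500 signature peaks, Dirichlet(1) weights) is ≈ 0.012 (bound: ≤ 0.05). A
linear ν-SVR mode (ν ∈ {0.25, 0.5, 0.75}, lowest RMSE kept) is provided for
fidelity to the CIBERSORT algorithm. Fit quality is reported as the Pearson
correlation and RMSE between the reconstruction and the (z-scored) mixture.

Leave-one-out cross-validation rebuilds the signature for every fold from the
remaining samples on the fixed joined peak set; the held-out sample's size
factor and VST use the training-fold geometric-mean reference, so the held-out
column never shapes its own reference values. A fold passes when the dominant
fraction (argmax, ties broken by column order) equals the sample's merged
group. On the default synthetic cohort (7 stages × 5 donors) the rate is
100%; with permuted labels it falls to ≈ 1/5. Fold outcomes under a single
permutation are correlated (they share the permuted signature), so the chance
check averages over several permutations rather than applying a binomial CI to
one.

## Motif enrichment

Occurrences are retained when they overlap (≥ 1 bp) a footprint scoring
strictly above 25; TFs must exceed 0.5 FPKM (strict) in the reference
expression table. Redundancy uses the containment coefficient (shared
locations / smaller set) with a strict 0.9 cutoff; connected components under
that relation keep the member with the most locations (ties: lexicographically
earlier id), and the drop map is returned for audit. The per-(motif, group)
contingency is: this motif in this group / this motif elsewhere / other motifs
in this group / other motifs elsewhere. The two-sided Fisher p uses the
minimum-likelihood criterion and matches an exhaustive hypergeometric
enumeration for every table with grand total ≤ 40 (max |Δp| ≈ 4·10⁻¹⁶).
The sample OR is ad/bc with 0.5 added to every cell only when a cell is zero
and only for the OR, never the p-value. Top-TF selection excludes motifs with
count SD < 10 across groups, then ranks significant motifs (BH-adjusted
p < 0.05 in any group) by the SD of their odds ratios.

## Integration

Peak–gene links use peak-edge-to-TSS distance with an inclusive 10 kb cutoff
(0 for overlap); a peak may link zero, one or many genes and vice versa.
Quadrants are assigned from the signs of the significant log2 fold changes;
a gene supported in one patient by peaks of both ATAC signs is counted in both
corresponding quadrants, and recurrence counts each gene–patient pair once per
quadrant regardless of supporting-peak multiplicity.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, not any
particular dataset; its distributions are configuration, not claims. Defaults
are the study's shape: 7 stages × 5 donors (35 sorted samples), 19 leukemia
patients (the first 10 with two replicates), NB dispersion α = 0.1, pattern
mix steady 0.59 / decreasing 0.29 / fluctuating 0.117 / increasing 0.003, one
gene up-dysregulated in 15/19 patients with a linked hyper-accessible peak,
and one gene silenced (counts and nearby peak zeroed) in 17/19.

Pattern trajectories are built to be unambiguous under the rules: steady peaks
are flat (mean ≈ 12–32, echoing the low mean of steady OCRs); decreasing peaks
fall geometrically from 80–260 down to 2–14, half of them steeply after the
first stage (these double as DN2 markers), and stagger their crossing of the
read-10 floor so accessible-peak totals shrink monotonically; fluctuating
peaks are a single spike (130–260 over a 36–48 baseline) at stages 2–7, with a
−26 dip before a last-stage spike to keep the profile non-monotone; increasing
peaks rise geometrically and stay above the floor. Spike positions double as
markers for the later merged groups, which is what makes the five groups
deconvolvable and the LOO check meaningful. Leukemia-specific peaks draw means
from the DN2-like high range, reflecting that leukemic chromatin is more
accessible than even the most immature sorted stage.

All randomness flows from one integer seed; `simulate_cohort` derives per-step
seeds via `numpy.random.SeedSequence`. Identical config + seed reproduces
bit-identical outputs (tested).

What the generator does *not* emulate: read-level data (no FASTQ/BAM),
fragment-size or Tn5 insertion structure, genome sequence content, donor batch
effects, GC or mappability bias, and correlated peak–peak covariance beyond
the mixture structure. Passing tests therefore demonstrate correctness of the
statistical machinery on data obeying its assumptions, not robustness to every
artifact of real ATAC-seq.

## Problem sizes

Simulated cohorts use 3,000 peaks (10,000 for the pattern-mix check), 400
genes, and 200-gene-per-chromosome genomes of 2 × 15 Mb — sizes chosen so the
whole suite and the acceptance script each run in a couple of minutes on one
CPU while keeping every statistical check well-powered. The signature sweep in
the analysis scripts runs 40–200 in steps of 10, scaled to this peak universe
(the default 300–800 range targets a genome-scale atlas).
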