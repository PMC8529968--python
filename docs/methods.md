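# Methods

## Scope and model

tmescope implements a composition-aware prognostic analysis for bulk tumor
transcriptomes. The underlying model is linear mixing: a bulk expression
profile is a non-negative combination of cell-type expression profiles,
weighted by the cell-type proportions of the sample. Downstream, per-sample
gene-set activation scores are screened for association with the estimated
proportions, and the retained sets feed a proportional-hazards risk model.

## Reference construction

Cells are kept iff the number of expressed genes lies in [200, 3000] and the
UMI total in [500, 10000], bounds inclusive (the discard rule excludes the
strict outside, so boundary cells are kept). Single-cell normalization is
`ln(1 + 10^4 · count/cell_total)`; bulk normalization is
`ln(1 + 10^6 · count/sample_total)` (CPM then natural log). A pseudocount of
1 is used inside every log transform.

Markers are selected one-vs-rest per type: the natural-log fold change is
computed on mean linear (de-logged) normalized expression with pseudocount 1;
the expressing-cell fraction must reach `min_pct` on at least one side; the
two-sided Wilcoxon rank-sum p-value (exact for tiny tie-free groups,
normal approximation otherwise) is Benjamini–Hochberg adjusted within each
type across the pre-filtered candidate genes, at a 0.05 default cutoff. Only
up-regulated genes are reported, since the purpose is a discriminative
signature. The natural-log scale for fold changes keeps the criterion
consistent with the natural-log normalization; tools that report log2 fold
changes will place the same threshold at a different numeric value.

The RGEP averages expression per type over the signature-gene union. The
default averaging scale is linear CPM, because the mixing model is linear in
expression and averaging logs would bias the basis; log-scale averaging
remains available as an option.

## Deconvolution

Per sample we minimize Σ_g w_g (y_g − Σ_t B_gt p_t)² over p ≥ 0, with gene
weights updated by iteratively reweighted least squares: residual scale is
1.4826 × MAD, and weights follow Tukey's bisquare (tuning constant 4.685;
Huber with c = 1.345 and plain NNLS are selectable). The inner solve is
non-negative least squares; the final coefficient vector is divided by its
sum so each row lies on the unit simplex. Consequences: the estimate is
invariant to a positive rescaling of the bulk sample, and a uniform scale
mismatch between bulk and reference (e.g. CPM-per-million vs per-10k) is
absorbed. A duplicated (collinear) reference column is detected up front and
reported by name. Gene overlap below 50% of the signature warns; below 2
genes it errors.

## Activation scores

Stage 1 estimates each gene's relative expression across samples with a
Gaussian kernel CDF, bandwidth sd/4 (an empirical-CDF kernel is available
for rank-only scoring). Stage 2 ranks genes within each sample by that
statistic, decreasing. Stage 3 walks the ranking: in-set genes step up
proportionally to |(p+1)/2 − rank|^tau (tau = 1 by default), out-of-set
genes step down uniformly. The reported score is the maximum positive
deviation plus the minimum negative deviation of the walk — a signed value
in [−1, 1] that is near zero when member genes are scattered, positive when
they concentrate at the top, negative at the bottom. The single
largest-magnitude-deviation convention is exposed as an alternative
(`convention="max"`); the signed-difference convention is the default
because it is symmetric under rank reversal and keeps null scores centered.
Zero-variance genes are excluded with a warning; sets are intersected with
the matrix's genes and kept when 5–2000 members survive.

## Association screen

For each gene set g and cell type C, the Pearson correlation r_gC across
samples is transformed and aggregated as z̄_g = ½ Σ_C ln((1+r_gC)/(1−r_gC)),
i.e. the sum over types of artanh(r). Correlations at |r| ≥ 1 are clipped to
1 − 1e−7 and counted. Standardization is robust:
S_g = (z̄_g − median(z)) / (1.4826 × MAD(z)), with MAD the raw median
absolute deviation of the screened population. p-values are two-sided
standard normal on |S_g| — two-sided because strongly negative aggregate
correlations are as meaningful as positive ones (a one-sided switch is
provided) — and sets with p < alpha (default 0.01) are retained. No
multiple-testing correction is applied at this stage by design; the screen
is a relative outlier criterion over the scored population.

A structural property worth knowing: because proportions sum to one, a set
whose activation tracks a single cell type necessarily anti-correlates with
the remaining types, and the signed sum over types partially cancels. The
cancellation is weakest for rare cell types (small Dirichlet concentration),
whose proportions are only weakly anti-correlated with the rest. The screen
is therefore most sensitive to sets tied to rare populations — the synthetic
end-to-end experiments couple their planted sets to rare types for exactly
this reason, and restricting the screened types to a prognostically selected
subset (see pipeline) sharpens it further.

## Survival modeling

Cox fits use Newton–Raphson on the partial likelihood with Efron tie
handling (the survival ecosystem's standard default; the data-generating
process here is continuous, so ties are incidental). LASSO-Cox fits an
L1-penalized path by coordinate descent on internally standardized features;
λ is chosen by 10-fold cross-validated partial-likelihood deviance in the
Verweij–van Houwelingen form, −2·(ll_full(β_train) − ll_train(β_train)) with
a Breslow evaluator, and "the minimizing λ" is λ_min, not λ_1se.
A grid value of exactly 0 is solved by the unpenalized Newton fit (the
λ → 0 limit of the path). Coefficients are reported on the original feature
scale. The risk model refits an unpenalized multivariate Cox on all features
selected at λ_min; its betas define the linear risk score Σ β_i x_i (no
intercept — Cox scores are relative).

The optimal cutpoint maximizes the standardized two-group log-rank statistic
|O − E|/√V over midpoints between adjacent distinct scores, subject to at
least `minprop` (default 0.1) of samples on each side. The reported p-value
of the subsequent log-rank test is not corrected for the threshold
selection; this matches the conventional reporting of maximally selected
statistics and is a known source of optimism. Kaplan–Meier curves use the
product-limit estimator; the k-group log-rank statistic is referred to
chi-square with k − 1 df; Harrell's C counts a pair concordant when the
higher score has the earlier event, ties scoring ½; AUC is the rank-based
Mann–Whitney statistic with tie correction; two-group comparisons use the
two-sided Wilcoxon rank-sum test, exact below a combined n of 20 when
tie-free.

## Synthetic data

The single-cell generator draws a shared log-normal baseline expression
profile, multiplies each type's marker block by exp(marker_logfc), and
normalizes profiles to relative abundances. Marker genes share a common
baseline value so that every type's marker block carries the same total
mass; without this, the per-type normalization constant differs and all
non-marker genes acquire a spurious composition-dependent factor in
pseudo-bulk, which would make "background" gene sets genuinely associated
with composition. Counts are gamma-Poisson (negative binomial,
var = μ + φμ²; φ = 0.3 by default, typical of UMI overdispersion) around a
per-cell library size drawn log-uniformly in [1000, 5000]. QC-failing cells
are built with ~50 total UMIs, violating both lower thresholds by
construction. Default pool geometry is 15 types × 150 cells over 2000 genes
with 25 markers per type at marker_logfc = 2.0 — a desk-scale stand-in for
a breast-tumor single-cell atlas with its immune, stromal and malignant
populations.

Pseudo-bulk mixtures follow the two-stage replaced-sampling scheme: per
sample, proportions are drawn from Dirichlet(α) (α = 1 by default — uniform
on the simplex, since no concentration is otherwise specified), a
multinomial allocates the per-sample cell draws to types, cells are drawn
uniformly with replacement within each type, and the bulk profile is the
column sum of the drawn cells' counts. The benchmark geometry is 100
samples × 10,000 cells.

Survival cohorts give each designated gene set a per-sample latent
activation a (standard normal, optionally correlated with a cell type's
true proportion at a configurable coupling); member genes are multiplied by
exp(effect_size·a); event times are exponential (Weibull shape 1) with
hazard ∝ exp(Σ β_k a_k), so proportional hazards holds exactly and Cox
recovery is well-posed; censoring is an independent exponential time with
rate calibrated to the requested censoring fraction. Pool-based cohorts add
multiplicative log-normal sample noise (σ = 0.2) on top of the pseudo-bulk,
emulating the biological sample-to-sample variability of real cohorts;
without it, the mass swing of the designated sets is the dominant source of
across-sample variation for every other gene and contaminates the null sets
of the screen.

What the generator does **not** model: doublets, ambient RNA, batch effects,
platform noise, cell-type-specific library-size differences, correlated
marker programs across types, and non-proportional hazards. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artifact of real data.

## Pipeline

The orchestrator runs simulate → reference → mixtures → deconvolution
benchmark → cohort → scoring → screen → model → stratification from one flat
YAML config. Designated prognostic sets (and the background sets of the
screen) are drawn from non-marker genes, keeping the deconvolution basis
clean and the background truly null. The proportion-based risk model is fit
first and its LASSO-selected cell types define the columns of the screen
(configurable to all types). Stage seeds derive deterministically from the
master seed; every output carries the config hash and reruns are
bit-identical. Problem sizes in the shipped demo (8 types, 1200 genes, 60
mixtures, 160-sample cohort) are chosen so the demo completes in seconds
while every stage remains statistically well-posed; the acceptance
benchmark uses the full 100 × 10,000 mixture geometry.

## Numerical choices and degenerate inputs

Robust-scale estimates of exactly 0 (perfect fits) fall back to unit
weights. All-zero deconvolution solutions raise rather than renormalize.
Correlation clipping keeps the Fisher transform finite. MAD = 0 in the
screen raises (degenerate population). Constant activation or proportion
vectors drop the affected set from aggregation with a warning. Cox fits
require ≥ 10 events and reject collinear or constant features by name;
non-convergence (e.g. perfect separation) raises with a suggestion to
penalize. Cutpoint search requires ≥ 2 distinct scores, ≥ 1 event and an
admissible split under minprop.

## Known limitations

The screen's p-values are nominal, not selection-corrected; the cutpoint
p-value is optimistic (see above); λ_min can overselect relative to λ_1se;
the activation-score null is only approximately centered for very small
sets; and the generator's marker-mass equalization, while necessary for a
clean null, removes one realistic source of compositional confounding that
real cohort analyses must handle by other means.
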