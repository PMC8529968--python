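# tmescope

Cell-type deconvolution of bulk tumor transcriptomes from a single-cell
reference, and functional gene-set prognostic modeling on top of the
estimated composition.

The package is aimed at computational biologists studying the tumor
microenvironment (TME) who want a fully testable, simulation-backed
implementation of the following analysis chain:

1. **Reference building.** From a labeled single-cell UMI count pool: QC
   filtering (cells kept iff 200 ≤ expressed genes ≤ 3000 and
   500 ≤ UMIs ≤ 10000), log-normalization `ln(1 + 10^4·c/total)`, one-vs-rest
   marker selection (natural-log fold change ≥ 0.5, min.pct ≥ 0.1, BH-adjusted
   rank-sum p), and per-type averaging of the signature-gene union into a
   **reference gene expression profile (RGEP)** — a signature-gene × cell-type
   matrix of mean linear CPM.
2. **Deconvolution.** Per bulk sample, weighted robust linear regression:
   iteratively reweighted NNLS with Tukey bisquare gene weights
   (c = 4.685), followed by sum-to-one renormalization, giving cell-type
   proportions on the unit simplex. Accuracy is scored by pooled Pearson *r*
   and RMSE against known proportions.
3. **Activation scoring.** Per-sample gene-set activation via a kernel-CDF
   rank statistic (Gaussian kernel, bandwidth sd/4) and a weighted
   Kolmogorov–Smirnov-like random walk; scores lie in [−1, 1].
4. **Association screen.** For gene set *g* and cell type *C* with Pearson
   correlation r<sub>gC</sub> across samples:

   z̄<sub>g</sub> = ½ Σ<sub>C</sub> ln((1 + r<sub>gC</sub>)/(1 − r<sub>gC</sub>)),  S<sub>g</sub> = (z̄<sub>g</sub> − median(z)) / (1.4826 × MAD(z))

   with two-sided normal p-values; sets with p < 0.01 are retained.
5. **Prognostic model.** Cross-validated LASSO-Cox selects features among the
   retained sets (λ<sub>min</sub>), a multivariate Cox refit (Efron ties) gives
   β, the risk score is the linear predictor Σ β<sub>i</sub>x<sub>i</sub>, and samples are
   stratified at the maximally selected log-rank cutpoint with Kaplan–Meier
   curves, log-rank tests, Harrell's C and rank-based AUC.

A first-class synthetic-data module generates everything the pipeline
consumes — negative-binomial single-cell pools with planted markers,
Dirichlet-proportioned pseudo-bulk mixtures built by resampling cells with
replacement, GMT gene-set collections, and survival cohorts whose hazard is
log-linear in designated gene-set activations — so every stage is testable
offline with known ground truth.

## Worked example

`examples/02_build_rgep_and_deconvolve.py` builds an 8-type reference from a
simulated pool and deconvolves 50 pseudo-bulk mixtures of 5000 cells each:

```
RGEP: 200 signature genes x 8 types
pooled Pearson r = 0.9986, RMSE = 0.0058
```

The pooled *r* is computed over all (sample, cell-type) pairs between the true
Dirichlet proportions and the estimates; at this self-mixture task the solver
recovers the composition almost exactly, and the residual RMSE (~0.6
percentage points per entry) is the multinomial sampling noise of the
mixtures themselves.

`examples/05_prognostic_model.py` runs the survival side on a simulated
cohort with two prognostic gene sets (true β = +1.0 and −0.8):

```
RANDOM_SET_00000    0.935
RANDOM_SET_00001   -0.685
C-index: 0.745
cutpoint 0.912 (96 high / 304 low), log-rank chi2 = 156.6, p = 6.37e-36
```

LASSO-Cox selects exactly the two planted sets, the refitted betas are close
to the truth, and the cutpoint split separates survival decisively.

The full chain (`examples/06_full_pipeline.py`, or
`tmescope run --config examples/demo_config.yaml`) writes every stage's
output plus a manifest with the config hash; reruns with the same seed are
bit-identical.

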