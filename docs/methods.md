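# Methods

This note documents the statistical machinery in `metprog`, the choices
made where the workflow was genuinely open, and what the synthetic
validation does and does not establish.

## Differential expression

Tumour-vs-normal comparison on FPKM-like abundances uses a two-sided
Wilcoxon rank-sum test per gene. No distributional form is assumed for
the abundances; the rank-sum test is robust to the heavy right tail of
FPKM and is the default (`method="ttest"` swaps in Welch's t for users
who prefer a parametric test). The fold change is computed on
pseudocounted group means, `log2((mean_T + c) / (mean_N + c))` with
`c = 1` (configurable); the pseudocount stabilises ratios for
low-abundance genes. A gene is called up (down) when its raw
*p* < 0.05 **and** log2 FC strictly exceeds 1 (falls below −1). Raw
p-values drive the filter; Benjamini–Hochberg adjusted values are
reported alongside for transparency but do not gate the selection.
Constant genes get *p* = 1 by definition. Gene symbols are matched
case-insensitively after trimming; collisions keep the first occurrence
and are logged.

## Random walk with restart

The network operator is the column-normalised weighted adjacency matrix,
`Y[i,j] = w(i,j) / Σ_i w(i,j)`: column normalisation makes the update
`P(l+1) = (1−b) Y P(l) + b P0` conserve probability mass. The restart
vector `P0` places exactly `1/T` on each of the `T` seed genes. Isolated
nodes produce zero columns; mass that would vanish there is teleported
back to `P0`, so `ΣP = 1` holds at every iterate even on fragmented
networks.

* **Restart probability** `b = 0.7` by default — the conventional choice
  in RWR gene prioritization; results are configurable and the solver is
  exercised at `b ∈ {0.3, 0.5, 0.7}` in the tests.
* **Stopping rule** — iterate until the L1 change falls below 1e-10,
  capped at 1e5 iterations. Because the iteration is a contraction with
  factor (1−b), the fixed point equals the closed-form stationary
  solution `b (I − (1−b) Y)⁻¹ P0`, which the package also exposes
  (`rwr_closed_form`) and uses as the test oracle; running a fixed large
  iteration count would give the same vector at more cost.
* **Ranking** — seeds are the query, not candidates, and are excluded
  from the ranked list; ties break lexicographically so rankings are
  deterministic. Default top-k is 200.
* STRING-style integer scores (0–1000] are divided by 1000 at read time;
  fractional weights pass through. Duplicate/reversed edges keep the
  maximum weight; self-loops are dropped.

## Cox models

**Univariate screening.** The Cox partial likelihood with Efron tie
handling is maximised by damped Newton–Raphson (step-halving on the
log-likelihood; convergence when the likelihood change < 1e-9 and the
gradient < 1e-6). Wald standard errors come from the observed
information. Monotone-likelihood separation is detected on the per-SD
coefficient scale (|β·sd(x)| > 30) and reported with a capped estimate
and a warning rather than a silent divergence. Genes with Wald
*p* < 0.05 (raw) pass the screen.

**Lasso-Cox.** The L1-penalized fit uses the standard IRLS + cyclic
coordinate descent scheme: a quadratic approximation of the Breslow
partial likelihood around the current linear predictor (per-sample
working weights from the diagonal of the Hessian in η), then
soft-thresholding updates on covariates standardised to unit variance,
warm-started along a 50-point log-spaced λ grid from λ_max (smallest
penalty that zeroes every coefficient) down to λ_max·10⁻³. Coefficients
are de-standardised for reporting so the printed risk formula is on the
expression scale. λ is chosen at the minimum of the 10-fold
cross-validated partial-likelihood deviance in the Verweij–Van
Houwelingen form, `−2[ll(all; β_{−k}) − ll(train_{−k}; β_{−k})]`, which
remains well defined when a single fold has few events; folds are
event-stratified and seeded. The inner loop uses Breslow ties (the
glmnet convention) while the exact Newton fits use Efron; the two
likelihoods coincide on tie-free data, which is where the λ = 0 ≡
unpenalized-Cox equivalence is asserted.

**Risk index.** `score_i = Σ_g β_g x_{g,i}`; the cohort is split at the
training-cohort median score, with scores exactly at the median assigned
to the low-risk group (a deterministic tie rule). Stratification is
invariant under any strictly increasing transform of the scores. The
pipeline feeds `log2(FPKM + 1)` into all hazard models. The pipeline is
endpoint-agnostic: `time`/`event` may encode overall survival,
progression-free interval, or any right-censored endpoint.

## Survival evaluation

Kaplan–Meier curves use the product-limit estimator with censored
subjects kept in the risk set at their own time (censoring tie-broken
after events). The two-group log-rank test accumulates observed vs
expected events with the hypergeometric variance at each distinct event
time; its chi-square (df = 1) equals the Cox score test for the binary
group covariate, an identity the tests verify numerically to 1e-8.

Time-dependent discrimination uses the cumulative-case / dynamic-control
AUC at horizon *t*: cases are subjects with an observed event by *t*,
controls those event-free past *t*, and censoring is handled by inverse
probability of censoring weights — cases weighted by 1/G(T⁻), controls
by 1/G(t), with G the Kaplan–Meier estimate of the censoring
distribution. Score ties count 1/2. Without censoring this reduces
exactly to the fraction of concordant case–control pairs, which is the
brute-force oracle in the tests. Note this IPCW estimator can differ
from nearest-neighbour-smoothed estimators used by some R packages. All
tests are two-sided.

## IHC scoring and association

Staining intensity ∈ {0, 1, 2} multiplies a staining-extent score
∈ {0, …, 4} binned from the percentage of immunoreactive cells; the
published bin labels (0, 1–5, 5–25, 25–75, >75%) overlap at 5 and 25, so
the bins are implemented half-open with inclusive upper edges —
(0, 5] → 1, (5, 25] → 2, (25, 75] → 3, > 75 → 4 — which is deterministic
and honours the top bin's "> 75%". Composite scores 0–4 are negative,
5–8 positive. Associations between marker status and clinical covariates
use the Pearson chi-square without continuity correction and without
switching to an exact test at low expected counts (low counts are
logged): this is the convention that reproduces all nine published
contingency p-values from their cell counts to four decimals. Where a
published table's marginal totals disagree with its cells, the cells are
treated as authoritative.

## Synthetic data

The generators plant known structure so recovery is checkable:

* **Expression** — gene baselines uniform on log2 ∈ [3, 8], Gaussian
  log2 noise (default SD 0.5), tumour samples of designated genes
  shifted ±`lfc_effect` (default 2) on the log2 scale; abundances are
  `2^value`, hence positive and heavy-tailed like FPKM. The default
  cohort shape (hundreds of tumours, tens of normals) mirrors a
  TCGA-plus-GTEx-style design at reduced scale.
* **Network** — Erdős–Rényi background (edge prob. 0.02) with a dense
  planted module (0.4) spanning the differential genes and the five seed
  genes; weights uniform on (0.4, 1].
* **Survival** — inverse-transform exponential proportional hazards,
  `T = −log(U) / (λ₀ · exp(xᵀβ))` with λ₀ = 0.2 events/time-unit,
  independent exponential censoring (rate 0.1) and administrative
  truncation at 15 time-units (the paperless parts of the design:
  endpoint distribution and censoring mechanism are nominal choices, not
  cohort-matched). The hazard covariate is per-gene z-scored
  `log2(x+1)`, so β is in per-SD log-hazard units; default planted
  effects are ±0.8.
* **Clinical table** — binary marker with a planted marker–exposure odds
  ratio (baseline exposure 0.3) plus independent null covariates.

The standard end-to-end experiment (`planted_prognostic_bundle`) uses
200 genes, 40 differential, 8 prognostic, 400 tumours and 60 normals and
one integer seed from which all generator seeds derive. Monte-Carlo
calibration performed while fixing these defaults: the differential
filter recovers all planted genes in every one of 200 replicate seeds,
and the planted β = 0.5 is recovered within ±0.1 at n = 1000 across 20
replicate seeds.

**What passing does not show.** The generator omits library-size
variation, count overdispersion, batch effects, correlated co-expression
modules, non-proportional hazards and informative censoring. Recovery on
planted data validates the machinery (the estimators find what is there,
at the stated effect sizes), not performance on real cohorts — planted
effects are far stronger than typical prognostic signal, which is why
the demonstration AUCs (~0.93) exceed those reported for real tumour
signatures (~0.6–0.7).

## Numerical conventions

* Determinism: every stochastic routine takes an explicit integer seed;
  the pipeline manifest hashes every output so reruns are verifiable
  byte-for-byte.
* Transition-matrix columns sum to 1 within 1e-12; probability vectors
  within 1e-9.
* Degenerate inputs fail loudly: empty gene-set intersections, constant
  covariates, all-identical risk scores, zero log-rank variance, and
  horizons with no cases or no controls are errors, not silent NaNs;
  all-censored simulations and non-converged walks warn.
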