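# Methods

## Model and procedure

The package targets the setting where a minority of genes modify the effect
of a binary treatment on a right-censored survival endpoint. Writing `r` for
the treatment indicator and `x_j` for per-gene standardized expression, the
working model is a Cox proportional-hazards model with treatment main effect
`λ`, gene main effects `b_j`, and treatment × expression interactions `i_j`:

    h(t|X) = h0(t) · exp(rλ + Σ_j x_j b_j + Σ_j r x_j i_j).

Because jointly fitting thousands of genes is not identifiable at cohort
sizes of a few hundred, the design composes **single-gene** fits: each gene
is screened with the three-column model `(r, x_j, r·x_j)` and genes are
ranked by the two-sided Wald p-value of `î_j`. A signature of the top `g`
genes scores a patient by the nominal hazard ratio

    nHR = exp(r·λ̄ + Σ_{j=1..g} (x_j b̂_j + r x_j î_j)),  evaluated at r = 1,

with `λ̄` the arithmetic mean of the `g` single-gene treatment-effect
estimates (a per-gene sum of `λ̂_j` would grow with `g`). A patient is
called treatment-sensitive when `nHR < R`, strict inequality. The score is
evaluated at `r = 1` for every patient — it is the counterfactual
"if treated" hazard ratio, which is what a benefit classifier should rank —
the actual-assignment variant is available via the `r=` argument.

Classification is cross-validated: fold-k patients are scored only by
models trained on the other K−1 folds, every patient receives exactly one
out-of-fold call, and the final evidence is a log-rank test of treated vs
untreated survival within the pooled predicted-sensitive subgroup.

## Inference caveat: the nominal validation test is anti-conservative

The final log-rank is *almost* valid under the global null: a patient's
call never uses their own outcome (a structural audit in the test suite
verifies this). It is not exactly valid, because K-fold training sets
overlap in ~(K−2)/(K−1) of their patients: each patient's outcome shapes
the coefficients and gene selection of the models that call *other*
patients, and the pooled subgroup is enriched for whatever spurious
interaction pattern drove the selection. In simulation at n = 120, 40 genes,
K = 10, g = 10, R = 0.5 under the global null, the nominal test rejects at
the 0.05 level in ≈ 11–12% of replicates (a permuted-calls control on the
same datasets sits at ≈ 5–7%, the residual being small-sample log-rank
anti-conservatism at ~40-patient subgroups). Users who need exact-level
inference should use `AdaptiveSignatureCV.permutation_pvalue`, which
permutes the treatment labels and re-runs the entire cross-validated
procedure per permutation; the nominal p-value is retained as the default
because it is what the published procedure reports.

## Tuning

`tune()` profiles the validation p-value over a `(g, R)` grid. Defaults:
`g ∈ {1..50, 60, 80, 100}` and 30 log-spaced `R` in `[0.005, 1.0]`, which
covers the published sarcoma optimum (g = 26, R = 0.035). Two methods:

- `first_fold` — train once on folds 2..K, evaluate every cell on fold 1
  (the published time-saving shortcut);
- `nested_cv` — an inner K-fold cross-validation inside each outer training
  set; the profile is the mean inner validation p across outer folds. The
  source material describes the inner loop but reports a single selected
  pair; averaging over outer folds is this package's aggregation choice —
  it uses every outer split symmetrically and keeps the returned profile a
  single surface.

Ties at the minimum prefer smaller `g` (parsimony), then larger `R`. Since
the single-gene fits do not depend on `(g, R)`, each training set is
screened once and the whole grid is evaluated from prefix sums, so tuning
costs one screen per split plus cheap log-rank evaluations.

## Survival primitives

`fit_cox` maximizes the log partial likelihood by Newton–Raphson with
step-halving, Efron (default) or Breslow tie handling, convergence when the
coefficient step falls below `tol = 1e-9`, and Wald inference from the
inverse observed information. Degenerate (constant) columns yield a flagged
fit with zero coefficients and p = 1 (callers rank such genes last);
rank-deficient designs raise a collinearity error; monotone likelihoods
(|coef| > 30 on standardized covariates) are flagged with a warning, never
silently returned. The log-rank test exposes per-group observed/expected
tables and uses the hypergeometric covariance with the chi-squared
reference on k−1 df. Kaplan–Meier bands use the Greenwood variance on the
log(−log S) scale, which keeps them inside [0, 1]. The Fisher exact test
delegates to scipy and is verified exhaustively against hypergeometric
enumeration for all 2×2 tables with total ≤ 30.

## Preprocessing

Expression filters run on raw values, max-expression rule first (genes with
max ≤ 10 removed; the boundary is included because a gene peaking exactly
at the cutoff still shows essentially no expression — the strict variant is
one flag away), then the zero-proportion rule (> 75% exact zeros, strict).
Standardization (mean 0, sample SD 1, denominator n−1) is computed once on
the full merged cohort, before any CV split, matching the published
workflow; the resulting train/test leakage is small (each patient
contributes 1/n to the per-gene moments) and is documented rather than
corrected. Missing covariates are filled by deterministic median/mode
single imputation (or rows dropped); chained-equation multiple imputation
is out of scope because covariates feed only the adjusted-Cox validation
panels, never the signature.

## Synthetic cohorts

`simulate()` draws exactly the world the design assumes: per-gene standard
normal expression (re-standardized; a log-normal marginal is available for
RNAseq-like skew), Bernoulli treatment, survival times by inverse-transform
sampling from the Cox model with an exponential (default) or Weibull
baseline, and independent exponential censoring whose rate is solved by
root-finding so the expected censored fraction hits the target (an
administrative-cutoff scheme is available). Ground truth carries each
patient's generating score `exp(λ + Σ x_j(b_j + i_j))` — the nHR at the
true coefficients, r = 1 — so classifier-vs-truth comparisons are exact
identities.

Defaults state one fixed world: n = 300 patients, 100 genes, 10 sensitive
genes with `i = −1.5`, no main effects, 30% truly sensitive patients
(threshold set at the matching quantile of the true scores), 30% treated
and 60% censored with median baseline survival 65.4 months — the treated
fraction, censoring level and median follow the real soft-tissue-sarcoma
cohort the design was developed on. These defaults emulate the *structure*
of such a cohort, not its texture: expression is independent across genes
(no co-expression blocks), censoring is independent of covariates, and
covariates (age, gender, chemotherapy, histology) are outcome-independent
nuisance columns. A green simulation test therefore establishes correctness
of the machinery under the stated model, not robustness to correlated
transcriptomes or informative censoring.

## What the stated world can and cannot deliver

Two empirical properties of the procedure, measured by the test suite in
this default world, are worth knowing before interpreting results:

- **Attenuation.** Single-gene screens omit the other sensitive genes,
  which act as strong unobserved frailty; with ten genes at `i = −1.5` the
  per-gene interaction estimates shrink to roughly −0.5 to −0.9, and
  null genes fill a substantial minority of signature slots. Out-of-fold
  nHR ranks patients with AUC ≈ 0.76–0.81 against the generating truth, so
  patient-level sensitivity and specificity cannot both exceed ≈ 0.7 at any
  threshold in this world. The nHR is a *ranking* score; its absolute scale
  is not calibrated to the generating hazard ratios.
- **Power.** With 30% treated and 60% censoring, a 90-patient predicted-
  sensitive subgroup carries only ~36 events; the within-subgroup treatment
  contrast reaches 0.05 in roughly a third of strong-signal replicates.
  Trial-like settings (50% treated, lighter censoring) behave much better.

## Numerical and design choices

- Wald (not likelihood-ratio) p-values throughout, matching the published
  single-model ranking and forest plots.
- Rank ties broken by larger |î|, then gene id — deterministic across
  platforms.
- Fold plans are stratified by treatment × event by default; every training
  complement must retain at least one event in each arm (bounded redraw,
  then a hard error).
- An empty or single-arm predicted-sensitive subgroup makes the validation
  test undefined and the signature "not effective" with a warning — tuning
  grids legitimately produce empty calls at small R, so this is not an
  exception.
- Hierarchical-clustering concordance uses Euclidean distance with complete
  linkage on the standardized signature genes (both configurable), cut at
  two groups, and reports the best label-assignment agreement.
- Strata analysis merges levels below a configurable minimum size (default
  30) into "other".

## Known limitations

No time-varying covariates, stratified baselines, frailty terms or
competing risks; no chained-equation imputation; no co-expression structure
in the generator; LOOCV only via `K = n`. The nominal validation p-value
inherits the anti-conservatism described above; the permutation test is the
remedy at ~`n_permutations ×` the cost of one cross-validated run.
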