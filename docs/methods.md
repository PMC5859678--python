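# Methods

## Model

Observed indicators for case *i* in cluster *g* follow the two-level
normal factor model

    y_gi = μ + Λ_B η_g + ε_g + Λ_W η_gi + ε_gi,

with independent normal latent factors and residuals at each level:
η_g ~ N(0, Ψ_B), ε_g ~ N(0, Θ_B), η_gi ~ N(0, Ψ_W), ε_gi ~ N(0, Θ_W).
The level covariances are Σ_L = Λ_L Ψ_L Λ_L′ + Θ_L and the total is
Σ_T = Σ_W + Σ_B. Analysis is covariance-only: means and intercept
structures are out of scope, as are equality constraints, multiple-group
analysis, categorical indicators and raw-data FIML for missing values.

Latent scales are identified with marker variables: the first indicator
listed for each factor has its loading fixed (default 1.0; settable, e.g.
0.8 to match a generating value, which only rescales Ψ and the loadings
jointly). Θ matrices are diagonal for hypothesised patterns;
cross-loadings are representable by marking any pattern entry free.

## Decomposition and MUML estimation

From sorted long-format data the package computes

* S_T = Σ Σ (y − ȳ)(y − ȳ)′ / (N − 1),
* S_PW = Σ Σ (y − ȳ_g)(y − ȳ_g)′ / (N − G),
* S_B = Σ n_g (ȳ_g − ȳ)(ȳ_g − ȳ)′ / (G − 1)  (size-weighted),
* c = (N² − Σ n_g²) / (N (G − 1)).

The size-weighted form of S_B is the one for which the exact identity
(N−1) S_T = (N−G) S_PW + (G−1) S_B holds and for which E[S_B] = Σ_W + cΣ_B;
both are enforced by tests. Two-level models minimise

    F_MUML = G·F_ML(S_B, Σ_W + cΣ_B) + (N−G)·F_ML(S_PW, Σ_W),

the weighted two-group quasi-likelihood that is exact ML in balanced
designs; one-level models minimise (N−1)·F_ML(S_T, Σ) (Wishart
convention; switchable to N). The minimised, count-weighted discrepancy is
the model chi-square directly.

Per-indicator ICCs use the moment estimates σ²_B,j = max((S_B,jj −
S_PW,jj)/c, 0) and σ²_W,j = S_PW,jj; negative raw between variances are
truncated to zero for the ICC (a variance cannot be negative) but kept
raw in the diagnostics column. The ICC is the standard variance ratio
σ²_B/(σ²_B + σ²_W); the workflow flags "multilevel modelling indicated"
when any ICC exceeds a configurable threshold (default 0.05 — literature
thresholds vary, so this is deliberately conservative and adjustable).

## Model kinds, scopes and degrees of freedom

* **CFA** — one-level pattern fitted to S_T; ignores clustering.
* **MCFA** — hypothesised patterns at both levels.
* **MAX MCFA** (maximum model) — hypothesised within pattern, saturated
  between block (all p(p+1)/2 between moments free). The saturated block
  reproduces S_B exactly, so the chi-square isolates within-level misfit.
* **PS_BETWEEN** — the mirror image: saturated within, hypothesised
  between; isolates between-level misfit.
* **SATURATED** / **INDEPENDENCE** — exact-fit and baseline references.

Degrees of freedom are moments minus free parameters; the within-specific
df of any model equals the df of the maximum model built from its within
pattern, and the between-specific df equals between moments minus between
parameters. Conventional side-by-side tabulations report the MCFA row at
the between-specific scope (its df arithmetic matches between moments
minus between parameters); the overall two-level statistics remain
available via `scope="overall"` and the choice is labelled in every
report.

## Fit statistics

* **Chi-square**: the minimised count-weighted discrepancy; p-values from
  the central chi-square (no scaled corrections).
* **RMSEA** = sqrt(max(χ² − df, 0)/(df·(N−1))) with the *total* N at every
  scope. Alternatives that use G for the between scope were considered
  and rejected: the total-N convention is the one consistent with the
  MUML chi-square's weighting and reproduces standard reported values.
* **CFI** against an independence baseline *of the same scope*: zero
  loadings with free diagonal at the scoped level, the other level
  saturated for two-level scopes. The one-level and within-specific
  baselines have closed-form optima (free variances = sample variances);
  the between-specific and overall two-level baselines are optimised
  numerically. Baseline construction is a package convention and is
  recorded here because CFI is only interpretable relative to it.
* **SRMR**: root mean square of residuals standardised by the sample
  matrix of the scoped block — S_T, S_PW (vs Σ̂_W), or S_B (vs
  Σ̂_W + cΣ̂_B, standardised by S_B diagonals, a stated convention). The
  overall two-level scope pools both blocks' standardised residuals.
* **R²** per indicator and level: (ΛΨΛ′)_jj / [(ΛΨΛ′)_jj + Θ_jj].

## Congruence diagnostics

The step-1 comparison of a CFA with the maximum model uses, for every free
within-level loading present in both:

* **relative difference** 100·(est_CFA − est_ref)/est_CFA — the
  denominator is deliberately the CFA estimate (the quantity under
  scrutiny), which differs from the usual relative-bias convention and is
  documented prominently for that reason;
* **Wald-type t** = (est₁ − est₂)/sqrt(se₁² + se₂²) with df = n₁ + n₂ − 2,
  treating the two fits as independent samples. Because both models are
  fitted to the same data this is a descriptive congruence index, not a
  formal test; no family-wise error control is applied, and the count of
  |t| > 1.96 is reported instead.

The workflow raises an incongruence flag when any |relative difference|
exceeds 10% or any |t| > 1.96.

## Numerical choices

* Free parameters are unconstrained reals: free loadings, the unique
  elements of Ψ, diagonal Θ entries, and for saturated blocks the unique
  elements of the level covariance directly.
* Start values: markers at their fixed value, free loadings 0.7, factor
  variances at half the marker indicator's sample variance (on the marker
  scale), factor covariances 0, residual variances at half the sample
  variances; saturated blocks start at their data-implied values (S_PW,
  and max((S_B − S_PW)/c, floored diagonal)).
* Optimisation: BFGS with analytic gradients
  (dF = Σ weights·tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)dΣ]), followed by full Newton steps
  using a central-difference Hessian of the analytic gradient (step
  1e-5·max(1,|θ|)). Non-positive-definite implied matrices during the
  search receive a large finite penalty so the line search backtracks.
* Convergence: gradient infinity-norm below 1e-6·max(1,|F|), or the
  Newton-predicted remaining decrease ½g′H⁻¹g below 1e-12·max(1,|F|) —
  the attainable gradient floor of a count-weighted discrepancy scales
  like sqrt(eps·F·curvature), so a pure absolute gradient test would
  spuriously fail on large samples. F never increases across accepted
  steps.
* No bounds are imposed during optimisation; admissibility is checked
  afterwards. Heywood cases (negative residual variances) and
  non-positive-semidefinite implied matrices are reported as messages,
  never clamped, mirroring classic SEM practice so the diagnostics stay
  visible.
* Standard errors: SE = sqrt(diag(2H⁻¹)) with H the numerical Hessian of
  the count-weighted discrepancy at the optimum (normal-theory
  quasi-likelihood; no sandwich correction). A non-positive-definite or
  ill-conditioned Hessian (condition number > 1e14) yields SEs reported
  as unavailable with the condition number attached.

## Missing data

Default policy is listwise deletion (clusters losing all rows are dropped
with a warning). Pairwise deletion — the convention of classic multi-group
MUML front ends — is available behind an explicit flag: each covariance
element is recomputed on the rows where both of its indicators are
observed, and the effective sample size for likelihood weighting is the
minimum pairwise complete count, a deliberately conservative choice since
no standard effective-N rule exists for pairwise matrices. Pairwise
matrices can be non-positive-semidefinite; when that happens the fit
aborts with a diagnostic rather than silently proceeding.

## Synthetic-data generator

`simulate.generate` draws from the two-level normal model above,
deterministic given a seed. Two bundled populations define the package's
study conditions:

* `benchmark_population()` — the balanced benchmark: 9 indicators, one
  within-level factor, three between-level factors of three indicators
  each, all loadings 0.80, all residual variances 0.36, unit factor
  variances, between-factor covariances 0.30, 50 clusters of 200. Every
  indicator then has unit variance at both levels and population ICC 0.5.
  The within level is exactly the published benchmark design; the
  original between level additionally carried externally specified
  cross-loadings that are not available here, so the bundled population
  uses simple structure at both levels and only within-level quantities
  (loadings, residuals, SEs, within-specific chi-square) are quantitative
  recovery targets — between-level numbers are checked qualitatively only.
* `family_iq_population()` — a synthetic, unbalanced family-IQ-style
  population (6 subtests, two within-family ability factors, one general
  family factor, ICCs ≈ 0.35–0.5, 60 families of 4–12 children) used to
  exercise the qualitative one-level-versus-multilevel contrasts:
  conflated CFA residual variances (≈ within + between components) and
  incongruent loading estimates under high ICC. It is a stand-in
  calibrated to the scale of classic family-IQ analyses, not a copy of
  any empirical dataset.

The generator emulates multivariate-normal two-level data only: no
non-normality, no missing-data mechanisms, no three-level designs, no
categorical indicators. Passing recovery tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
their violation.

## Monte-Carlo experiment sizes

The bundled recovery experiment runs 100 replications of the full
benchmark design (50×200); estimator-unbiasedness and chi-square
calibration checks use smaller designs (12×5 with 200 replications;
20×8 with 500 replications) chosen so the Monte-Carlo standard errors are
small enough for 2–3 SE assertions while keeping the default test run
quick on a single CPU.

## Known limitations

* MUML is a limited-information estimator: for unbalanced designs it is a
  quasi-likelihood using the single scalar c, not full ML; FIML
  alternatives are out of scope.
* Between-level information scales with G, so between-specific statistics
  and SEs are noisy when clusters are few; the between-specific CFI
  baseline can then be weak and the index hard to interpret.
* The Wald congruence t ignores the dependence between the two fits (both
  use the same data); it is reported as a descriptive index.
* Pairwise-deletion decompositions have no guaranteed positive
  semidefiniteness and no principled effective N; results under heavy
  missingness should be treated as screening only.
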