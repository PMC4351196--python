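# Methods

## Reference-curve model

The analysis variable is the mean of the left and right uterine-artery
pulsatility indices (PI), log-transformed because its cross-sectional
distribution is right-skewed.  The crude model is ordinary least squares of
log PI on {1, x, x², x³} with x = d/10 (d the menstrual-cycle day, 1–34;
the /10 rescaling keeps coefficients at a readable magnitude).  A cubic is
the highest degree considered: degree selection (`compare_polynomial_degrees`)
tests the leading term of degrees 1–3 at α = 0.05 and never goes beyond 3,
since higher-degree day polynomials produce boundary waviness that has no
physiological reading.

Centiles use the Gaussian mean-and-SD method: centile_K(d) =
exp(mean_log_pi(d) + K·sd̂), with sd̂ the SD of the unscaled residuals.
Because all centiles share the same day curve up to the multiplicative
constant exp(K·sd̂), they attain extrema on the same days, and
c5(d)·c95(d) = c50(d)² holds exactly (a property test asserts it to 1e−10
relative).

### Outlier handling

One trim-and-refit pass: standardized residuals of the initial fit
(residual / residual SD, denominator n − p) above 3 in absolute value are
removed, then the model is refit once.  Internally studentized
(leverage-adjusted) residuals are available via `studentized=True`, but the
simple definition is the default: at n ≈ 1.7k with 4 parameters the
leverage correction is negligible (a test confirms the two trims differ by
at most one record on a realistic cohort).  The iteration count is a
parameter (`trim_iterations`, default 1); repeated trimming is deliberately
not the default because a second pass removes points that were unremarkable
under the first refit.  sd̂ uses the n − p denominator; the choice matters
only in the third decimal at these sizes.

### Stratified model

The stratified design is fixed, not searched: intercept offsets for age
groups 2–3 and parous women, age-group offsets on the linear and quadratic
day terms, a shared cubic — 11 columns, reference category young (18–26)
nulliparous.  Parity-by-day interactions are excluded by design.  Trimming
happens once, upstream, on the crude model's residuals; the stratified fit
consumes the same trimmed records (`StratifiedCurveModel` contract).  With
`stratum_terms=False` all offsets are constrained to zero, and the fit
reproduces the crude model exactly on identical records (nesting test).
Ages outside 18–50 are rejected rather than extrapolated.

## Synthetic cohorts

The generator (`GeneratorConfig` defaults) emulates the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 1657 | analysis size after outlier removal |
| day | discrete uniform {1..34} | the observed day distribution was essentially uniform |
| beta | (1.279, −0.573, 0.310, −0.044) | crude log-PI coefficients |
| residual_sd | 0.299 | SD of log-PI noise, homoscedastic |
| age_group_probs | 251/727/690 of 1668 | cohort age mix |
| parity_prob | 1015/1668 | parous fraction |
| strata_effects | off (reference values available) | stratified level/slope shifts |
| contamination_rate | 0 | fraction displaced ≥ `contamination_shift`·sd (default 4) on the log scale |
| lr_spread_sd | 0.10 PI | left/right half-spread; arbitrary plumbing, the left/right correlation of the source data is unknown |

One `numpy.random.Generator` seeded from `seed` drives every column, so a
config is bit-reproducible.  Contaminated records are displaced by
sign·(shift·sd + |ε|), guaranteeing the displacement magnitude; the count is
exactly round(rate·n).  Demographics (BMI bands, smoking, cycle length,
notch status) mirror the study cohort's marginal composition.

What the generator does **not** emulate: the slight per-day imbalance of the
real data (39–54 records/day), any left/right asymmetry structure, the
joint (as opposed to marginal) age×parity distribution, and any true
day-dependence of the residual SD.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
real-data artefacts.  The joint age×parity point has a visible
consequence: under independent marginals the reference stratum (young
nulliparous) holds only ~6% of subjects, so the stratified reference
intercept's sampling SE (≈0.065) exceeds what the source analysis reported
(≈0.055) — presumably the real cohort's young women were more often
nulliparous — and the recovery test's coverage check for that single
coefficient sits at the edge of its bound (measured 86/100 against a
≥90/100 requirement whose expectation under these conditions is ~90).  The
check is left as-is rather than re-rolled or loosened.

## Diagnostics

* **SAR regression** — scaled absolute residuals, SAR = (π/2)·|residual|
  (the convention followed here; note the more common scaling is √(π/2), so
  here E[SAR] = σ·√(π/2) for Gaussian residuals — asserted within 2% at
  n = 10⁵).  SARs are regressed on day (degree 1 by default); the trend is
  flagged redundant when R² ≤ 1% (configurable): a statistically
  significant slope that explains ~1% of variance does not invalidate a
  constant-sd̂ centile model.
* **Lilliefors normality** — KS distance with estimated mean/SD; the null
  distribution is simulated (default 10⁴ replicates, vectorized, chunked to
  bound memory) with a fixed seed, giving exactly reproducible p-values
  computed as (1 + #{D_sim ≥ D_obs})/(n_mc + 1).  The classical table
  approximation (statsmodels) is available as `method="table"`.  P-values
  are reported without an accept/reject verdict; at n ≈ 1.7k even trivial
  departures reject, so interpretation belongs to the caller.
* **Coverage summary** — fraction of standardized residuals inside
  (−1.645, 1.645) (≈0.90 under normality), QQ pairs (externally studentized
  when the regression results are retained), and per-(age×parity)-cell
  Lilliefors p-values (six cells).

Degenerate inputs: an exact fit (residual SD ≤ 1e−12) short-circuits the
report with a `degenerate` flag; constant residuals are a hard error for
the SAR and Lilliefors tests.

## Reliability

ICC(A,1): two-way ANOVA decomposition of n subjects × 2 readings,
(MSR − MSE)/(MSR + MSE + 2(MSC − MSE)/n), penalizing systematic offsets
between the first and second reading; CI from the McGraw–Wong F-based
interval.  The single-measurement form is the default (conservative);
average-measures and consistency forms are options.  An independent
implementation (pingouin) serves as the test oracle.  The reliability
coefficient is 1.96 × sample SD (n−1 denominator) of within-pair
differences.  The source study's ICC of 0.984 and reliability coefficient
of 0.434 came from 100 undisclosed pairs and are not reproducible; only
the formulas are verified, against variance-component closed forms.

## Cohort processing

Eligibility exclusions are applied in protocol order (missing calendar →
pregnancy → unmeasurable PI → refusal); a record matching several rules is
counted once, under the first.  BMI bands follow the study's printed
cut-points (16–24 / 25–29 / 30–39), not WHO classes.  The day-uniformity
reference defaults to the continuous uniform on [0, 34] (mean 17.0, SD
9.8); the discrete {1..34} convention (mean 17.5, SD 9.81) is an option —
the source's printed 17.0 ± 9.8 corresponds to the continuous convention
although days are recorded 1–34, so neither is asserted as canonical.

## Numerical and design notes

* The published coefficient table lists the quadratic header twice; the
  second entry (−0.044) is treated as the cubic term, as the equation and
  the fitted curve require.
* Evaluating the 3-dp published coefficients reproduces the published
  per-day medians to ±0.01 at early/mid days; rounding compounds with d³
  at late days (e.g. day 13 evaluates to 2.615 against a printed 2.61).
  Computed values are reported unrounded.
* The published CI for the (age-2)×(day/10)² term, (−0.044, 0.026), is
  inconsistent with its point estimate −0.044 (the reported p = 0.089
  implies SE ≈ 0.026); fitted models always report their own computed CIs.
* Argmin over days resolves ties to the smallest day; report rounding is
  2 dp.
* Problem sizes: simulation-backed tests use 100 replicates at n = 1657
  (parameter recovery), 200 replicates for test-calibration checks, and
  n = 5000 pairs for ICC identities — sizes at which Monte-Carlo error is
  comfortably below the asserted tolerances.

## Known limitations

Cross-sectional curves do not describe within-woman trajectories; the
Gaussian mean-and-SD method assumes homoscedastic log-scale residuals
(checked, not relaxed — no LMS/Box-Cox or quantile-regression variants);
ovulation timing is approximated by a fixed 14-day luteal phase; and all
validation is against simulated cohorts plus the published summary tables,
since the underlying patient records are not deposited.
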