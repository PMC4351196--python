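"""Published reference values for the UtA-PI day-of-cycle model.

These constants are the coefficient estimates, residual scale and cohort
summaries of the reference-range study this package reimplements.  They
serve two purposes: as defaults for the synthetic-cohort generator (so
simulated cohorts have the statistical structure of the original data)
and as fixed inputs for worked examples, since the underlying per-subject
records are not publicly deposited.

All model coefficients are on the log-PI scale with cycle day rescaled to
day/10.
"""

from __future__ import annotations

# Crude cubic model of E[log PI | day]: intercept, day/10, (day/10)^2, (day/10)^3.
CRUDE_BETA: tuple[float, float, float, float] = (1.279, -0.573, 0.310, -0.044)

#: 95% confidence intervals for CRUDE_BETA, same order.
CRUDE_BETA_CI: tuple[tuple[float, float], ...] = (
    (1.214, 1.344),
    (-0.730, -0.416),
    (0.206, 0.414),
    (-0.064, -0.024),
)

#: Residual SD of log PI around the crude model (unscaled residuals).
RESIDUAL_SD: float = 0.299

#: Predicted 50th and 95th centiles of PI at cycle day 1 under the crude model.
#: Their ratio back-identifies the residual SD: ln(c95/c50)/1.6449.
DAY1_PRED_P50: float = 3.40
DAY1_PRED_P95: float = 5.55

#: Gaussian quantile for the 5th/95th centile pair.
Z_90: float = 1.6449

#: Age-group and parity stratified model coefficients with 95% CIs.
#: Reference categories: age group 1 (18-26 years) and nulliparous.
#: The (age2, day2) interval as printed is inconsistent with its point
#: estimate (an apparent misprint); the value is kept as printed here and
#: the package always reports its own computed CIs for fitted models.
STRATIFIED_COEFS: dict[str, tuple[float, tuple[float, float]]] = {
    "intercept": (1.546, (1.438, 1.654)),
    "age2": (-0.236, (-0.361, -0.110)),
    "age3": (-0.335, (-0.463, -0.206)),
    "parous": (-0.066, (-0.098, -0.034)),
    "day": (-0.792, (-0.992, -0.592)),
    "day2": (0.353, (0.244, 0.461)),
    "day3": (-0.042, (-0.062, -0.023)),
    "age2:day": (0.216, (0.041, 0.391)),
    "age3:day": (0.365, (0.188, 0.543)),
    "age2:day2": (-0.044, (-0.044, 0.026)),
    "age3:day2": (-0.091, (-0.142, -0.039)),
}

# ---------------------------------------------------------------------------
# Cohort composition (demographic table of the included women, n = 1668)
# ---------------------------------------------------------------------------

N_ELIGIBLE: int = 1821
N_INCLUDED: int = 1668
#: Exclusions in protocol order: missing menstrual calendar, pregnancy,
#: unmeasurable PI, refusal.
EXCLUSION_COUNTS: dict[str, int] = {
    "missing_calendar": 128,
    "pregnant": 11,
    "unmeasurable_pi": 10,
    "refused": 4,
}
#: Records remaining in the regression after removing 11 residual outliers.
N_ANALYSIS: int = 1657

AGE_GROUP_BOUNDS: dict[int, tuple[int, int]] = {1: (18, 26), 2: (27, 35), 3: (36, 50)}
AGE_GROUP_COUNTS: tuple[int, int, int] = (251, 727, 690)
NULLIPAROUS_COUNT: int = 653
PAROUS_COUNT: int = 1015
SMOKER_COUNT: int = 288
BMI_BAND_COUNTS: dict[str, int] = {"16-24": 1032, "25-29": 480, "30-39": 156}
BILATERAL_NOTCH_COUNT: int = 1568
ANY_NOTCH_COUNT: int = 1626  # bilateral or unilateral
MISCARRIAGE_COUNT: int = 188
PREECLAMPSIA_COUNT: int = 24

CYCLE_LENGTH_MEAN: float = 28.8
CYCLE_LENGTH_SD: float = 4.2
PERIOD_LENGTH_MEAN: float = 5.0
PERIOD_LENGTH_SD: float = 1.7
MENARCHE_AGE_MEAN: float = 12.1
MENARCHE_AGE_SD: float = 1.17

#: Day-of-cycle empirical summary of the source cohort vs the uniform reference.
DAY_MEAN_OBSERVED: float = 17.3
DAY_SD_OBSERVED: float = 9.7
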