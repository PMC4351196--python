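"""Age-group and parity stratified UtA-PI centile curves.

Extends the crude cubic log-PI model with stratum structure:

    E[log PI | d, a, p] = b0(a, p) + b1(a) (d/10) + b2(a) (d/10)^2 + b3 (d/10)^3

The intercept depends on age group (1: 18-26, 2: 27-35, 3: 36-50 years) and
parity (nulliparous vs parous); the linear and quadratic day terms depend on
age group only; the cubic term is shared.  Reference categories are the
youngest age group and nulliparous women, and no parity-by-day interactions
are included (none were significant in the source analysis).

The design is fixed (11 columns) rather than searched: this module
reproduces the selected model, not a model-selection procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import published
from .reference import DEFAULT_DAYS, Z_90

COEF_NAMES = [
    "intercept",
    "age2",
    "age3",
    "parous",
    "day",
    "day2",
    "day3",
    "age2:day",
    "age3:day",
    "age2:day2",
    "age3:day2",
]

AGE_GROUP_BOUNDS = published.AGE_GROUP_BOUNDS


class StratificationError(ValueError):
    """A required age-group/parity cell is empty or a label is unknown."""


def age_to_group(age_years: float) -> int:
    """Map age in years to age group 1/2/3; ages outside 18-50 are rejected."""
    for group, (lo, hi) in AGE_GROUP_BOUNDS.items():
        if lo <= age_years <= hi:
            return group
    raise ValueError(f"age {age_years} outside the supported range 18-50")


def _parous_indicator(parity) -> np.ndarray:
    arr = np.asarray(parity)
    if arr.dtype.kind in "biu":
        return arr.astype(bool)
    out = np.empty(arr.size, dtype=bool)
    for i, v in enumerate(arr.reshape(-1)):
        s = str(v).strip().lower()
        if s in {"parous", "1", "true"}:
            out[i] = True
        elif s in {"nulliparous", "0", "false"}:
            out[i] = False
        else:
            raise StratificationError(f"unknown parity label: {v!r}")
    return out


def _stratified_design(days, age_group, parous, day_scale: float) -> np.ndarray:
    x = np.asarray(days, dtype=float) / day_scale
    a2 = (np.asarray(age_group) == 2).astype(float)
    a3 = (np.asarray(age_group) == 3).astype(float)
    par = np.asarray(parous, dtype=float)
    cols = [
        np.ones_like(x), a2, a3, par,
        x, x**2, x**3,
        a2 * x, a3 * x, a2 * x**2, a3 * x**2,
    ]
    return np.column_stack(cols)


class StratifiedCurveModel(BaseEstimator):
    """Least-squares fit of the stratified log-PI model.

    Expects the record set to be trimmed upstream (the crude model's
    outlier pass): both models are fitted on the same trimmed records.

    Setting ``stratum_terms=False`` constrains every stratum offset to zero,
    which reduces the design to the crude cubic: on identical records the
    day-term coefficients then reproduce the crude fit exactly (the crude
    model is nested in this one).

    Attributes
    ----------
    params_ : pandas.Series indexed by COEF_NAMES
    conf_int_ : DataFrame with columns ``low``/``high`` (95%)
    residual_sd_ : SD of the unscaled residuals (denominator n - p)
    n_used_ : number of records fitted
    """

    _CRUDE_COLS = [0, 4, 5, 6]  # intercept and day polynomial columns

    def __init__(self, day_scale: float = 10.0, stratum_terms: bool = True):
        self.day_scale = day_scale
        self.stratum_terms = stratum_terms

    def fit(self, X: pd.DataFrame, y=None):
        """Fit from a DataFrame with cycle_day, age_group, parity (+ pi_mean).

        ``y`` may give the PI values explicitly; otherwise the ``pi_mean``
        column is used.
        """
        df = X
        pi = np.asarray(df["pi_mean"] if y is None else y, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("PI values must be strictly positive")
        days = np.asarray(df["cycle_day"], dtype=float)
        age_group = np.asarray(df["age_group"], dtype=int)
        if not set(np.unique(age_group)) <= {1, 2, 3}:
            raise StratificationError("age_group must take values 1, 2, 3")
        parous = _parous_indicator(df["parity"].to_numpy())

        if self.stratum_terms:
            for g in (1, 2, 3):
                for p, lab in ((False, "nulliparous"), (True, "parous")):
                    if not np.any((age_group == g) & (parous == p)):
                        raise StratificationError(
                            f"empty stratum: age group {g}, {lab}"
                        )

        design = _stratified_design(days, age_group, parous, self.day_scale)
        if not self.stratum_terms:
            design = design[:, self._CRUDE_COLS]
        res = sm.OLS(np.log(pi), design).fit()
        self.result_ = res
        params = np.zeros(len(COEF_NAMES))
        ci = np.zeros((len(COEF_NAMES), 2))
        pvals = np.full(len(COEF_NAMES), np.nan)
        cols = self._CRUDE_COLS if not self.stratum_terms else range(len(COEF_NAMES))
        params[list(cols)] = np.asarray(res.params)
        ci[list(cols)] = np.asarray(res.conf_int(alpha=0.05))
        pvals[list(cols)] = np.asarray(res.pvalues)
        self.params_ = pd.Series(params, index=COEF_NAMES)
        self.conf_int_ = pd.DataFrame(ci, index=COEF_NAMES, columns=["low", "high"])
        self.p_values_ = pd.Series(pvals, index=COEF_NAMES)
        dof = res.nobs - design.shape[1]
        self.residual_sd_ = (
            float(np.sqrt(np.sum(res.resid**2) / dof)) if dof > 0 else 0.0
        )
        self.n_used_ = int(res.nobs)
        return self

    @classmethod
    def from_coefficients(
        cls, coefficients: dict[str, float], residual_sd: float,
        day_scale: float = 10.0,
    ) -> "StratifiedCurveModel":
        """Build a model from a name->value mapping (e.g. a published table)."""
        missing = set(COEF_NAMES) - set(coefficients)
        if missing:
            raise ValueError(f"missing coefficients: {sorted(missing)}")
        model = cls(day_scale=day_scale)
        model.params_ = pd.Series(
            [float(coefficients[k]) for k in COEF_NAMES], index=COEF_NAMES
        )
        model.conf_int_ = pd.DataFrame(
            {"low": model.params_, "high": model.params_}
        )
        model.residual_sd_ = float(residual_sd)
        model.n_used_ = 0
        return model

    # ------------------------------------------------------------- curves

    def _check_stratum(self, age_group: int, parity) -> tuple[int, bool]:
        if age_group not in (1, 2, 3):
            raise StratificationError(f"unknown age group: {age_group!r}")
        return age_group, bool(_parous_indicator([parity])[0])

    def mean_log_pi(self, days, age_group: int, parity) -> np.ndarray:
        check_is_fitted(self, "params_")
        g, par = self._check_stratum(age_group, parity)
        days = np.asarray(days, dtype=float).reshape(-1)
        design = _stratified_design(
            days, np.full(days.size, g), np.full(days.size, par), self.day_scale
        )
        return design @ self.params_.to_numpy()

    def centile_curve(
        self, age_group: int, parity, K: float = 0.0, days=DEFAULT_DAYS
    ) -> np.ndarray:
        """exp(stratum mean polynomial + K * residual_sd) over the given days."""
        return np.exp(self.mean_log_pi(days, age_group, parity)
                      + K * self.residual_sd_)

    def stratum_extrema(self, age_group: int, parity, days=DEFAULT_DAYS) -> dict:
        """Argmin day (ties -> smallest) and flatness (max - min) of the median curve."""
        days = np.asarray(days)
        curve = self.centile_curve(age_group, parity, K=0.0, days=days)
        i = int(np.argmin(curve))
        return {
            "argmin_day": int(days[i]),
            "min_value": float(curve[i]),
            "range": float(curve.max() - curve.min()),
        }

    def centile_tables(
        self, days=DEFAULT_DAYS, K_values=(-Z_90, 0.0, Z_90)
    ) -> pd.DataFrame:
        """Long-format table keyed by (age_group, parity, day, centile)."""
        check_is_fitted(self, "params_")
        frames = []
        labels = {K_values[0]: "p5", K_values[1]: "p50", K_values[2]: "p95"}
        for g in (1, 2, 3):
            for parity in ("nulliparous", "parous"):
                for K, lab in labels.items():
                    frames.append(pd.DataFrame({
                        "age_group": g,
                        "parity": parity,
                        "day": np.asarray(days),
                        "centile": lab,
                        "pi": self.centile_curve(g, parity, K, days),
                    }))
        return pd.concat(frames, ignore_index=True)

    def coefficient_table(self) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        return pd.DataFrame({
            "coefficient": COEF_NAMES,
            "estimate": self.params_.to_numpy(),
            "ci_low": self.conf_int_["low"].to_numpy(),
            "ci_high": self.conf_int_["high"].to_numpy(),
        })


def fit_stratified_model(records: pd.DataFrame, **kwargs) -> StratifiedCurveModel:
    """Fit the stratified model from a (pre-trimmed) cohort DataFrame."""
    return StratifiedCurveModel(**kwargs).fit(records)
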