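"""Crude day-of-cycle reference-curve model for the UtA pulsatility index.

The model is ordinary least squares of log(PI) on a cubic polynomial in
day/10:

    E[log PI | d] = b0 + b1 (d/10) + b2 (d/10)^2 + b3 (d/10)^3

Centile curves follow the Gaussian mean-and-SD method:

    centile_K(d) = exp(mean_log_pi(d) + K * sd)

with K a standard-normal quantile (K = ±1.6449 for the 5th/95th) and sd
the SD of the unscaled residuals.  One trim-and-refit pass removes gross
outliers with |standardized residual| above a threshold (default 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import published

Z_90 = published.Z_90
DEFAULT_DAYS = np.arange(1, 35)


def _design(days: np.ndarray, degree: int, day_scale: float) -> np.ndarray:
    x = np.asarray(days, dtype=float) / day_scale
    return np.vander(x, degree + 1, increasing=True)


def _validate_day_pi(X, y):
    days = np.asarray(X, dtype=float).reshape(-1)
    pi = np.asarray(y, dtype=float).reshape(-1)
    if days.shape[0] != pi.shape[0]:
        raise ValueError("days and PI values must have equal length")
    if not np.all(np.isfinite(days)) or not np.all(np.isfinite(pi)):
        raise ValueError("days and PI values must be finite")
    if np.any(pi <= 0):
        raise ValueError("PI values must be strictly positive (log transform)")
    return days, pi


class ReferenceCurveModel(BaseEstimator):
    """Gaussian centile curves from a polynomial fit of log(PI) on day/10.

    Parameters
    ----------
    degree : int
        Polynomial degree in day/10 (default 3, the selected model).
    trim_threshold : float
        Records with |standardized residual| above this are removed before
        the final refit (default 3).
    trim_iterations : int
        Number of trim-and-refit passes (default 1; 0 disables trimming).
    studentized : bool
        If True, use internally studentized (leverage-adjusted) residuals
        for trimming instead of residual/SD.  At cohort sizes in the
        thousands with 4 parameters the two are nearly identical.
    day_scale : float
        Rescaling of the day variable (default 10, avoiding tiny
        coefficients).

    Attributes
    ----------
    beta_ : ndarray of shape (degree + 1,)
        Fitted coefficients on the log-PI scale.
    beta_ci_ : ndarray of shape (degree + 1, 2)
        95% confidence intervals.
    beta_se_ : ndarray
        Standard errors.
    residual_sd_ : float
        SD of the unscaled residuals of the final fit (denominator n - p).
    n_used_, n_removed_ : int
        Record counts after/removed by trimming.
    inlier_mask_ : ndarray of bool
        True for records kept in the final fit (in input order).
    """

    def __init__(
        self,
        degree: int = 3,
        trim_threshold: float = 3.0,
        trim_iterations: int = 1,
        studentized: bool = False,
        day_scale: float = 10.0,
    ):
        self.degree = degree
        self.trim_threshold = trim_threshold
        self.trim_iterations = trim_iterations
        self.studentized = studentized
        self.day_scale = day_scale

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        days, pi = _validate_day_pi(X, y)
        p = self.degree + 1
        if np.unique(days).size < p:
            raise ValueError(
                f"need at least {p} distinct days to fit a degree-{self.degree} "
                "polynomial (rank-deficient design)"
            )
        log_pi = np.log(pi)
        keep = np.ones(days.size, dtype=bool)

        res = self._ols(days[keep], log_pi[keep])
        for _ in range(int(self.trim_iterations)):
            z = self._scaled_residuals(res)
            bad = np.abs(z) > self.trim_threshold
            if not bad.any():
                break
            keep[np.flatnonzero(keep)[bad]] = False
            if keep.sum() < p:
                raise ValueError("trimming removed too many records to refit")
            res = self._ols(days[keep], log_pi[keep])

        self.result_ = res
        self.beta_ = np.asarray(res.params, dtype=float)
        self.beta_ci_ = np.asarray(res.conf_int(alpha=0.05), dtype=float)
        self.beta_se_ = np.asarray(res.bse, dtype=float)
        dof = res.nobs - p
        rss = float(np.sum(res.resid**2))
        self.residual_sd_ = float(np.sqrt(rss / dof)) if dof > 0 else 0.0
        self.n_used_ = int(res.nobs)
        self.n_removed_ = int(days.size - res.nobs)
        self.inlier_mask_ = keep
        return self

    def _ols(self, days: np.ndarray, log_pi: np.ndarray):
        return sm.OLS(log_pi, _design(days, self.degree, self.day_scale)).fit()

    def _scaled_residuals(self, res) -> np.ndarray:
        resid = np.asarray(res.resid, dtype=float)
        if self.studentized:
            infl = res.get_influence()
            return np.asarray(infl.resid_studentized_internal, dtype=float)
        dof = res.nobs - len(res.params)
        sd = np.sqrt(np.sum(resid**2) / dof) if dof > 0 else 0.0
        if sd == 0.0:
            return np.zeros_like(resid)
        return resid / sd

    @classmethod
    def from_coefficients(
        cls,
        beta,
        residual_sd: float,
        beta_ci=None,
        n_used: int = 0,
        day_scale: float = 10.0,
    ) -> "ReferenceCurveModel":
        """Build a usable model directly from known coefficients.

        Lets published coefficient tables be evaluated without the source
        records.
        """
        beta = np.asarray(beta, dtype=float)
        model = cls(degree=beta.size - 1, day_scale=day_scale)
        model.beta_ = beta
        model.beta_ci_ = (
            np.asarray(beta_ci, dtype=float)
            if beta_ci is not None
            else np.column_stack([beta, beta])
        )
        model.beta_se_ = np.full(beta.size, np.nan)
        model.residual_sd_ = float(residual_sd)
        model.n_used_ = int(n_used)
        model.n_removed_ = 0
        return model

    # ------------------------------------------------------------- predict

    def mean_log_pi(self, days) -> np.ndarray:
        check_is_fitted(self, "beta_")
        return _design(np.asarray(days, dtype=float).reshape(-1),
                       len(self.beta_) - 1, self.day_scale) @ self.beta_

    def predict(self, X) -> np.ndarray:
        """Median (50th centile) PI at the given days."""
        return self.predict_centile(np.asarray(X).reshape(-1), K=0.0)

    def predict_centile(self, days, K: float = 0.0) -> np.ndarray:
        """PI centile curve exp(mean_log_pi(d) + K * residual_sd)."""
        check_is_fitted(self, "beta_")
        return np.exp(self.mean_log_pi(days) + K * self.residual_sd_)

    def residuals(self, X, y) -> np.ndarray:
        """Unscaled log-scale residuals log(PI) - mean_log_pi(day)."""
        days, pi = _validate_day_pi(X, y)
        return np.log(pi) - self.mean_log_pi(days)

    def centile_table(
        self,
        days=DEFAULT_DAYS,
        records: pd.DataFrame | None = None,
        K_values: tuple[float, float, float] = (-Z_90, 0.0, Z_90),
    ) -> pd.DataFrame:
        """Per-day predicted (and optionally observed) 5th/50th/95th centiles.

        ``records`` (columns ``cycle_day`` and ``pi_mean``) adds empirical
        per-day percentiles alongside the predictions.
        """
        check_is_fitted(self, "beta_")
        days = np.asarray(days)
        if days.size == 0:
            raise ValueError("empty day range")
        k_lo, k_mid, k_hi = K_values
        table = pd.DataFrame(
            {
                "day": days,
                "pred_p5": self.predict_centile(days, k_lo),
                "pred_p50": self.predict_centile(days, k_mid),
                "pred_p95": self.predict_centile(days, k_hi),
            }
        )
        if records is not None:
            grouped = records.groupby("cycle_day")["pi_mean"]
            obs = grouped.quantile([0.05, 0.50, 0.95]).unstack()
            obs.columns = ["obs_p5", "obs_p50", "obs_p95"]
            obs["n_observed"] = grouped.size()
            table = table.merge(
                obs, left_on="day", right_index=True, how="left"
            )
            table["n_observed"] = table["n_observed"].fillna(0).astype(int)
            table = table[
                ["day", "n_observed", "obs_p5", "obs_p50", "obs_p95",
                 "pred_p5", "pred_p50", "pred_p95"]
            ]
        return table

    def find_extrema(self, days=DEFAULT_DAYS, K: float = 0.0) -> dict:
        """Minimum of a centile curve over integer days (ties -> smallest day)."""
        days = np.asarray(days)
        curve = self.predict_centile(days, K)
        i = int(np.argmin(curve))  # argmin takes the first (smallest) day on ties
        return {
            "argmin_day": int(days[i]),
            "min_value": float(curve[i]),
            "first_day_value": float(curve[0]),
            "last_day_value": float(curve[-1]),
        }

    def to_multiplicative(self) -> tuple[float, np.ndarray]:
        """Rewrite E[PI | d] = C * exp(g1 d + g2 d^2 + g3 d^3).

        C = exp(b0) and g_k = b_k / day_scale**k; the transform is a
        bijection, so the polynomial coefficients round-trip exactly.
        """
        check_is_fitted(self, "beta_")
        powers = np.arange(1, len(self.beta_))
        return float(np.exp(self.beta_[0])), self.beta_[1:] / self.day_scale**powers

    @classmethod
    def from_multiplicative(
        cls, C: float, gamma, residual_sd: float = 0.0, day_scale: float = 10.0
    ) -> "ReferenceCurveModel":
        gamma = np.asarray(gamma, dtype=float)
        powers = np.arange(1, gamma.size + 1)
        beta = np.concatenate([[np.log(C)], gamma * day_scale**powers])
        return cls.from_coefficients(beta, residual_sd, day_scale=day_scale)

    def to_dict(self) -> dict:
        check_is_fitted(self, "beta_")
        return {
            "beta": self.beta_.tolist(),
            "beta_ci": self.beta_ci_.tolist(),
            "residual_sd": self.residual_sd_,
            "n_used": self.n_used_,
            "n_removed": self.n_removed_,
            "day_scale": self.day_scale,
            "degree": len(self.beta_) - 1,
        }


def fit_crude_model(
    records: pd.DataFrame, trim_threshold: float = 3.0, **kwargs
) -> ReferenceCurveModel:
    """Fit the crude model from a cohort DataFrame (cycle_day, pi_mean)."""
    model = ReferenceCurveModel(trim_threshold=trim_threshold, **kwargs)
    return model.fit(records["cycle_day"].to_numpy(), records["pi_mean"].to_numpy())


def compare_polynomial_degrees(
    X, y, max_degree: int = 3, alpha: float = 0.05
) -> dict:
    """Choose the polynomial degree by significance of the leading term.

    Fits degrees 1..max_degree and returns the highest degree whose top
    coefficient is significant at ``alpha`` (partial t test), never
    exceeding ``max_degree`` — higher-degree day polynomials are prone to
    boundary waviness and are not considered.
    """
    days, pi = _validate_day_pi(X, y)
    log_pi = np.log(pi)
    p_values: dict[int, float] = {}
    chosen = 1
    for deg in range(1, max_degree + 1):
        res = sm.OLS(log_pi, _design(days, deg, 10.0)).fit()
        p_top = float(res.pvalues[deg])
        p_values[deg] = p_top
        if p_top < alpha:
            chosen = deg
    return {"chosen_degree": chosen, "top_term_p_values": p_values}
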