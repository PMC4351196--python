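"""Residual diagnostics for the log-PI centile models.

Covers the three checks the centile method rests on:

* homoscedasticity, via regression of scaled absolute residuals
  (SAR = (pi/2)*|residual|) on cycle day — a material day trend in the SARs
  would invalidate a single residual SD for all days;
* normality of the residuals, via the Lilliefors-corrected
  Kolmogorov-Smirnov test (mean and SD estimated from the sample), with an
  exactly reproducible Monte-Carlo null by default;
* summary coverage: the fraction of standardized residuals inside
  (-1.645, 1.645), QQ pairs, and per-stratum normality p-values.

For Gaussian residuals with SD sigma, E[SAR] = sigma * sqrt(pi/2); the
(pi/2) scaling is kept as defined in the source analysis (the more common
convention scales by sqrt(pi/2) so that E[SAR] = sigma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SAR_SCALE = math.pi / 2.0
Z_90 = 1.6449


@dataclass
class SARTestResult:
    slope: float
    slope_p: float
    r_squared: float
    redundant: bool  # trend explains too little variance to matter
    degree: int = 1


@dataclass
class LillieforsResult:
    statistic: float
    p_value: float
    method: str
    n: int


@dataclass
class DiagnosticsReport:
    n: int
    prop_within_1645: float
    ks_lilliefors_p: float | None
    sar_r_squared: float | None
    sar_slope_p: float | None
    qq_points: pd.DataFrame | None
    per_stratum_p: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "prop_within_1645": self.prop_within_1645,
            "ks_lilliefors_p": self.ks_lilliefors_p,
            "sar_r_squared": self.sar_r_squared,
            "sar_slope_p": self.sar_slope_p,
            "per_stratum_p": {
                f"age{g}_{p}": v for (g, p), v in self.per_stratum_p.items()
            },
            "degenerate": self.degenerate,
        }


def sar_heteroscedasticity_test(
    residuals,
    days,
    degree: int = 1,
    redundancy_r2: float = 0.01,
) -> SARTestResult:
    """Regress (pi/2)*|residual| on a day polynomial (degree 1 by default).

    Returns the day slope, its p-value and the regression R^2.  The trend
    is flagged ``redundant`` when R^2 <= ``redundancy_r2``: even a
    statistically significant slope that explains ~1% of the SAR variance
    does not compromise a constant-SD centile model.
    """
    r = np.asarray(residuals, dtype=float).reshape(-1)
    d = np.asarray(days, dtype=float).reshape(-1)
    if r.size != d.size:
        raise ValueError("residuals and days must be aligned")
    if r.size < 10:
        raise ValueError("need at least 10 residuals")
    if np.ptp(r) == 0.0:
        raise ValueError("zero-variance residuals: SAR regression is degenerate")
    sar = SAR_SCALE * np.abs(r)
    if np.ptp(sar) == 0.0:
        return SARTestResult(0.0, 1.0, 0.0, True, degree)
    X = np.vander(d, degree + 1, increasing=True)
    res = sm.OLS(sar, X).fit()
    return SARTestResult(
        slope=float(res.params[1]),
        slope_p=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        redundant=bool(res.rsquared <= redundancy_r2),
        degree=degree,
    )


def _ks_statistic_rows(z: np.ndarray) -> np.ndarray:
    """KS distance to N(0,1) for each (already standardized) row, vectorized."""
    z = np.sort(z, axis=-1)
    n = z.shape[-1]
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_plus = np.max(grid - cdf, axis=-1)
    d_minus = np.max(cdf - (np.arange(n) / n), axis=-1)
    return np.maximum(d_plus, d_minus)


def lilliefors_normality_test(
    x,
    n_mc: int = 10000,
    seed: int = 0,
    method: str = "monte_carlo",
) -> LillieforsResult:
    """Kolmogorov-Smirnov test of normality with estimated mean and SD.

    Because the Gaussian parameters are estimated from the same sample, the
    plain KS null distribution is wrong (anti-conservative correction
    needed); the default computes the null by Monte Carlo — ``n_mc``
    standard-normal samples of the same size, each standardized by its own
    sample moments — which is exact up to simulation error and reproducible
    under ``seed``.  ``method="table"`` uses the classical Lilliefors table
    approximation via statsmodels.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("insufficient variation: all observations identical")
    z = (x - x.mean()) / sd
    d_obs = float(_ks_statistic_rows(z[None, :])[0])
    if method == "table":
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        _, p = sm_lilliefors(x, dist="norm", pvalmethod="table")
        return LillieforsResult(d_obs, float(p), "table", x.size)
    if method != "monte_carlo":
        raise ValueError(f"unknown method: {method!r}")
    rng = np.random.default_rng(seed)
    n = x.size
    # chunk the null replicates to bound memory at large n
    chunk = max(1, min(n_mc, int(2e7 // n)))
    exceed = 0
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        sim = rng.standard_normal((m, n))
        sim = (sim - sim.mean(axis=1, keepdims=True)) / sim.std(axis=1, ddof=1,
                                                                keepdims=True)
        exceed += int(np.sum(_ks_statistic_rows(sim) >= d_obs))
        done += m
    p = (1 + exceed) / (n_mc + 1)
    return LillieforsResult(d_obs, float(p), "monte_carlo", n)


def residual_summary(
    model,
    records: pd.DataFrame,
    n_mc: int = 2000,
    seed: int = 0,
    strata: bool = False,
) -> DiagnosticsReport:
    """Diagnostic battery for a fitted centile model on a record set.

    ``model`` is a fitted :class:`~utaref.reference.ReferenceCurveModel` or
    :class:`~utaref.stratified.StratifiedCurveModel`; residuals are computed
    on the log scale against the model's mean curve.  With ``strata=True``
    a per-(age group, parity) Lilliefors p-value is added (six cells).

    Standardized residuals (residual / residual SD) feed the coverage
    proportion; the QQ pairs use externally studentized residuals when the
    model retains its regression results, otherwise standardized ones.
    """
    days = records["cycle_day"].to_numpy(dtype=float)
    pi = records["pi_mean"].to_numpy(dtype=float)
    if hasattr(model, "params_"):  # stratified
        resid = np.empty(len(records))
        ag = records["age_group"].to_numpy()
        par = records["parity"].to_numpy()
        log_pi = np.log(pi)
        for g in (1, 2, 3):
            for p in ("nulliparous", "parous"):
                mask = (ag == g) & (_parity_eq(par, p))
                if mask.any():
                    resid[mask] = log_pi[mask] - model.mean_log_pi(
                        days[mask], g, p
                    )
    else:
        resid = model.residuals(days, pi)

    sd = model.residual_sd_
    if sd <= 1e-12:  # exact-fit / all-zero residuals: summaries are degenerate
        return DiagnosticsReport(
            n=len(resid),
            prop_within_1645=1.0,
            ks_lilliefors_p=None,
            sar_r_squared=None,
            sar_slope_p=None,
            qq_points=None,
            degenerate=True,
        )

    z = resid / sd
    prop = float(np.mean(np.abs(z) < Z_90))
    lillie = lilliefors_normality_test(resid, n_mc=n_mc, seed=seed)
    sar = sar_heteroscedasticity_test(resid, days)

    zq = _studentized(model, z)
    order = np.argsort(zq)
    n = len(zq)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "empirical": zq[order]})

    per_stratum: dict = {}
    if strata:
        ag = records["age_group"].to_numpy()
        par = records["parity"].to_numpy()
        for g in (1, 2, 3):
            for p in ("nulliparous", "parous"):
                mask = (ag == g) & (_parity_eq(par, p))
                if mask.sum() >= 5:
                    per_stratum[(g, p)] = lilliefors_normality_test(
                        resid[mask], n_mc=n_mc, seed=seed + g * 2 + (p == "parous")
                    ).p_value

    return DiagnosticsReport(
        n=n,
        prop_within_1645=prop,
        ks_lilliefors_p=lillie.p_value,
        sar_r_squared=sar.r_squared,
        sar_slope_p=sar.slope_p,
        qq_points=qq,
        per_stratum_p=per_stratum,
    )


def _parity_eq(values: np.ndarray, label: str) -> np.ndarray:
    want_parous = label == "parous"
    out = np.empty(values.size, dtype=bool)
    for i, v in enumerate(values):
        s = str(v).strip().lower()
        out[i] = (s in {"parous", "1", "true"}) == want_parous
    return out


def _studentized(model, z: np.ndarray) -> np.ndarray:
    """Externally studentized residuals if the fit is available, else z."""
    res = getattr(model, "result_", None)
    if res is not None and res.nobs == z.size:
        try:
            return np.asarray(res.get_influence().resid_studentized_external)
        except Exception:
            pass
    return z
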