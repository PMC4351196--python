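"""Intraobserver reliability of repeated PI readings.

Two statistics from paired readings of the same subjects by one operator:

* the intraclass correlation ICC(A,1) — two-way model with the two readings
  treated as fixed (mixed), absolute agreement, single measurement — which
  penalizes a systematic offset between first and second readings, with the
  standard F-based 95% confidence interval (McGraw & Wong);
* the reliability coefficient, 1.96 times the SD of the within-pair
  differences: the difference magnitude exceeded by only 5% of repeat
  pairs, in PI units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReliabilityResult:
    icc: float
    icc_ci: tuple[float, float]
    reliability_coefficient: float
    n_pairs: int
    form: str  # "A,1" or "A,k" / "C,1"


def _as_pairs(pairs) -> np.ndarray:
    if isinstance(pairs, pd.DataFrame):
        arr = pairs.to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of paired readings")
    if np.any(~np.isfinite(arr)):
        raise ValueError("pairs contain missing or non-finite values")
    return arr


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # between readings
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way_mixed_absolute(
    pairs,
    confidence: float = 0.95,
    average: bool = False,
    agreement: str = "absolute",
) -> ReliabilityResult:
    """ICC of paired readings from the two-way ANOVA decomposition.

    Default is the single-measurement absolute-agreement form

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with k = 2 readings.  ``average=True`` gives the average-measures form
    ICC(A,k); ``agreement="consistency"`` drops the reading-mean variance
    term (ICC(C,1)), which ignores a systematic offset between readings.
    """
    x = _as_pairs(pairs)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 complete pairs")
    msr, msc, mse, n, k = _anova_mean_squares(x)
    alpha = 1.0 - confidence

    if agreement == "consistency":
        denom = msr + (k - 1) * mse
        icc = 0.0 if denom == 0 else (msr - mse) / denom
        fl = (msr / mse) / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1)) \
            if mse > 0 else np.inf
        fu = (msr / mse) * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1) \
            if mse > 0 else np.inf
        lo = (fl - 1) / (fl + k - 1) if np.isfinite(fl) else 1.0
        hi = (fu - 1) / (fu + k - 1) if np.isfinite(fu) else 1.0
        form = "C,1"
    elif agreement == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:  # all readings identical across and within subjects
            icc, lo, hi = 1.0, 1.0, 1.0
        else:
            icc = (msr - mse) / denom
            lo, hi = _absolute_ci(msr, msc, mse, n, k, icc, alpha)
        form = "A,1"
    else:
        raise ValueError(f"unknown agreement form: {agreement!r}")

    if average:
        # Spearman-Brown style step-up of point estimate and CI
        icc = k * icc / (1 + (k - 1) * icc)
        lo = k * lo / (1 + (k - 1) * lo)
        hi = k * hi / (1 + (k - 1) * hi)
        form = form.replace("1", "k")

    rc = reliability_coefficient(x)
    return ReliabilityResult(float(icc), (float(lo), float(hi)), rc, n, form)


def _absolute_ci(msr, msc, mse, n, k, icc, alpha) -> tuple[float, float]:
    """McGraw & Wong F-based interval for ICC(A,1)."""
    if mse == 0 and msc == 0:
        return 1.0, 1.0
    if icc >= 1.0:
        return 1.0, 1.0
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else np.inf
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))


def reliability_coefficient(pairs) -> float:
    """1.96 times the sample SD (n-1 denominator) of within-pair differences."""
    x = _as_pairs(pairs)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    return float(1.96 * np.std(x[:, 0] - x[:, 1], ddof=1))


def analyze_pairs(pairs, **kwargs) -> ReliabilityResult:
    """ICC(A,1) with CI plus the reliability coefficient, in one report."""
    return icc_two_way_mixed_absolute(pairs, **kwargs)
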