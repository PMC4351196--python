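"""Cohort-level processing: eligibility, derived clinical variables and
demographic summaries.

Covers the steps between raw visit records and the regression dataset:
computing the pulsatility index from velocities, classifying protodiastolic
notch status, the expected ovulation date under a fixed 14-day luteal
phase, rule-ordered eligibility exclusion, the day-of-cycle uniformity
check, and a demographic summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def compute_pi(systolic_peak: float, end_diastolic: float, mean_velocity: float) -> float:
    """Pulsatility index: (peak systolic - end diastolic) / mean velocity."""
    if mean_velocity <= 0:
        raise ValueError("mean velocity must be positive")
    if systolic_peak < end_diastolic:
        raise ValueError("systolic peak velocity must be >= end-diastolic velocity")
    return (systolic_peak - end_diastolic) / mean_velocity


def classify_notch(notch_left, notch_right) -> str:
    """'bilateral', 'unilateral_only' or 'absent' from the two side flags.

    "Any notch" is bilateral or unilateral_only; absence requires the notch
    to be missing on both sides.
    """
    if notch_left is None or notch_right is None or (
        isinstance(notch_left, float) and math.isnan(notch_left)
    ) or (isinstance(notch_right, float) and math.isnan(notch_right)):
        raise ValueError("both notch flags are required")
    left, right = bool(notch_left), bool(notch_right)
    if left and right:
        return "bilateral"
    if left or right:
        return "unilateral_only"
    return "absent"


def notch_prevalence(records: pd.DataFrame) -> dict:
    """Counts and percentages of bilateral / any notch in a cohort."""
    classes = [
        classify_notch(l, r)
        for l, r in zip(records["notch_left"], records["notch_right"])
    ]
    n = len(classes)
    n_bilateral = sum(c == "bilateral" for c in classes)
    n_any = sum(c != "absent" for c in classes)
    return {
        "n": n,
        "bilateral": n_bilateral,
        "bilateral_pct": round(100.0 * n_bilateral / n, 1),
        "any_notch": n_any,
        "any_notch_pct": round(100.0 * n_any / n, 1),
    }


def expected_ovulation_date(cycle_length_days: float) -> float:
    """EOD = cycle length - 14 (fixed-duration luteal phase assumption)."""
    if cycle_length_days <= 14:
        raise ValueError("EOD undefined for cycle length <= 14 days")
    return cycle_length_days - 14


@dataclass(frozen=True)
class EligibilityConfig:
    """Exclusion rules in protocol order; first matching rule wins."""

    exclusion_flags: tuple[str, ...] = (
        "missing_calendar",
        "pregnant",
        "unmeasurable_pi",
        "refused",
    )
    day_min: int = 1
    day_max: int = 34
    age_min: float = 18.0
    age_max: float = 50.0

    def __post_init__(self):
        if self.day_min > self.day_max or self.age_min > self.age_max:
            raise ValueError("bounds must be ordered")


def apply_eligibility(
    records: pd.DataFrame, config: EligibilityConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Partition records into (included, excluded-with-reason, summary).

    Flag columns absent from ``records`` are treated as all-False.  Every
    excluded record carries exactly one reason: the first matching rule in
    ``config.exclusion_flags`` order; the partition is exhaustive.
    """
    config = config or EligibilityConfig()
    n = len(records)
    reason = np.array([""] * n, dtype=object)
    for flag in config.exclusion_flags:
        if flag not in records.columns:
            continue
        col = records[flag].fillna(False).astype(bool).to_numpy()
        reason = np.where((reason == "") & col, flag, reason)
    excluded_mask = reason != ""
    included = records.loc[~excluded_mask].copy()
    excluded = records.loc[excluded_mask].copy()
    excluded["exclusion_reason"] = reason[excluded_mask]
    summary = {
        "n_total": n,
        "n_included": int((~excluded_mask).sum()),
        "n_excluded": int(excluded_mask.sum()),
        "excluded_pct": round(100.0 * excluded_mask.sum() / n, 1) if n else 0.0,
        "by_reason": {
            flag: int((reason == flag).sum()) for flag in config.exclusion_flags
        },
    }
    return included, excluded, summary


@dataclass
class DayDistributionCheck:
    sample_mean: float
    sample_sd: float
    expected_mean: float
    expected_sd: float
    support: str


def day_distribution_check(
    days, support: str = "continuous", day_min: int = 1, day_max: int = 34
) -> DayDistributionCheck:
    """Empirical day mean/SD against the uniform reference.

    ``support="continuous"`` compares with the continuous uniform on
    [0, day_max] (mean day_max/2, SD day_max/sqrt(12) — for day_max = 34:
    17.0 and 9.8); ``support="discrete"`` with the discrete uniform on
    {day_min..day_max} (mean 17.5, SD 9.81 for 1..34).
    """
    d = np.asarray(days, dtype=float).reshape(-1)
    if d.size < 2:
        raise ValueError("need at least 2 records")
    if support == "continuous":
        exp_mean = day_max / 2.0
        exp_sd = day_max / math.sqrt(12.0)
    elif support == "discrete":
        k = day_max - day_min + 1
        exp_mean = (day_min + day_max) / 2.0
        exp_sd = math.sqrt((k**2 - 1) / 12.0)
    else:
        raise ValueError(f"unknown support: {support!r}")
    return DayDistributionCheck(
        sample_mean=float(d.mean()),
        sample_sd=float(d.std(ddof=1)),
        expected_mean=exp_mean,
        expected_sd=exp_sd,
        support=support,
    )


#: BMI bands as printed in the source cohort table (not WHO classes).
BMI_BANDS = {"16-24": (16.0, 25.0), "25-29": (25.0, 30.0), "30-39": (30.0, 40.0)}


@dataclass
class DemographicsSummary:
    """Counts per category block; percentages recomputed from counts."""

    n: int
    blocks: dict[str, dict[str, int]]
    means: dict[str, tuple[float, float]] = field(default_factory=dict)

    def percentages(self, block: str) -> dict[str, float]:
        counts = self.blocks[block]
        return {k: round(100.0 * v / self.n, 1) for k, v in counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, counts in self.blocks.items():
            for cat, cnt in counts.items():
                rows.append(
                    {
                        "block": block,
                        "category": cat,
                        "count": cnt,
                        "percent": round(100.0 * cnt / self.n, 1),
                    }
                )
        for name, (mean, sd) in self.means.items():
            rows.append({"block": name, "category": "mean±SD",
                         "count": mean, "percent": sd})
        return pd.DataFrame(rows)


def summarize_demographics(records: pd.DataFrame) -> DemographicsSummary:
    """Demographic composition of an included cohort.

    Blocks: age group, BMI band, parity, smoking, notch status.  Means:
    cycle length (days).  Percentages are derived from counts at display
    time, never stored.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    n = len(records)
    blocks: dict[str, dict[str, int]] = {}

    ag = records["age_group"].astype(int)
    blocks["age_group"] = {str(g): int((ag == g).sum()) for g in (1, 2, 3)}

    if "bmi" in records.columns:
        bmi = records["bmi"].to_numpy(dtype=float)
        blocks["bmi_band"] = {
            name: int(((bmi >= lo) & (bmi < hi)).sum())
            for name, (lo, hi) in BMI_BANDS.items()
        }

    parity = records["parity"].astype(str).str.lower()
    blocks["parity"] = {
        "nulliparous": int((parity == "nulliparous").sum()),
        "parous": int((parity == "parous").sum()),
    }

    if "smoking" in records.columns:
        smoking = records["smoking"].astype(bool)
        blocks["smoking"] = {"no": int((~smoking).sum()), "yes": int(smoking.sum())}

    if {"notch_left", "notch_right"} <= set(records.columns):
        classes = pd.Series(
            [
                classify_notch(l, r)
                for l, r in zip(records["notch_left"], records["notch_right"])
            ]
        )
        blocks["notch"] = {
            "bilateral": int((classes == "bilateral").sum()),
            "unilateral_only": int((classes == "unilateral_only").sum()),
            "absent": int((classes == "absent").sum()),
        }

    means = {}
    if "cycle_length_days" in records.columns:
        cl = records["cycle_length_days"].to_numpy(dtype=float)
        means["cycle_length_days"] = (float(cl.mean()),
                                      float(cl.std(ddof=1)) if n > 1 else 0.0)
    return DemographicsSummary(n=n, blocks=blocks, means=means)
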