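"""Synthetic cross-sectional cohorts for the UtA-PI reference-range analysis.

The original per-subject records are not deposited, so every downstream
stage is exercised on simulated cohorts that reproduce the statistical
structure the analysis assumes: cycle days discrete-uniform on 1-34,
log(PI) Gaussian around a cubic polynomial in day/10 (optionally with
age-group/parity level and slope shifts), homoscedastic residual SD,
demographic composition matching the study cohort, and optional outlier
contamination displaced by a configurable number of residual SDs.

A single :class:`numpy.random.Generator` seeded from ``config.seed`` drives
every column, so identical configurations produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import published

COHORT_COLUMNS = [
    "subject_id",
    "cycle_day",
    "pi_left",
    "pi_right",
    "pi_mean",
    "age_years",
    "age_group",
    "parity",
    "bmi",
    "smoking",
    "cycle_length_days",
    "notch_left",
    "notch_right",
    "contaminated",
]


@dataclass(frozen=True)
class StrataEffects:
    """Additive shifts of the log-PI polynomial by age group and parity.

    Offsets are relative to the reference stratum (age group 1,
    nulliparous).  ``day_*`` shift the day/10 slope, ``day2_*`` the
    quadratic term; the cubic term is shared across strata.
    """

    intercept_age2: float = 0.0
    intercept_age3: float = 0.0
    intercept_parous: float = 0.0
    day_age2: float = 0.0
    day_age3: float = 0.0
    day2_age2: float = 0.0
    day2_age3: float = 0.0

    @classmethod
    def reference(cls) -> "StrataEffects":
        """Offsets of the published stratified model."""
        c = published.STRATIFIED_COEFS
        return cls(
            intercept_age2=c["age2"][0],
            intercept_age3=c["age3"][0],
            intercept_parous=c["parous"][0],
            day_age2=c["age2:day"][0],
            day_age3=c["age3:day"][0],
            day2_age2=c["age2:day2"][0],
            day2_age3=c["age3:day2"][0],
        )


def _reference_age_probs() -> tuple[float, float, float]:
    counts = np.asarray(published.AGE_GROUP_COUNTS, dtype=float)
    p = counts / counts.sum()
    return (float(p[0]), float(p[1]), float(p[2]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator.

    Defaults reproduce the study conditions: analysis sample size 1657,
    crude-model coefficients on log PI, residual SD 0.299, and the cohort's
    age-group/parity mix.  ``contamination_rate`` displaces that fraction of
    records by at least ``contamination_shift`` residual SDs on the log
    scale, with a negative displacement with probability
    ``contamination_left_prob``.
    """

    n_subjects: int = published.N_ANALYSIS
    day_min: int = 1
    day_max: int = 34
    beta: tuple[float, float, float, float] = published.CRUDE_BETA
    residual_sd: float = published.RESIDUAL_SD
    age_group_probs: tuple[float, float, float] = field(
        default_factory=_reference_age_probs
    )
    parity_prob: float = published.PAROUS_COUNT / published.N_INCLUDED
    strata_effects: StrataEffects | None = None
    contamination_rate: float = 0.0
    contamination_shift: float = 4.0
    contamination_left_prob: float = 0.5
    lr_spread_sd: float = 0.10  # left/right PI half-spread SD; not data-derived
    smoking_prob: float = published.SMOKER_COUNT / published.N_INCLUDED
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.day_min >= 1 and self.day_max >= self.day_min):
            raise ValueError("day range must satisfy 1 <= day_min <= day_max")
        if len(self.beta) != 4:
            raise ValueError("beta must have 4 coefficients")
        if not self.residual_sd >= 0:
            raise ValueError("residual_sd must be >= 0")
        probs = np.asarray(self.age_group_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("age_group_probs must be 3 probabilities in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("age_group_probs must sum to 1")
        for name in ("parity_prob", "contamination_rate",
                     "contamination_left_prob", "smoking_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lr_spread_sd < 0:
            raise ValueError("lr_spread_sd must be >= 0")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta"] = list(self.beta)
        d["age_group_probs"] = list(self.age_group_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if d.get("strata_effects") is not None:
            d["strata_effects"] = StrataEffects(**d["strata_effects"])
        if "beta" in d:
            d["beta"] = tuple(d["beta"])
        if "age_group_probs" in d:
            d["age_group_probs"] = tuple(d["age_group_probs"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def mean_log_pi(
    days: np.ndarray,
    beta: tuple[float, float, float, float],
    age_group: np.ndarray | None = None,
    parous: np.ndarray | None = None,
    effects: StrataEffects | None = None,
) -> np.ndarray:
    """E[log PI] as the cubic polynomial in day/10, plus stratum shifts."""
    x = np.asarray(days, dtype=float) / 10.0
    mu = beta[0] + beta[1] * x + beta[2] * x**2 + beta[3] * x**3
    if effects is not None:
        if age_group is None or parous is None:
            raise ValueError("stratum shifts require age_group and parous arrays")
        a2 = np.asarray(age_group) == 2
        a3 = np.asarray(age_group) == 3
        par = np.asarray(parous, dtype=bool)
        mu = (
            mu
            + effects.intercept_age2 * a2
            + effects.intercept_age3 * a3
            + effects.intercept_parous * par
            + (effects.day_age2 * a2 + effects.day_age3 * a3) * x
            + (effects.day2_age2 * a2 + effects.day2_age3 * a3) * x**2
        )
    return mu


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one synthetic cohort as a DataFrame (one row per woman).

    ``log(pi_mean)`` of uncontaminated rows is Gaussian with mean given by
    the configured polynomial (plus stratum shifts when ``strata_effects``
    is set) and SD ``residual_sd``; exactly
    ``round(contamination_rate * n_subjects)`` rows are displaced by at
    least ``contamination_shift`` residual SDs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    days = rng.integers(config.day_min, config.day_max + 1, size=n)
    age_group = rng.choice([1, 2, 3], size=n, p=np.asarray(config.age_group_probs))
    lo = np.array([published.AGE_GROUP_BOUNDS[g][0] for g in age_group], dtype=float)
    hi = np.array([published.AGE_GROUP_BOUNDS[g][1] for g in age_group], dtype=float)
    age_years = np.round(lo + rng.random(n) * (hi - lo), 1)
    parous = rng.random(n) < config.parity_prob

    mu = mean_log_pi(days, config.beta, age_group, parous, config.strata_effects)
    eps = rng.normal(0.0, config.residual_sd, size=n)
    log_pi = mu + eps

    contaminated = np.zeros(n, dtype=bool)
    n_bad = int(round(config.contamination_rate * n))
    if n_bad > 0:
        idx = rng.choice(n, size=n_bad, replace=False)
        sign = np.where(rng.random(n_bad) < config.contamination_left_prob, -1.0, 1.0)
        # |log_pi - mu| >= shift * sd by construction
        log_pi[idx] = mu[idx] + sign * (
            config.contamination_shift * config.residual_sd + np.abs(eps[idx])
        )
        contaminated[idx] = True

    pi_mean = np.exp(log_pi)
    half = np.abs(rng.normal(0.0, config.lr_spread_sd, size=n))
    half = np.minimum(half, 0.9 * pi_mean)  # keep both sides positive
    side = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    pi_left = pi_mean + side * half
    pi_right = pi_mean - side * half

    # demographics mirroring the study cohort's composition
    bmi_band = rng.choice(3, size=n, p=np.array([1032, 480, 156]) / 1668.0)
    band_lo = np.array([16.0, 25.0, 30.0])[bmi_band]
    band_hi = np.array([24.9, 29.9, 39.0])[bmi_band]
    bmi = np.round(band_lo + rng.random(n) * (band_hi - band_lo), 1)
    smoking = rng.random(n) < config.smoking_prob
    cycle_length = np.clip(
        np.round(rng.normal(published.CYCLE_LENGTH_MEAN, published.CYCLE_LENGTH_SD, n)),
        21, 40,
    ).astype(int)
    # notch status: bilateral / unilateral-only / absent
    p_bilateral = published.BILATERAL_NOTCH_COUNT / published.N_INCLUDED
    p_any = published.ANY_NOTCH_COUNT / published.N_INCLUDED
    u = rng.random(n)
    bilateral = u < p_bilateral
    unilateral = (u >= p_bilateral) & (u < p_any)
    left_if_uni = rng.random(n) < 0.5
    notch_left = bilateral | (unilateral & left_if_uni)
    notch_right = bilateral | (unilateral & ~left_if_uni)

    width = max(4, len(str(n)))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "cycle_day": days.astype(int),
            "pi_left": pi_left,
            "pi_right": pi_right,
            "pi_mean": pi_mean,
            "age_years": age_years,
            "age_group": age_group.astype(int),
            "parity": np.where(parous, "parous", "nulliparous"),
            "bmi": bmi,
            "smoking": smoking,
            "cycle_length_days": cycle_length,
            "notch_left": notch_left,
            "notch_right": notch_right,
            "contaminated": contaminated,
        }
    )


def generate_repeated_pairs(
    n_pairs: int,
    between_sd: float,
    within_sd: float,
    seed: int = 0,
    grand_mean: float = 2.7,
) -> pd.DataFrame:
    """Paired repeated PI readings sharing a subject-level true value.

    reading_j = grand_mean + subject_effect + noise_j, with subject effects
    of SD ``between_sd`` and independent within-subject noise of SD
    ``within_sd``; the population ICC is therefore
    between_sd**2 / (between_sd**2 + within_sd**2).
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2 (ICC undefined otherwise)")
    if between_sd < 0 or within_sd < 0:
        raise ValueError("SDs must be >= 0")
    rng = np.random.default_rng(seed)
    true = grand_mean + rng.normal(0.0, between_sd, size=n_pairs)
    r1 = true + rng.normal(0.0, within_sd, size=n_pairs)
    r2 = true + rng.normal(0.0, within_sd, size=n_pairs)
    return pd.DataFrame({"reading1": r1, "reading2": r2})


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort with the documented header; missing values as empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "cycle_day", "pi_mean"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {sorted(missing)}")
    return df
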