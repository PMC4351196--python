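"""Cohort processing: PI arithmetic, notch classes, EOD, eligibility
partition, day-uniformity reference and demographics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from utaref import (
    EligibilityConfig,
    apply_eligibility,
    classify_notch,
    compute_pi,
    day_distribution_check,
    expected_ovulation_date,
    notch_prevalence,
    summarize_demographics,
)


# ------------------------------------------------------------------------- PI


@pytest.mark.parametrize("psv,edv,mv,expected",
                         [(60, 10, 20, 2.5), (50, 5, 15, 3.0), (40, 40, 9, 0.0)])
def test_compute_pi(psv, edv, mv, expected):
    assert compute_pi(psv, edv, mv) == pytest.approx(expected)


@pytest.mark.parametrize("psv,edv,mv", [(60, 10, 0), (60, 10, -5), (10, 60, 20)])
def test_compute_pi_domain_errors(psv, edv, mv):
    with pytest.raises(ValueError):
        compute_pi(psv, edv, mv)


# ---------------------------------------------------------------------- notch


@pytest.mark.parametrize("l,r,expected", [
    (True, True, "bilateral"),
    (True, False, "unilateral_only"),
    (False, True, "unilateral_only"),
    (False, False, "absent"),
])
def test_classify_notch(l, r, expected):
    assert classify_notch(l, r) == expected


def test_classify_notch_requires_both_flags():
    with pytest.raises(ValueError):
        classify_notch(True, None)


def test_notch_prevalence_reproduces_reference_proportions():
    # 1568 bilateral + 58 unilateral-only + 42 absent = 1668
    df = pd.DataFrame({
        "notch_left": [True] * 1568 + [True] * 58 + [False] * 42,
        "notch_right": [True] * 1568 + [False] * 58 + [False] * 42,
    })
    prev = notch_prevalence(df)
    assert prev["any_notch"] == 1626
    assert prev["any_notch_pct"] == 97.5
    assert prev["bilateral_pct"] == 94.0


# ------------------------------------------------------------------------ EOD


@pytest.mark.parametrize("length,eod", [(28, 14), (34, 20), (28.8, 14.8)])
def test_expected_ovulation_date(length, eod):
    assert expected_ovulation_date(length) == pytest.approx(eod)


def test_eod_undefined_for_short_cycles():
    with pytest.raises(ValueError):
        expected_ovulation_date(14)


@given(st.floats(14.01, 60), st.floats(0.01, 10))
def test_eod_strictly_increasing(length, delta):
    assert expected_ovulation_date(length + delta) > expected_ovulation_date(length)


# ---------------------------------------------------------------- eligibility


def _flagged_cohort():
    n = 1821
    df = pd.DataFrame({
        "subject_id": range(n),
        "missing_calendar": [True] * 128 + [False] * (n - 128),
        "pregnant": [False] * 128 + [True] * 11 + [False] * (n - 139),
        "unmeasurable_pi": [False] * 139 + [True] * 10 + [False] * (n - 149),
        "refused": [False] * 149 + [True] * 4 + [False] * (n - 153),
    })
    return df


def test_eligibility_partition_reproduces_reference_counts():
    included, excluded, summary = apply_eligibility(_flagged_cohort())
    assert summary["n_included"] == 1668
    assert summary["n_excluded"] == 153
    assert summary["excluded_pct"] == 8.4
    assert summary["by_reason"] == {"missing_calendar": 128, "pregnant": 11,
                                    "unmeasurable_pi": 10, "refused": 4}
    assert len(included) + len(excluded) == 1821


def test_eligibility_first_matching_rule_wins():
    df = pd.DataFrame({"missing_calendar": [True], "pregnant": [True]})
    _, excluded, summary = apply_eligibility(df)
    assert list(excluded["exclusion_reason"]) == ["missing_calendar"]
    assert summary["n_excluded"] == 1


def test_eligibility_no_flags_and_all_flags():
    df = pd.DataFrame({"subject_id": range(5)})
    included, excluded, _ = apply_eligibility(df)
    assert len(included) == 5 and len(excluded) == 0
    df["refused"] = True
    included, excluded, _ = apply_eligibility(df)
    assert len(included) == 0
    assert (excluded["exclusion_reason"] == "refused").all()


def test_eligibility_partition_property(rng):
    n = 400
    df = pd.DataFrame({
        flag: rng.random(n) < 0.05
        for flag in EligibilityConfig().exclusion_flags
    })
    included, excluded, summary = apply_eligibility(df)
    assert len(included) + len(excluded) == n
    assert excluded["exclusion_reason"].isin(
        EligibilityConfig().exclusion_flags).all()
    assert sum(summary["by_reason"].values()) == len(excluded)


# ----------------------------------------------------------- day distribution


def test_uniform_reference_moments():
    days = [1, 2, 3, 4]
    cont = day_distribution_check(days, support="continuous")
    assert cont.expected_mean == 17.0
    assert round(cont.expected_sd, 1) == 9.8
    disc = day_distribution_check(days, support="discrete")
    assert disc.expected_mean == 17.5
    assert disc.expected_sd == pytest.approx(math.sqrt(96.25))


def test_day_check_sample_moments(clean_cohort):
    out = day_distribution_check(clean_cohort["cycle_day"])
    assert out.sample_mean == pytest.approx(clean_cohort["cycle_day"].mean())
    same = day_distribution_check([7, 7, 7])
    assert same.sample_sd == 0.0


# --------------------------------------------------------------- demographics


def test_demographics_reproduce_reference_percentages():
    n = 1668
    df = pd.DataFrame({
        "age_group": [1] * 251 + [2] * 727 + [3] * 690,
        "parity": ["nulliparous"] * 653 + ["parous"] * 1015,
        "smoking": [True] * 288 + [False] * 1380,
        "bmi": [20.0] * 1032 + [27.0] * 480 + [33.0] * 156,
        "notch_left": [True] * 1626 + [False] * 42,
        "notch_right": [True] * 1568 + [False] * 100,
        "cycle_length_days": [28.8] * n,
    })
    summary = summarize_demographics(df)
    assert summary.percentages("parity")["nulliparous"] == 39.1
    assert summary.percentages("smoking")["yes"] == 17.3
    assert summary.blocks["notch"]["bilateral"] == 1568
    for block in summary.blocks.values():
        assert sum(block.values()) == n
    for block in summary.blocks:
        # rounding each category to 1 dp can shift the block sum by up to 0.1
        assert sum(summary.percentages(block).values()) == pytest.approx(
            100, abs=0.1 + 1e-9)


def test_demographics_single_record():
    df = pd.DataFrame({
        "age_group": [2], "parity": ["parous"], "smoking": [False],
        "bmi": [22.0], "notch_left": [True], "notch_right": [True],
        "cycle_length_days": [28],
    })
    summary = summarize_demographics(df)
    assert summary.percentages("age_group") == {"1": 0.0, "2": 100.0, "3": 0.0}
    with pytest.raises(ValueError):
        summarize_demographics(df.iloc[:0])
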