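"""Crude centile model: OLS oracle agreement, trimming, centile algebra,
extrema and degree selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from utaref import (
    GeneratorConfig,
    ReferenceCurveModel,
    Z_90,
    compare_polynomial_degrees,
    fit_crude_model,
    generate_cohort,
)
from utaref.published import CRUDE_BETA
from utaref.reference import _design

DERIVED_SD = np.log(5.55 / 3.40) / Z_90  # residual SD implied by the day-1 centile ratio


def normal_equations(days, log_pi, degree=3):
    """Independent brute-force least squares via the normal equations."""
    X = _design(np.asarray(days, float), degree, 10.0)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(log_pi, float))


# --------------------------------------------------------------------- fitting


def test_ols_matches_normal_equations_oracle(rng):
    days = rng.integers(1, 35, 200)
    log_pi = 1.2 - 0.5 * days / 10 + rng.normal(0, 0.3, 200)
    model = ReferenceCurveModel(trim_iterations=0).fit(days, np.exp(log_pi))
    oracle = normal_equations(days, log_pi)
    np.testing.assert_allclose(model.beta_, oracle, rtol=1e-11)


def test_noise_free_cubic_recovered_exactly(noise_free_cohort):
    model = fit_crude_model(noise_free_cohort)
    np.testing.assert_allclose(model.beta_, CRUDE_BETA, rtol=1e-10)
    assert model.n_removed_ == 0
    assert model.residual_sd_ == pytest.approx(0.0, abs=1e-12)
    assert np.all(model.beta_ci_[:, 0] <= model.beta_)
    assert np.all(model.beta_ >= model.beta_ci_[:, 0])


def test_constant_pi_degenerates_gracefully(rng):
    days = rng.integers(1, 35, 100)
    pi = np.full(100, np.e)
    model = fit_crude_model(pd.DataFrame({"cycle_day": days, "pi_mean": pi}))
    np.testing.assert_allclose(model.beta_, [1, 0, 0, 0], atol=1e-10)
    assert model.residual_sd_ == pytest.approx(0.0, abs=1e-12)
    assert model.n_removed_ == 0


def test_injected_outliers_are_trimmed(rng):
    from utaref.synthetic import mean_log_pi

    cfg = GeneratorConfig(n_subjects=1000, seed=21)
    cohort = generate_cohort(cfg)
    # keep only records well inside the threshold so the clean part
    # contributes no outliers of its own
    pre = fit_crude_model(cohort, trim_threshold=2.5)
    clean = cohort.loc[pre.inlier_mask_, ["cycle_day", "pi_mean"]]
    days_bad = rng.integers(1, 35, 5)
    pi_bad = np.exp(mean_log_pi(days_bad, cfg.beta) + 5 * cfg.residual_sd)
    df = pd.concat(
        [clean, pd.DataFrame({"cycle_day": days_bad, "pi_mean": pi_bad})],
        ignore_index=True,
    )
    model = fit_crude_model(df)
    assert model.n_removed_ == 5
    assert model.n_used_ + model.n_removed_ == len(df)
    assert not model.inlier_mask_[-5:].any()


def test_trimming_monotone_in_threshold(clean_cohort):
    removed = [
        fit_crude_model(clean_cohort, trim_threshold=t).n_removed_
        for t in (2.0, 2.5, 3.0, 4.0)
    ]
    assert removed == sorted(removed, reverse=True)


def test_studentized_trimming_close_to_standardized(clean_cohort):
    a = fit_crude_model(clean_cohort, studentized=False)
    b = fit_crude_model(clean_cohort, studentized=True)
    # with n ~ 1657 and 4 parameters leverage is negligible
    assert abs(a.n_removed_ - b.n_removed_) <= 1


@pytest.mark.parametrize("bad", ["single_day", "nonpositive"])
def test_fit_input_errors(bad, rng):
    if bad == "single_day":
        with pytest.raises(ValueError):
            ReferenceCurveModel().fit(np.full(50, 7), np.full(50, 2.5))
    else:
        with pytest.raises(ValueError):
            ReferenceCurveModel().fit(rng.integers(1, 35, 50), np.zeros(50))


# ------------------------------------------------------------------- centiles


def test_published_coefficients_reproduce_reference_medians():
    model = ReferenceCurveModel.from_coefficients(CRUDE_BETA, DERIVED_SD)
    for day, expected in [(1, 3.40), (5, 2.90), (10, 2.64), (13, 2.61)]:
        value = model.predict_centile([day], K=0.0)[0]
        assert value == pytest.approx(expected, abs=0.011)


def test_tail_centiles_from_derived_sd():
    model = ReferenceCurveModel.from_coefficients(CRUDE_BETA, DERIVED_SD)
    assert round(model.predict_centile([1], K=-Z_90)[0], 2) == 2.08
    table = model.centile_table()
    assert round(table["pred_p95"].min(), 2) == 4.27


def test_zero_sd_collapses_centiles():
    model = ReferenceCurveModel.from_coefficients(CRUDE_BETA, 0.0)
    days = np.arange(1, 35)
    np.testing.assert_allclose(model.predict_centile(days, -Z_90),
                               model.predict_centile(days, Z_90))


def test_centile_table_log_symmetry_and_order(clean_cohort):
    model = fit_crude_model(clean_cohort)
    table = model.centile_table(records=clean_cohort.loc[model.inlier_mask_])
    assert (table["pred_p5"] < table["pred_p50"]).all()
    assert (table["pred_p50"] < table["pred_p95"]).all()
    np.testing.assert_allclose(table["pred_p5"] * table["pred_p95"],
                               table["pred_p50"] ** 2, rtol=1e-10)
    assert table["n_observed"].sum() == model.n_used_


def test_median_centile_equals_exponentiated_mean(clean_cohort):
    model = fit_crude_model(clean_cohort)
    days = np.linspace(1, 34, 67)
    np.testing.assert_allclose(model.predict_centile(days, 0.0),
                               np.exp(model.mean_log_pi(days)), rtol=1e-14)


# -------------------------------------------------------------------- extrema


def test_extrema_match_brute_force():
    model = ReferenceCurveModel.from_coefficients(CRUDE_BETA, DERIVED_SD)
    days = np.arange(1, 35)
    curve = model.predict_centile(days, 0.0)
    info = model.find_extrema()
    assert info["argmin_day"] == days[np.argmin(curve)] == 13
    assert info["min_value"] == pytest.approx(curve.min())


def test_flat_model_argmin_tie_breaks_to_first_day():
    model = ReferenceCurveModel.from_coefficients([1.0, 0, 0, 0], 0.1)
    info = model.find_extrema()
    assert info["argmin_day"] == 1
    assert info["first_day_value"] == pytest.approx(info["last_day_value"])


# ----------------------------------------------------------- degree selection


def test_degree_selection_noise_free_cubic(noise_free_cohort):
    out = compare_polynomial_degrees(noise_free_cohort["cycle_day"],
                                     noise_free_cohort["pi_mean"])
    assert out["chosen_degree"] == 3


def test_degree_selection_on_quadratic_truth():
    chosen = []
    for seed in range(20):
        cfg = GeneratorConfig(beta=(1.279, -0.573, 0.310, 0.0), seed=seed)
        c = generate_cohort(cfg)
        chosen.append(
            compare_polynomial_degrees(c["cycle_day"], c["pi_mean"])["chosen_degree"]
        )
    # cubic term is pure type-I error here (~5% rate)
    assert sum(d == 2 for d in chosen) >= 16
    assert all(d <= 3 for d in chosen)


def test_degree_selection_detects_cubic_at_study_size():
    chosen = []
    for seed in range(20):
        c = generate_cohort(GeneratorConfig(seed=seed + 100))
        chosen.append(
            compare_polynomial_degrees(c["cycle_day"], c["pi_mean"])["chosen_degree"]
        )
    assert sum(d == 3 for d in chosen) >= 11  # majority of seeds


# ------------------------------------------------------- multiplicative form


def test_multiplicative_form_of_published_fit():
    model = ReferenceCurveModel.from_coefficients(CRUDE_BETA, 0.299)
    C, gamma = model.to_multiplicative()
    assert C == pytest.approx(np.exp(1.279))
    np.testing.assert_allclose(gamma, [-0.0573, 0.00310, -0.000044], rtol=1e-12)


@given(
    beta=st.tuples(*[st.floats(-2, 2, allow_nan=False) for _ in range(4)]),
)
def test_multiplicative_form_round_trips(beta):
    model = ReferenceCurveModel.from_coefficients(np.asarray(beta), 0.1)
    C, gamma = model.to_multiplicative()
    back = ReferenceCurveModel.from_multiplicative(C, gamma, 0.1)
    np.testing.assert_allclose(back.beta_, beta, rtol=1e-12, atol=1e-12)
    if all(abs(b) < 1e-12 for b in beta):
        assert C == pytest.approx(1.0)
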