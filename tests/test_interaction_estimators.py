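"""Interaction estimators: corner algebra, profiles, gradients, grouping."""

import numpy as np
import pandas as pd
import pytest

import stressorint as si
from stressorint.interaction_estimators import StepError

from conftest import A, B, factorial_frame


def test_identity_link_ad_estimate_is_the_interaction_coefficient(
        gaussian_fit, contrast_ab):
    est = si.average_interaction(gaussian_fit, "AD", contrast_ab)
    assert est.estimate == pytest.approx(0.5, abs=1e-10)
    assert est.per_observation == pytest.approx(np.full(64, 0.5), abs=1e-10)


def test_loglink_mu_estimate_is_the_interaction_coefficient(
        loglink_fit, contrast_ab):
    est = si.average_interaction(loglink_fit, "MU", contrast_ab)
    assert est.estimate == pytest.approx(0.7, abs=1e-9)


def test_misalignment_of_ad_under_a_loglink_null(loglink_null_fit, contrast_ab):
    """Zero interaction on the log scale is not zero on the response scale."""
    mu = si.average_interaction(loglink_null_fit, "MU", contrast_ab)
    ad = si.average_interaction(loglink_null_fit, "AD", contrast_ab)
    closed_form = 10 * (np.exp(np.log(0.5)) - 1) * (np.exp(np.log(0.8)) - 1)
    assert mu.estimate == pytest.approx(0.0, abs=1e-9)
    assert ad.estimate == pytest.approx(closed_form, abs=1e-9)
    assert abs(ad.estimate) > 0.5


def test_do_contrast_on_printed_corner_means(factor_terms, contrast_ab):
    corner = {(0, 0): 10.0, (1, 0): 6.0, (0, 1): 4.0, (1, 1): 4.0}
    df = factorial_frame(np.array([corner[(a, b)] for a, b in zip(A, B)]))
    fit = si.fit_model(df, si.ModelSpec("y", factor_terms, "gaussian"))
    assert si.interaction_estimate(fit, "DO", contrast_ab,
                                   {"A": 0, "B": 0}) == pytest.approx(0.0,
                                                                      abs=1e-10)


def test_estimators_symmetric_in_stressor_roles(nb_fit, nb_design):
    _, _, contrast = nb_design
    for nm in ("AD", "MU", "DO"):
        a = si.average_interaction(nb_fit, nm, contrast).estimate
        b = si.average_interaction(nb_fit, nm, contrast.swapped()).estimate
        assert a == pytest.approx(b, rel=1e-10)


def test_relabelling_control_and_stress_flips_the_sign(nb_fit, nb_design):
    _, _, contrast = nb_design
    flipped = si.ContrastSpec(
        si.Stressor("sal", "factor", 1, 0), contrast.stressor_b,
        contrast.step_fraction, contrast.profile)
    for nm in ("AD", "MU"):
        a = si.average_interaction(nb_fit, nm, contrast).estimate
        b = si.average_interaction(nb_fit, nm, flipped).estimate
        assert a == pytest.approx(-b, rel=1e-10)


def test_observationwise_constant_without_covariates(gaussian_fit, contrast_ab):
    vec = si.observationwise_interaction(gaussian_fit, "AD", contrast_ab)
    assert np.ptp(vec) < 1e-12


def test_identity_link_ad_constant_across_covariate_values():
    rng = np.random.default_rng(6)
    cov = rng.normal(size=len(A))
    df = factorial_frame(5 - A + 2 * B + 0.8 * A * B + 0.5 * cov)
    df["cov"] = cov
    fit = si.fit_model(df, si.ModelSpec(
        "y", (si.factor("A"), si.factor("B"), si.linear("cov"),
              si.interaction("A", "B")), "gaussian"))
    con = si.ContrastSpec(si.Stressor("A", "factor", 0, 1),
                          si.Stressor("B", "factor", 0, 1))
    vec = si.observationwise_interaction(fit, "AD", con)
    assert vec == pytest.approx(np.full(len(A), 0.8), abs=1e-9)


def test_gradient_estimates_match_brute_force_corner_oracle(
        poisson_gradient_fit):
    """Row-wise estimates equal direct four-corner prediction differences."""
    fit, contrast, df = poisson_gradient_fit
    got = si.observationwise_interaction(fit, "AD", contrast, df)
    x = df["x"].to_numpy()
    h = contrast.step_fraction * np.ptp(x)
    expected = np.empty(len(df))
    for i, row in df.iterrows():
        mus = {}
        for fa, lv in ((row["x"], "hi"), (row["x"], "lo"),
                       (row["x"] + h, "hi"), (row["x"] + h, "lo")):
            mus[(fa, lv)] = fit.predict_mean(
                pd.DataFrame([{"x": fa, "f": lv}]))[0]
        expected[i] = (mus[(row["x"] + h, "lo")] - mus[(row["x"] + h, "hi")]
                       - mus[(row["x"], "lo")] + mus[(row["x"], "hi")]) / h
    assert got == pytest.approx(expected, abs=1e-6)


def test_gradient_step_halving_converges(poisson_gradient_fit):
    """Richardson-style check: the estimate stabilizes as the step shrinks."""
    fit, contrast, df = poisson_gradient_fit
    row = df.iloc[[3]]
    vals = {}
    for frac in (4e-4, 2e-4, 1e-4):
        con = si.ContrastSpec(contrast.stressor_a, contrast.stressor_b,
                              step_fraction=frac)
        vals[frac] = si.interaction_estimate(fit, "AD", con, row)
    d1 = abs(vals[2e-4] - vals[4e-4])
    d2 = abs(vals[1e-4] - vals[2e-4])
    assert d2 <= 0.75 * d1 + 1e-10


def test_average_equals_mean_of_rowwise_and_single_row(nb_fit, nb_design):
    _, _, contrast = nb_design
    est = si.average_interaction(nb_fit, "AD", contrast)
    vec = si.observationwise_interaction(nb_fit, "AD", contrast)
    assert est.estimate == pytest.approx(np.mean(vec), abs=1e-12)
    one = nb_fit.data.iloc[[0]]
    single = si.average_interaction(nb_fit, "AD", contrast, one)
    assert single.estimate == pytest.approx(
        si.interaction_estimate(nb_fit, "AD", contrast, nb_fit.data.iloc[0]))


def test_grouped_estimates_decompose_the_pooled_mean(nb_fit, nb_design):
    gen, _, contrast = nb_design
    groups = si.grouped_interaction(nb_fit, "AD", contrast, gen.data, "sed")
    pooled = si.average_interaction(nb_fit, "AD", contrast, gen.data)
    sizes = gen.data["sed"].value_counts()
    weighted = sum(groups[lv].estimate * sizes[lv] for lv in groups) / len(gen.data)
    assert pooled.estimate == pytest.approx(weighted, abs=1e-10)
    for lv, est in groups.items():
        manual = si.average_interaction(nb_fit, "AD", contrast,
                                        gen.data[gen.data["sed"] == lv])
        assert est.estimate == pytest.approx(manual.estimate, abs=1e-12)


def test_mu_domain_error_on_nonpositive_corner(factor_terms, contrast_ab):
    corner = {(0, 0): 10.0, (1, 0): 6.0, (0, 1): 4.0, (1, 1): -1.0}
    df = factorial_frame(np.array([corner[(a, b)] for a, b in zip(A, B)]))
    fit = si.fit_model(df, si.ModelSpec("y", factor_terms, "gaussian"))
    with pytest.raises(ValueError, match="MU"):
        si.observationwise_interaction(fit, "MU", contrast_ab)


def test_gradient_step_underflow_raises(poisson_gradient_fit):
    fit, contrast, df = poisson_gradient_fit
    con = si.ContrastSpec(contrast.stressor_a, contrast.stressor_b,
                          step_fraction=1e-300)
    with pytest.raises(StepError, match="step"):
        si.interaction_estimate(fit, "AD", con, df.iloc[[3]])


def test_covariate_profiles_mean_and_representative():
    rng = np.random.default_rng(6)
    cov = rng.normal(size=len(A))
    df = factorial_frame(5 - A + 2 * B + 0.8 * A * B + 1.5 * cov)
    df["cov"] = cov
    fit = si.fit_model(df, si.ModelSpec(
        "y", (si.factor("A"), si.factor("B"), si.linear("cov"),
              si.interaction("A", "B")), "gaussian"))
    mean_prof = si.ContrastSpec(
        si.Stressor("A", "factor", 0, 1), si.Stressor("B", "factor", 0, 1),
        profile=si.CovariateProfile("mean"))
    est = si.average_interaction(fit, "AD", mean_prof)
    assert est.n_obs == 1 and est.estimate == pytest.approx(0.8, abs=1e-9)
    rep = si.ContrastSpec(
        si.Stressor("A", "factor", 0, 1), si.Stressor("B", "factor", 0, 1),
        profile=si.CovariateProfile("representative", {"cov": 2.0}))
    est2 = si.average_interaction(fit, "AD", rep)
    assert est2.estimate == pytest.approx(0.8, abs=1e-9)


def test_both_focal_stressors_must_be_in_the_model(gaussian_fit):
    con = si.ContrastSpec(si.Stressor("A", "factor", 0, 1),
                          si.Stressor("Z", "factor", 0, 1))
    with pytest.raises(ValueError, match="Z"):
        si.observationwise_interaction(gaussian_fit, "AD", con)
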