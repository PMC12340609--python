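"""Model fitting, prediction and covariance contracts."""

import numpy as np
import pandas as pd
import pytest

import stressorint as si
from stressorint.design import UnseenLevelError
from stressorint.model_layer import likelihood_ratio_test
from stressorint.synthetic_data import (gen_factor_gradient_counts,
                                        gen_factorial_counts,
                                        gen_ray_design_binomial)

from conftest import A, B, factorial_frame


def test_noiseless_factorial_recovers_generating_coefficients(gaussian_fit):
    assert gaussian_fit.coefficients == pytest.approx([10, -4, -6, 0.5],
                                                      abs=1e-10)


def test_gaussian_identity_matches_normal_equations():
    rng = np.random.default_rng(4)
    df = factorial_frame(10 - 4 * A - 6 * B + 0.5 * A * B
                         + rng.normal(0, 2, len(A)))
    df["cov"] = rng.normal(size=len(df))
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"), si.linear("cov"),
                              si.interaction("A", "B")), "gaussian")
    fit = si.fit_model(df, spec)
    X = fit.design_matrix(df)
    beta_ols = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
    assert fit.coefficients == pytest.approx(beta_ols, abs=1e-8)


@pytest.mark.parametrize("link,coefs,expected", [
    ("identity", (1.0, 2.0, 0.0, 0.0), 3.0),
    ("log", (np.log(10), np.log(0.5), 0.0, 0.0), 5.0),
])
def test_predict_mean_inverts_the_link(gaussian_fit, link, coefs, expected):
    spec = si.ModelSpec("y", gaussian_fit.spec.terms, "gaussian", link=link)
    model = si.fit_model(gaussian_fit.data, spec)
    row = pd.DataFrame({"A": [1], "B": [0]})
    mu = model.predict_mean(row, coefficients=np.asarray(coefs))
    assert mu[0] == pytest.approx(expected, rel=1e-12)


def test_logit_link_all_zero_coefficients_predict_half():
    df = factorial_frame((A + B) % 2).assign(trials=10, y=5)
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B")), "binomial",
                        trials="trials")
    model = si.fit_model(df, spec)
    rows = pd.DataFrame({"A": [0, 1], "B": [1, 0]})
    mu = model.predict_mean(rows, coefficients=np.zeros(3))
    assert mu == pytest.approx([0.5, 0.5])


def test_predict_on_training_rows_reproduces_fitted_means(nb_fit):
    assert nb_fit.predict_mean(nb_fit.data) == pytest.approx(
        nb_fit.fitted_means, rel=1e-12)


def test_unseen_factor_level_error_names_the_level(gaussian_fit):
    with pytest.raises(UnseenLevelError, match="7"):
        gaussian_fit.predict_mean(pd.DataFrame({"A": [7], "B": [0]}))


def test_family_support_validation():
    df = factorial_frame(np.array([-1.0] * len(A)))
    with pytest.raises(ValueError, match="non-negative"):
        si.fit_model(df, si.ModelSpec("y", (si.factor("A"),), "poisson"))


def test_needs_more_rows_than_coefficients():
    df = pd.DataFrame({"A": [0, 1], "B": [0, 1], "y": [1.0, 2.0]})
    with pytest.raises(ValueError, match="rows"):
        si.fit_model(df, si.ModelSpec(
            "y", (si.factor("A"), si.factor("B"), si.interaction("A", "B")),
            "gaussian"))


def test_covariance_symmetric_and_psd(nb_fit):
    V = nb_fit.covariance()
    assert np.allclose(V, V.T, atol=1e-10)
    assert np.all(np.linalg.eigvalsh(V) > -1e-10)


def test_parametric_unconditional_equals_conditional(nb_fit):
    assert np.array_equal(nb_fit.covariance(), nb_fit.covariance(True))


@pytest.fixture(scope="module")
def gradient_gam():
    gen = gen_factor_gradient_counts(seed=5)
    spec = si.ModelSpec("richness",
                        (si.factor("nut"), si.smooth("chloride", k=8),
                         si.smooth_interaction("chloride", "nut", k=8)),
                        "poisson")
    return si.fit_model(gen.data, spec)


def test_gam_unconditional_covariance_inflates_diagonal(gradient_gam):
    Vc = np.diag(gradient_gam.covariance())
    Vu = np.diag(gradient_gam.covariance(unconditional=True))
    assert np.all(Vu >= Vc - 1e-12)
    assert gradient_gam.edf < len(gradient_gam.coefficients)


def test_deviance_never_increases_with_nested_interaction_term():
    rng = np.random.default_rng(8)
    df = factorial_frame(rng.poisson(np.exp(2.0 + 0.3 * A - 0.2 * B
                                            + 0.2 * A * B)).astype(float))
    base = (si.factor("A"), si.factor("B"))
    small = si.fit_model(df, si.ModelSpec("y", base, "poisson"))
    big = si.fit_model(df, si.ModelSpec(
        "y", base + (si.interaction("A", "B"),), "poisson"))
    assert big.llf >= small.llf - 1e-10
    stat, df_, p = likelihood_ratio_test(big, small)
    wstat, wdf, wp = big.wald_test("A:B")
    assert stat >= 0 and wdf == 1 == df_
    assert abs(np.log10(max(p, 1e-12)) - np.log10(max(wp, 1e-12))) < 1.0


def test_canonical_link_irls_stationarity():
    """For canonical-link GLMs the score X'(y - mu) vanishes at the fit."""
    rng = np.random.default_rng(9)
    df = factorial_frame(rng.poisson(np.exp(2.0 + 0.3 * A)).astype(float))
    fit = si.fit_model(df, si.ModelSpec(
        "y", (si.factor("A"), si.factor("B")), "poisson"))
    X = fit.design_matrix(df)
    score = X.T @ (df["y"].to_numpy() - fit.fitted_means)
    assert score == pytest.approx(np.zeros(X.shape[1]), abs=1e-6)


def test_nb_dispersion_recovered_from_factorial_generator():
    """Median estimated NB size over replicates lands near the truth."""
    theta_true = 12.0
    spec = si.ModelSpec("abundance", (si.factor("sal"), si.factor("sed"),
                                      si.factor("flow")), "negative_binomial")
    estimates = []
    for seed in range(200):
        gen = gen_factorial_counts(dispersion=theta_true, seed=seed)
        try:
            estimates.append(si.fit_model(gen.data, spec).dispersion)
        except si.ConvergenceError:
            continue
    med = np.median(estimates)
    assert len(estimates) > 190
    assert abs(med - theta_true) / theta_true < 0.5


def test_poisson_wald_rejects_near_nominal_rate_under_null():
    """Wald test of a zero interaction coefficient rejects ~5% of the time."""
    rejections = 0
    reps = 400
    n = 500
    rng_a = np.random.default_rng(100)
    Ab = rng_a.integers(0, 2, n)
    Bb = rng_a.integers(0, 2, n)
    mu = np.exp(1.0 + 0.4 * Ab - 0.3 * Bb)
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"),
                              si.interaction("A", "B")), "poisson")
    for seed in range(reps):
        rng = np.random.default_rng([101, seed])
        df = pd.DataFrame({"A": Ab, "B": Bb,
                           "y": rng.poisson(mu).astype(float)})
        _, _, p = si.fit_model(df, spec).wald_test("A:B")
        rejections += p < 0.05
    assert 0.025 < rejections / reps < 0.08


def test_binomial_accepts_counts_or_proportions():
    gen = gen_ray_design_binomial(seed=2)
    terms = (si.linear("dose_a"), si.linear("dose_b"))
    counts = si.fit_model(gen.data, si.ModelSpec("survived", terms, "binomial",
                                                 trials="trials"))
    prop = gen.data.assign(survived=gen.data["survived"] / gen.data["trials"])
    props = si.fit_model(prop, si.ModelSpec("survived", terms, "binomial",
                                            trials="trials"))
    assert counts.coefficients == pytest.approx(props.coefficients, rel=1e-8)


def test_beta_family_logit_only_smoke():
    rng = np.random.default_rng(12)
    x = rng.uniform(0, 1, 80)
    mu = 1 / (1 + np.exp(-(0.5 + 1.5 * x)))
    phi = 30.0
    y = rng.beta(mu * phi, (1 - mu) * phi)
    fit = si.fit_model(pd.DataFrame({"x": x, "y": y}),
                       si.ModelSpec("y", (si.linear("x"),), "beta"))
    assert fit.dispersion > 0
    assert fit.coefficients == pytest.approx([0.5, 1.5], abs=0.6)
    with pytest.raises(ValueError, match="logit"):
        si.fit_model(pd.DataFrame({"x": x, "y": y}),
                     si.ModelSpec("y", (si.linear("x"),), "beta", link="log"))


def test_negative_binomial_rejects_non_log_link(nb_design):
    gen, spec, _ = nb_design
    bad = si.ModelSpec(spec.response, spec.terms, "negative_binomial",
                       link="identity")
    with pytest.raises(ValueError, match="log link"):
        si.fit_model(gen.data, bad)
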