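"""Null-surface extraction, null-true data simulation and the type-I protocol."""

import numpy as np
import pandas as pd
import pytest

import stressorint as si
from stressorint.simulation import (extract_surfaces, null_mean_surface,
                                    simulate_null_dataset, type1_error_study)
from stressorint.synthetic_data import gen_ray_design_binomial

from conftest import A, B, factorial_frame


@pytest.fixture(scope="module")
def additive_truth_fit(contrast_ab):
    df = factorial_frame(10.0 - 2 * A - 3 * B)  # AD-true, noiseless
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"),
                              si.interaction("A", "B")), "gaussian")
    return si.fit_model(df, spec), df


def test_surface_consistency_at_control(additive_truth_fit, contrast_ab):
    fit, df = additive_truth_fit
    surf = extract_surfaces(fit, contrast_ab)
    C = surf.control_mean()
    assert surf.f_A(0) == pytest.approx(C, abs=1e-12)
    assert surf.f_B(0) == pytest.approx(C, abs=1e-12)


def test_factorial_surfaces_take_two_values_per_stressor(additive_truth_fit,
                                                         contrast_ab):
    fit, df = additive_truth_fit
    surf = extract_surfaces(fit, contrast_ab)
    assert len(np.unique(np.round(surf.f_A(df["A"].to_numpy()), 9))) == 2
    assert len(np.unique(np.round(surf.f_B(df["B"].to_numpy()), 9))) == 2


def test_additive_truth_reproduced_by_ad_combination(additive_truth_fit,
                                                     contrast_ab):
    fit, df = additive_truth_fit
    surf = extract_surfaces(fit, contrast_ab)
    means, truncated = null_mean_surface("AD", surf, df)
    assert truncated == 0
    assert means == pytest.approx(fit.fitted_means, abs=1e-9)


def test_null_mean_surface_trivial_points(additive_truth_fit, contrast_ab):
    fit, _ = additive_truth_fit
    surf = extract_surfaces(fit, contrast_ab)
    control = pd.DataFrame({"A": [0], "B": [0]})
    for nm in ("AD", "MU", "DO"):
        m, _ = null_mean_surface(nm, surf, control)
        assert m[0] == pytest.approx(10.0, abs=1e-9)
    joint = pd.DataFrame({"A": [1], "B": [1]})
    ad, _ = null_mean_surface("AD", surf, joint)
    assert ad[0] == pytest.approx(8 + 7 - 10, abs=1e-9)
    do, _ = null_mean_surface("DO", surf, joint)
    assert do[0] == pytest.approx(min(8, 7), abs=1e-9)


def test_poisson_simulation_matches_target_means(contrast_ab):
    rng_df = factorial_frame(np.exp(2.0 - 0.3 * A - 0.2 * B))
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"),
                              si.interaction("A", "B")), "gaussian", link="log")
    fit = si.fit_model(rng_df, spec)
    fit.spec = si.ModelSpec("y", fit.spec.terms, "poisson")  # simulate Poisson
    surf = extract_surfaces(fit, contrast_ab)
    design = pd.concat([rng_df] * 160, ignore_index=True)  # ~10k rows
    sim = simulate_null_dataset("MU", surf, design, seed=17)
    means, _ = null_mean_surface("MU", surf, design)
    for cell in range(4):
        mask = (design["A"] == cell // 2) & (design["B"] == cell % 2)
        mu = means[mask.to_numpy()][0]
        n = int(mask.sum())
        assert sim.loc[mask, "y"].mean() == pytest.approx(
            mu, abs=3 * np.sqrt(mu / n))


def test_negative_binomial_simulation_variance_identity(nb_fit, nb_design,
                                                        contrast_ab):
    gen, _, contrast = nb_design
    surf = extract_surfaces(nb_fit, contrast)
    one = gen.data.iloc[[0]]
    design = pd.concat([one] * 50_000, ignore_index=True)
    sim = simulate_null_dataset("MU", surf, design, seed=23)
    mu, _ = null_mean_surface("MU", surf, one)
    theta = nb_fit.dispersion
    target_var = mu[0] + mu[0] ** 2 / theta
    assert sim[nb_fit.spec.response].var() == pytest.approx(target_var,
                                                            rel=0.10)
    assert sim[nb_fit.spec.response].mean() == pytest.approx(mu[0], rel=0.05)


def test_ad_truncation_is_counted_for_count_families(nb_fit, nb_design):
    """Strong single-stressor effects push AD means below zero; report it."""
    gen, _, _ = nb_design
    harsh = si.ContrastSpec(si.Stressor("sal", "factor", 0, 1),
                            si.Stressor("sed", "factor", 0, 1))
    df = gen.data
    surf = extract_surfaces(nb_fit, harsh)
    C, SA, SB = surf.components(df)
    expect_neg = int(np.sum(SA + SB - C < 0))
    _, truncated = null_mean_surface("AD", surf, df)
    assert truncated == expect_neg


def test_type1_study_deterministic_given_seed(contrast_ab):
    rng = np.random.default_rng(31)
    df = factorial_frame(10 - 2 * A - 3 * B + rng.normal(0, 1.5, len(A)))
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"),
                              si.interaction("A", "B")), "gaussian")
    r1 = type1_error_study(df, spec, contrast_ab, "AD", reps=120, seed=9,
                           kr_draws=500)
    r2 = type1_error_study(df, spec, contrast_ab, "AD", reps=120, seed=9,
                           kr_draws=500)
    assert r1.rate == r2.rate and r1.rejections == r2.rejections
    assert r1.detail == r2.detail
    assert r1.mc_se == pytest.approx(
        np.sqrt(r1.rate * (1 - r1.rate) / r1.reps))


def test_type1_study_invariant_to_stressor_relabelling(contrast_ab):
    rng = np.random.default_rng(32)
    df = factorial_frame(10 - 2 * A - 3 * B + rng.normal(0, 1.5, len(A)))
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"),
                              si.interaction("A", "B")), "gaussian")
    r1 = type1_error_study(df, spec, contrast_ab, "AD", reps=100, seed=4,
                           kr_draws=500)
    r2 = type1_error_study(df, spec, contrast_ab.swapped(), "AD", reps=100,
                           seed=4, kr_draws=500)
    assert r1.rate == r2.rate


def test_zero_effect_surfaces_make_all_null_models_agree(contrast_ab):
    # balanced +/-1 noise: every cell mean is exactly 7, fitted effects exactly 0
    noise = np.tile(np.repeat([1.0, -1.0], 4), len(A) // 8)
    df = factorial_frame(7.0 + noise)
    spec = si.ModelSpec("y", (si.factor("A"), si.factor("B"),
                              si.interaction("A", "B")), "gaussian")
    fit = si.fit_model(df, spec)
    surf = extract_surfaces(fit, contrast_ab)
    sims = [simulate_null_dataset(nm, surf, df, seed=41)["y"].to_numpy()
            for nm in ("AD", "MU", "DO")]
    # identical up to rounding of the (numerically) zero fitted effects
    assert sims[0] == pytest.approx(sims[1], abs=1e-9)
    assert sims[0] == pytest.approx(sims[2], abs=1e-9)


def test_mu_true_ray_design_nominal_with_representable_refit():
    """Type-I error is near nominal when the refit family can represent the
    multiplicative null surface exactly (log-link binomial, so the MU
    estimator reduces to the interaction coefficient)."""
    gen = gen_ray_design_binomial(seed=7)
    spec = si.ModelSpec("survived",
                        (si.linear("dose_a"), si.linear("dose_b"),
                         si.interaction("dose_a", "dose_b")),
                        "binomial", link="log", trials="trials")
    contrast = si.ContrastSpec(si.Stressor("dose_a", "gradient", control=0.0),
                               si.Stressor("dose_b", "gradient", control=0.0))
    res = type1_error_study(gen.data, spec, contrast, "MU", reps=400, seed=13,
                            kr_draws=2000)
    assert 0.02 <= res.rate <= 0.09
    assert res.failures <= 8
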