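import numpy as np
import pandas as pd
import pytest

import stressorint as si
from stressorint.synthetic_data import gen_factorial_counts

# two binary stressors, 16 units per cell layout reused across tests
A = np.tile(np.repeat([0, 1], 2), 16)
B = np.tile([0, 1], 32)


def factorial_frame(y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"A": A, "B": B, "y": y})


@pytest.fixture(scope="session")
def factor_terms():
    return (si.factor("A"), si.factor("B"), si.interaction("A", "B"))


@pytest.fixture(scope="session")
def contrast_ab():
    return si.ContrastSpec(si.Stressor("A", "factor", 0, 1),
                           si.Stressor("B", "factor", 0, 1))


@pytest.fixture(scope="session")
def gaussian_fit(factor_terms):
    """Noiseless gaussian/identity factorial: coefficients (10, -4, -6, 0.5)."""
    df = factorial_frame(10 - 4 * A - 6 * B + 0.5 * A * B)
    return si.fit_model(df, si.ModelSpec("y", factor_terms, "gaussian"))


@pytest.fixture(scope="session")
def loglink_fit(factor_terms):
    """Noiseless log-link factorial: log-scale coefficients incl. beta3=0.7."""
    df = factorial_frame(np.exp(np.log(10) + np.log(0.5) * A
                                + np.log(0.8) * B + 0.7 * A * B))
    return si.fit_model(df, si.ModelSpec("y", factor_terms, "gaussian", link="log"))


@pytest.fixture(scope="session")
def loglink_null_fit(factor_terms):
    """Log-link factorial with interaction coefficient exactly zero."""
    df = factorial_frame(np.exp(np.log(10) + np.log(0.5) * A + np.log(0.8) * B))
    return si.fit_model(df, si.ModelSpec("y", factor_terms, "gaussian", link="log"))


@pytest.fixture(scope="session")
def nb_design():
    """Overdispersed factorial counts plus the three-factor model and contrast."""
    gen = gen_factorial_counts(seed=3)
    spec = si.ModelSpec(
        "abundance",
        (si.factor("sal"), si.factor("sed"), si.factor("flow"),
         si.interaction("sal", "sed"), si.interaction("sal", "flow"),
         si.interaction("sed", "flow"), si.interaction("sal", "sed", "flow")),
        "negative_binomial")
    contrast = si.ContrastSpec(si.Stressor("sal", "factor", 0, 1),
                               si.Stressor("flow", "factor", 0, 1))
    return gen, spec, contrast


@pytest.fixture(scope="session")
def nb_fit(nb_design):
    gen, spec, _ = nb_design
    return si.fit_model(gen.data, spec)


@pytest.fixture(scope="session")
def poisson_gradient_fit():
    """Poisson/log fit with one gradient and one factor stressor."""
    rng = np.random.default_rng(21)
    x = np.tile(np.linspace(0.0, 10.0, 30), 2)
    f = np.repeat(["lo", "hi"], 30)
    mu = np.exp(1.8 + 0.12 * x - 0.4 * (f == "hi") + 0.015 * x * (f == "hi"))
    df = pd.DataFrame({"x": x, "f": f, "y": rng.poisson(mu).astype(float)})
    spec = si.ModelSpec("y", (si.linear("x"), si.factor("f"),
                              si.interaction("x", "f")), "poisson")
    contrast = si.ContrastSpec(si.Stressor("x", "gradient"),
                               si.Stressor("f", "factor", "hi", "lo"))
    return si.fit_model(df, spec), contrast, df
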