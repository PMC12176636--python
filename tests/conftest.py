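import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from twoprocess import ModelParams, preset

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def std_params() -> ModelParams:
    """Standard human set, 24 h cosine forcing, amplitude 0.12."""
    return preset("fig1b")


@pytest.fixture
def unforced_params() -> ModelParams:
    """Standard set with zero circadian amplitude."""
    return preset("fig6a")


def random_valid_params(rng: np.random.Generator, a: float | None = None) -> ModelParams:
    """Draw a parameter set satisfying the ordering invariant.

    Thresholds are placed at interior fractions of the asymptote span so
    that neither perpetual-wake nor perpetual-sleep states are drawn.
    """
    mu_s = rng.uniform(-0.5, 0.5)
    mu = rng.uniform(0.5, 2.0)
    f_lo = rng.uniform(0.05, 0.4)
    f_hi = rng.uniform(0.55, 0.95)
    return ModelParams(
        chi_w=rng.uniform(5.0, 30.0),
        chi_s=rng.uniform(1.0, 10.0),
        H0_plus=mu_s + f_hi * mu,
        H0_minus=mu_s + f_lo * mu,
        a=rng.uniform(0.0, 0.1) * mu if a is None else a,
        mu_w=mu_s + mu,
        mu_s=mu_s,
        T_f=rng.uniform(10.0, 30.0),
    )


@st.composite
def model_params(draw, a_max: float = 0.1) -> ModelParams:
    """Hypothesis strategy for valid parameter sets."""
    mu_s = draw(st.floats(-0.5, 0.5))
    mu = draw(st.floats(0.5, 2.0))
    f_lo = draw(st.floats(0.05, 0.4))
    f_hi = draw(st.floats(0.55, 0.95))
    return ModelParams(
        chi_w=draw(st.floats(5.0, 30.0)),
        chi_s=draw(st.floats(1.0, 10.0)),
        H0_plus=mu_s + f_hi * mu,
        H0_minus=mu_s + f_lo * mu,
        a=draw(st.floats(0.0, a_max)) * mu,
        mu_w=mu_s + mu,
        mu_s=mu_s,
        T_f=draw(st.floats(10.0, 30.0)),
    )
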