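import numpy as np
import pytest

from ooidgrowth import ModelParams, NutrientParams


@pytest.fixture
def params():
    """Defaults: limiting-size and finite-upper-bound regimes both hold."""
    return ModelParams(k_m=0.5, k_b=0.1, k_b_I=1.0, k_b_II=0.2, c=1.0)


@pytest.fixture
def nutrients():
    """Unit outer-layer width: w = sqrt(2*0.5*1/1) = 1."""
    return NutrientParams(c_I=0.5, c_II=1.0, D=1.0, k=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20180111)


def draw_limiting_regime_params(rng, with_geometry=False, finite_upper=False):
    """Random parameter draw guaranteed to be in the limiting-size regime.

    Samples rates and the volume scale over two decades, then rejects draws
    with c*k_b_I <= k_m (and, if ``finite_upper``, draws whose upper bound is
    not finite).  Optionally appends a random layer width and mineral volume
    for cubic-root sweeps.
    """
    while True:
        k_b_I = 10.0 ** rng.uniform(-1, 1)
        c = 10.0 ** rng.uniform(-1, 1)
        k_m = 10.0 ** rng.uniform(-2, 1)
        k_b_II = 10.0 ** rng.uniform(-2, 0)
        if c * k_b_I - k_m <= 1e-6:
            continue
        if finite_upper and c * k_b_I - k_m - c * k_b_II <= 1e-6:
            continue
        break
    p = ModelParams(
        k_m=k_m,
        k_b=10.0 ** rng.uniform(-2, 0),
        k_b_I=k_b_I,
        k_b_II=k_b_II,
        c=c,
    )
    if not with_geometry:
        return p
    w = 10.0 ** rng.uniform(-1, 1)
    V_m = 10.0 ** rng.uniform(-2, 2)
    return p, w, V_m
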