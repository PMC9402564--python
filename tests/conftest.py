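import numpy as np
import pytest

from afhomeo import ModelParams, dispersion_coefficients_closed_form


@pytest.fixture
def default_params():
    """Reference parameter set (N=1000, T=309.5 K, V=6e-16 m^3, lam=0.2,
    a=10, f0=1 pN, l0=80, kb'/kb=4, m=N)."""
    return ModelParams()


@pytest.fixture
def default_geom(default_params):
    return dispersion_coefficients_closed_form(default_params.a,
                                               default_params.m)


@pytest.fixture
def rng():
    return np.random.default_rng(20220824)
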