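import numpy as np
import pytest

from geltrap import DimensionlessParameters, from_dimensionless


@pytest.fixture
def fast_exchange_point():
    """Strong-trapping point: fast anchor-matrix exchange, many sites."""
    return DimensionlessParameters(
        d_ratio=20.0, N=15, tau_ratio=20.0, conc_dimless=10.0, phi=0.3, C=1.0)


@pytest.fixture
def permanent_anchor_point():
    """Permanently matrix-bound anchors (phi = 0), slow matrix kinetics."""
    return DimensionlessParameters(
        d_ratio=20.0, N=15, tau_ratio=0.01, conc_dimless=2.0, phi=0.0, C=1.0)


@pytest.fixture
def permanent_anchor_params(permanent_anchor_point):
    return from_dimensionless(permanent_anchor_point)


def random_dimensionless(rng: np.random.Generator, n_max: int = 15) -> DimensionlessParameters:
    """A random valid interior parameter point for property sweeps."""
    return DimensionlessParameters(
        d_ratio=float(rng.uniform(2.0, 40.0)),
        N=int(rng.integers(1, n_max + 1)),
        tau_ratio=float(rng.uniform(0.05, 50.0)),
        conc_dimless=float(rng.uniform(0.2, 12.0)),
        phi=float(rng.uniform(0.02, 0.98)),
        C=1.0,
    )
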