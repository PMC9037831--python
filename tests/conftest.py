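import numpy as np
import pytest

from flexsaxs.core import ScatteringProfile
from flexsaxs.synthetic_data import SurrogateSpec, build_antibody_surrogate


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Analytic scattering of a homogeneous sphere (form factor squared)."""
    x = np.asarray(q) * radius
    F = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return i0 * F**2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form P(r) of a homogeneous sphere (unnormalized r^2 gamma(r))."""
    u = np.asarray(r) / radius
    gamma = np.clip(1.0 - 0.75 * u + u**3 / 16.0, 0.0, None)
    gamma[np.asarray(r) > 2 * radius] = 0.0
    return r**2 * gamma


def make_profile(q, I, rel_sigma=1e-5, metadata=None) -> ScatteringProfile:
    I = np.asarray(I, dtype=float)
    return ScatteringProfile(q, I, rel_sigma * np.abs(I), metadata or {})


@pytest.fixture(scope="session")
def sphere50():
    """Noiseless analytic sphere, R = 50 A, with tiny statistical weights."""
    q = np.linspace(0.004, 0.30, 400)
    return make_profile(q, sphere_intensity(q, 50.0, 1e6), rel_sigma=1e-5)


@pytest.fixture(scope="session")
def surrogate():
    """Default antibody surrogate (session-scoped; treat as read-only)."""
    return build_antibody_surrogate(SurrogateSpec())


@pytest.fixture(scope="session")
def surrogate_spec():
    return SurrogateSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
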