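import numpy as np
import pytest

from contractionmodes.containers import IntensityMatrix, ModeBasis


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_detrended(values, dt=3.0):
    values = np.asarray(values, dtype=float)
    values = values - values.mean(axis=1, keepdims=True)
    return IntensityMatrix(values=values, dt=dt, stage="detrended")


@pytest.fixture
def quadrature_tube_basis():
    """Two orthonormal Fourier-like modes with quadrature coefficients,
    composing a wave traveling toward -x."""
    n_x, T, dt = 64, 400, 3.0
    t = np.arange(T) * dt
    om = 2 * np.pi / 100.0
    x = np.linspace(0, 1, n_x)
    phi1 = np.sin(2 * np.pi * x)
    phi2 = np.cos(2 * np.pi * x)
    phi1 /= np.linalg.norm(phi1)
    phi2 /= np.linalg.norm(phi2)
    return ModeBasis(
        modes=np.column_stack([phi1, phi2]),
        eigenvalues=np.array([1.0, 1.0]),
        coefficients=np.vstack([np.cos(om * t), np.sin(om * t)]),
        temporal_mean=np.zeros(n_x),
        dt=dt,
    )
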