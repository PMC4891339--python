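"""Shared fixtures: small grids, analytic fields, phantom specs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from svfmorph import ScalarImage, Svf


def centered_coords(n: int) -> np.ndarray:
    """(n, n, n, 3) voxel coordinates relative to the grid center."""
    c = (n - 1) / 2.0
    return np.stack(np.meshgrid(*[np.arange(n, dtype=float)] * 3,
                                indexing="ij"), axis=-1) - c


def linear_svf(n: int, A: np.ndarray) -> Svf:
    """v(x) = A (x - center): exp has closed form via the matrix exponential."""
    return Svf(centered_coords(n) @ np.asarray(A, dtype=float).T)


def smooth_random_svf(n: int, max_norm: float, seed: int = 0,
                      scale: float = 4.0) -> Svf:
    """Smooth zero-boundary random field with given maximum voxel norm."""
    rng = np.random.default_rng(seed)
    data = np.stack([gaussian_filter(rng.standard_normal((n, n, n)), scale,
                                     mode="constant") for _ in range(3)],
                    axis=-1)
    w = np.hanning(n)
    window = w[:, None, None] * w[None, :, None] * w[None, None, :]
    data *= window[..., None]
    norms = np.sqrt((data ** 2).sum(-1))
    data *= max_norm / max(norms.max(), 1e-12)
    return Svf(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def ramp16() -> ScalarImage:
    """Linear-ramp image: exact under linear interpolation."""
    idx = np.arange(16, dtype=float)
    data = (idx[:, None, None] * 1.0 + idx[None, :, None] * 2.0
            + idx[None, None, :] * 0.5)
    return ScalarImage(data)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 32-cubed phantom and mask, shared across tests."""
    from svfmorph.synthetic import PhantomSpec, make_baseline
    spec = PhantomSpec(shape=(32, 32, 32), noise_sd=0.0, bias_amplitude=0.0,
                       rim_amplitude=0.0, seed=5)
    img, mask = make_baseline(spec)
    return spec, img, mask
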