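"""Toroidal geometry and normalized sampling densities.

All functions treat points as arrays of shape ``(..., 2)`` with
coordinates in ``[0, L)``.  The wrapped Gaussian density sums image terms
over enough periodic copies that the truncation error is below 1e-12.
"""

from __future__ import annotations

import math

import numpy as np

from .params import SamplingKernel

__all__ = ["torus_distance", "kernel_density", "wrap_brownian_step"]


def torus_distance(a, b, L: float) -> np.ndarray:
    """Minimum-image Euclidean distance between points on the torus."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.abs(a - b) % L
    d = np.minimum(d, L - d)
    return np.sqrt((d**2).sum(axis=-1))


def _wrapped_normal_1d(delta: np.ndarray, width: float, L: float) -> np.ndarray:
    """Wrapped normal density along one axis; ``delta`` is the raw offset."""
    n_images = int(math.ceil(6.0 * width / L)) + 1
    ks = np.arange(-n_images, n_images + 1)
    # shape (..., n_images)
    z = delta[..., None] + ks * L
    return np.exp(-z**2 / (2.0 * width**2)).sum(axis=-1) / (width * math.sqrt(2.0 * math.pi))


def kernel_density(kernel: SamplingKernel, p, L: float) -> np.ndarray:
    """Sampling density per unit area at point(s) ``p``.

    Integrates to 1 over the habitat.  For ``kind="uniform"`` this is
    ``1 / L**2`` everywhere; for ``kind="gaussian"`` it is the product of
    two wrapped normal densities centred on ``kernel.center``.
    """
    p = np.asarray(p, dtype=float)
    if kernel.kind == "uniform":
        return np.broadcast_to(np.asarray(1.0 / L**2), p.shape[:-1]).copy()
    cx, cy = kernel.center
    w = float(kernel.width)
    dx = (p[..., 0] - cx + L / 2.0) % L - L / 2.0
    dy = (p[..., 1] - cy + L / 2.0) % L - L / 2.0
    return _wrapped_normal_1d(dx, w, L) * _wrapped_normal_1d(dy, w, L)


def wrap_brownian_step(p, dt: float, sigma: float, L: float, rng: np.random.Generator):
    """Advance point(s) by ``dt`` generations of isotropic diffusion.

    Each axis receives an independent Gaussian increment with variance
    ``(sigma**2 / 2) * dt``, so the RMS two-dimensional displacement over
    one generation is ``sigma``.  Results wrap modulo ``L``.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    p = np.asarray(p, dtype=float)
    if dt == 0:
        return p.copy()
    sd = sigma * math.sqrt(dt / 2.0)
    return (p + rng.normal(0.0, sd, size=p.shape)) % L
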