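"""Regularized step functions, the localization kernel, and difference operators.

These are the numeric primitives shared by every energy term: the smooth
Heaviside/Dirac pair that selects the interior of the contour, the truncated
Gaussian window that localizes the region statistics, and plain
central-difference gradient/curvature/Laplacian operators.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelWindow",
    "heaviside_eps",
    "dirac_eps",
    "gaussian_kernel",
    "grad",
    "grad_norm",
    "curvature",
    "laplacian",
]

#: floor applied to |grad phi| before dividing (flat regions of phi)
CURVATURE_FLOOR = 1e-8


def heaviside_eps(x, eps_h: float):
    """Smooth Heaviside: 0 below -eps_h, 1 above +eps_h, arctan ramp between.

    H(x) = [1 + 2*arctan(x/eps_h)/pi] / 2 on [-eps_h, eps_h]; continuous and
    non-decreasing. ``eps_h`` is the half-width (in level-set units, i.e.
    pixels) over which the interior indicator is smeared.
    """
    if eps_h <= 0:
        raise ValueError(f"eps_h must be > 0, got {eps_h}")
    x = np.asarray(x, dtype=float)
    ramp = 0.5 * (1.0 + 2.0 * np.arctan(x / eps_h) / np.pi)
    out = np.where(x > eps_h, 1.0, np.where(x < -eps_h, 0.0, ramp))
    return float(out) if out.ndim == 0 else out


def dirac_eps(x, eps_h: float):
    """Regularized Dirac delta: (1/pi) * eps_h / (eps_h**2 + x**2).

    The derivative of the arctan ramp of :func:`heaviside_eps`; even in x,
    positive everywhere, maximal at x = 0.
    """
    if eps_h <= 0:
        raise ValueError(f"eps_h must be > 0, got {eps_h}")
    x = np.asarray(x, dtype=float)
    out = (eps_h / np.pi) / (eps_h * eps_h + x * x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class KernelWindow:
    """Truncated, renormalized Gaussian stencil used to localize statistics.

    Attributes
    ----------
    sigma : kernel scale in pixels.
    radius : truncation half-width; the stencil covers (2*radius+1)**2 offsets.
    weights : 2-D array of non-negative weights summing to 1.
    weights_1d : 1-D profile such that ``weights == outer(weights_1d, weights_1d)``
        (the truncated square window keeps the Gaussian exactly separable).
    """

    sigma: float
    radius: int
    weights: np.ndarray = field(repr=False)
    weights_1d: np.ndarray = field(repr=False)


def gaussian_kernel(sigma: float, radius: int | None = None) -> KernelWindow:
    """Discrete Gaussian window, truncated at ``radius`` (default ceil(2*sigma)).

    Weights are samples of exp(-d^2 / 2 sigma^2) renormalized to sum to 1;
    the 1/(2 pi sigma^2) factor cancels in the normalization.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if radius is None:
        radius = int(math.ceil(2.0 * sigma))
    radius = max(int(radius), 1)
    d = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(d * d) / (2.0 * sigma * sigma))
    g /= g.sum()
    weights = np.outer(g, g)
    return KernelWindow(sigma=float(sigma), radius=radius, weights=weights, weights_1d=g)


def _check_grid(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] < 3 or phi.shape[1] < 3:
        raise ValueError(f"field must be 2-D with >= 3 pixels per axis, got shape {phi.shape}")
    return phi


def grad(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(d/drow, d/dcol) by central differences, one-sided at borders."""
    phi = _check_grid(phi)
    gr, gc = np.gradient(phi)
    return gr, gc


def grad_norm(phi: np.ndarray) -> np.ndarray:
    gr, gc = grad(phi)
    return np.hypot(gr, gc)


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|), with the norm floored to avoid 0/0."""
    gr, gc = grad(phi)
    norm = np.maximum(np.hypot(gr, gc), CURVATURE_FLOOR)
    nr = gr / norm
    nc = gc / norm
    return np.gradient(nr, axis=0) + np.gradient(nc, axis=1)


def laplacian(phi: np.ndarray) -> np.ndarray:
    phi = _check_grid(phi)
    gr, gc = np.gradient(phi)
    return np.gradient(gr, axis=0) + np.gradient(gc, axis=1)
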