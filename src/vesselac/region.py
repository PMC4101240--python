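"""Localized region energy: fitting means f1/f2, data force, total energy.

The data model: around every point x near the contour, intensities are
summarized by two kernel-weighted means — f1(x) over the current interior
{phi < 0} and f2(x) over the exterior — and the contour moves so each pixel
joins the region whose local mean fits its intensity better. Because the
kernel weights decay with distance, the means track slowly varying
brightness (intensity inhomogeneity) that defeats global two-phase models,
and because the energy is collected only along the curve (the regularized
delta factor), the statistics stay local to the boundary being refined.

The data force is the kernel-localized binary-fitting gradient flow:

    dphi/dt(z) = delta(phi(z)) * [lambda1 * sum_x K(z, x) (I(z) - f1(x))^2
                                  - lambda2 * sum_x K(z, x) (I(z) - f2(x))^2]
               + v  * delta(phi(z)) * div(grad phi / |grad phi|)
               + mu * (lap phi(z) - div(grad phi / |grad phi|))

i.e. the pixel's own intensity I(z) is compared against the fitting means of
all nearby points x under the kernel; the regularized delta restricts where
the data force acts to the vicinity of the curve. A positive value pushes z
toward the exterior; the flow settles where I(z) sits halfway between the
local interior and exterior means — the local edge.

Numerics: the truncated Gaussian window is exactly separable, so every
kernel-weighted sum is computed on the full grid by two 1-D convolutions
(zero padding realizes the stencil clipped at the image border; numerator
and denominator of any weighted mean clip identically, so means stay
exact). ``at_points`` arguments select output pixels from that full-grid
computation, which makes restricted evaluation trivially identical to the
unrestricted one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .calculus import KernelWindow, curvature, dirac_eps, grad, heaviside_eps, laplacian

__all__ = [
    "EnergyWeights",
    "FittingFields",
    "kernel_convolve",
    "compute_fitting_means",
    "lrf_force",
    "total_energy",
]

#: denominators below this are treated as vanished interior/exterior mass
DENOM_GUARD = 1e-10


@dataclass(frozen=True)
class EnergyWeights:
    """Scalar weights of the energy functional.

    lambda1/lambda2 weight the interior/exterior squared residuals (kept
    equal by default so neither region is favored), ``v`` weights the
    contour-length penalty, ``mu`` the distance-regularization term that
    keeps ``|grad phi|`` near 1.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    v: float = 0.2
    mu: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "v", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FittingFields:
    """Per-pixel local interior (f1) and exterior (f2) weighted mean intensities.

    Where the interior or exterior kernel mass vanished (deep inside or
    outside the contour), the value falls back to the plain kernel-weighted
    mean of the image — there the two residuals cancel, so the fallback
    keeps the force defined without biasing it — and ``defined_mask`` is
    False. When computed at selected points only, other pixels hold NaN.
    """

    f1: np.ndarray
    f2: np.ndarray
    defined_mask: np.ndarray


def kernel_convolve(kernel: KernelWindow, field: np.ndarray) -> np.ndarray:
    """Kernel-weighted sums of ``field`` at every pixel, border-clipped."""
    g = kernel.weights_1d
    tmp = convolve1d(np.asarray(field, dtype=float), g, axis=0, mode="constant", cval=0.0)
    return convolve1d(tmp, g, axis=1, mode="constant", cval=0.0)


def _select(full: np.ndarray, at_points):
    if at_points is None:
        return full
    rows = np.asarray(at_points[0], dtype=np.intp)
    cols = np.asarray(at_points[1], dtype=np.intp)
    if rows.size == 0:
        raise ValueError("at_points must be non-empty")
    out = np.full(full.shape, np.nan)
    out[rows, cols] = full[rows, cols]
    return out


def compute_fitting_means(
    image: np.ndarray,
    phi: np.ndarray,
    kernel: KernelWindow,
    eps_h: float = 1.0,
    at_points: tuple[np.ndarray, np.ndarray] | None = None,
) -> FittingFields:
    """Local interior/exterior kernel-weighted mean intensities.

    f1(x) = sum_y K(x,y) Hin(phi(y)) I(y) / sum_y K(x,y) Hin(phi(y)) over
    the stencil clipped to the image, and f2 the analogue with 1 - Hin.
    The interior is {phi < 0}, so the interior indicator is Hin = H(-phi)
    and f1 is the interior mean.
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if image.shape != phi.shape:
        raise ValueError(f"image {image.shape} and phi {phi.shape} shapes differ")
    h_in = heaviside_eps(-phi, eps_h)
    h_out = 1.0 - h_in

    den1 = kernel_convolve(kernel, h_in)
    num1 = kernel_convolve(kernel, h_in * image)
    den2 = kernel_convolve(kernel, h_out)
    num2 = kernel_convolve(kernel, h_out * image)

    defined = (den1 >= DENOM_GUARD) & (den2 >= DENOM_GUARD)
    plain_num = kernel_convolve(kernel, image)
    plain_den = kernel_convolve(kernel, np.ones_like(image))
    fallback = plain_num / np.maximum(plain_den, DENOM_GUARD)
    f1 = np.where(den1 >= DENOM_GUARD, num1 / np.where(den1 >= DENOM_GUARD, den1, 1.0), fallback)
    f2 = np.where(den2 >= DENOM_GUARD, num2 / np.where(den2 >= DENOM_GUARD, den2, 1.0), fallback)

    if at_points is None:
        return FittingFields(f1=f1, f2=f2, defined_mask=defined)
    sel_mask = np.zeros(image.shape, dtype=bool)
    rows = np.asarray(at_points[0], dtype=np.intp)
    cols = np.asarray(at_points[1], dtype=np.intp)
    if rows.size == 0:
        raise ValueError("at_points must be non-empty")
    sel_mask[rows, cols] = True
    return FittingFields(
        f1=_select(f1, at_points),
        f2=_select(f2, at_points),
        defined_mask=defined & sel_mask,
    )


def lrf_force(
    image: np.ndarray,
    phi: np.ndarray,
    fits: FittingFields,
    kernel: KernelWindow,
    eps_h: float,
    weights: EnergyWeights,
    at_points: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Localized-region gradient flow (see module doc for the formula).

    ``fits`` must cover the full grid: the force at z sums over every
    neighbor x under the kernel, i.e. f1/f2 enter as fields, not only at
    the evaluated pixels. Returns a full-shape array; with ``at_points``
    given, unrequested pixels are NaN.
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if image.shape != phi.shape:
        raise ValueError("image and phi shapes differ")
    if not (np.all(np.isfinite(fits.f1)) and np.all(np.isfinite(fits.f2))):
        raise ValueError(
            "fitting means must be finite on the full grid "
            "(compute them with at_points=None)"
        )

    delta = dirac_eps(phi, eps_h)
    # expand sum_x K(z,x) (I(z) - f_i(x))^2 in powers of I(z):
    #   I(z)^2 conv(K, 1) - 2 I(z) conv(K, f_i) + conv(K, f_i^2)
    a0 = kernel_convolve(kernel, np.ones_like(image))
    l1, l2 = weights.lambda1, weights.lambda2
    b = kernel_convolve(kernel, l1 * fits.f1 - l2 * fits.f2)
    c = kernel_convolve(kernel, l1 * fits.f1 ** 2 - l2 * fits.f2 ** 2)
    data = delta * ((l1 - l2) * image * image * a0 - 2.0 * image * b + c)

    kappa = curvature(phi)
    lap = laplacian(phi)
    force = data + weights.v * delta * kappa + weights.mu * (lap - kappa)
    return _select(force, at_points)


def total_energy(
    image: np.ndarray,
    phi: np.ndarray,
    kernel: KernelWindow,
    eps_h: float,
    weights: EnergyWeights,
    return_parts: bool = False,
):
    """Discretized total energy (pixel area 1): data + length + regularization.

    E = sum_x delta(phi(x)) sum_y K(x,y) [l1 Hin(y)(I(y)-f1(x))^2
                                          + l2 Hout(y)(I(y)-f2(x))^2]
        + v sum_x delta(phi(x)) |grad phi(x)|
        + mu sum_x (|grad phi(x)| - 1)^2 / 2
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if image.shape != phi.shape:
        raise ValueError("image and phi shapes differ")

    fits = compute_fitting_means(image, phi, kernel, eps_h)
    f1, f2 = fits.f1, fits.f2
    h_in = heaviside_eps(-phi, eps_h)
    h_out = 1.0 - h_in
    c_h = kernel_convolve(kernel, h_in)
    c_hi = kernel_convolve(kernel, h_in * image)
    c_hi2 = kernel_convolve(kernel, h_in * image * image)
    c_g = kernel_convolve(kernel, h_out)
    c_gi = kernel_convolve(kernel, h_out * image)
    c_gi2 = kernel_convolve(kernel, h_out * image * image)

    # sum_y K Hin (I - f1)^2 = c_hi2 - 2 f1 c_hi + f1^2 c_h, ditto exterior
    t1 = c_hi2 - 2.0 * f1 * c_hi + f1 * f1 * c_h
    t2 = c_gi2 - 2.0 * f2 * c_gi + f2 * f2 * c_g
    delta = dirac_eps(phi, eps_h)
    e_data = float(np.sum(delta * (weights.lambda1 * t1 + weights.lambda2 * t2)))

    gr, gc = grad(phi)
    norm = np.hypot(gr, gc)
    e_len = weights.v * float(np.sum(delta * norm))
    e_reg = weights.mu * float(np.sum(0.5 * (norm - 1.0) ** 2))

    if return_parts:
        return {"data": e_data, "length": e_len, "regularization": e_reg,
                "total": e_data + e_len + e_reg}
    return e_data + e_len + e_reg
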