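"""Contour- and mask-based evaluation: the MRMSE boundary metric and Dice.

MRMSE (modified root mean squared error) compares a truth boundary point set
with an evolved one: each truth point is matched to its nearest evolved
point inside a (2r+1) x (2r+1) window; matched pairs contribute their squared
distance, and every unmatched point on either side contributes a 2*r^2
penalty. The printed formula takes no square root — despite the name, the
value is a mean of squared pixel distances (plus penalties), and that is
what this module computes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import mask_to_contours

__all__ = ["MRMSEResult", "mrmse", "dice", "mask_mrmse", "boundary_points"]


@dataclass(frozen=True)
class MRMSEResult:
    """value: the metric (squared-pixel units); k1 matched truth points,
    k2 unmatched truth points, k3 unmatched evolved points; r window radius."""

    value: float
    k1: int
    k2: int
    k3: int
    r: float


def mrmse(truth: np.ndarray, evolved: np.ndarray, r: float = 12.0) -> MRMSEResult:
    """Boundary distance between two point sets.

    Matching is nearest-within-window and many-to-one: several truth points
    may share one evolved point. ``k3`` counts evolved points that were never
    selected as any truth point's nearest AND have no truth point within
    their own window.

    value = [sum of matched squared distances + 2 (k2 + k3) r^2] / (k1 + k2 + k3)
    """
    if r < 1:
        raise ValueError("window radius r must be >= 1")
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    evolved = np.asarray(evolved, dtype=float).reshape(-1, 2)
    n, m = len(truth), len(evolved)
    if n == 0 and m == 0:
        raise ValueError("MRMSE is undefined for two empty point sets")
    if n == 0:
        return MRMSEResult(value=2.0 * r * r, k1=0, k2=0, k3=m, r=r)
    if m == 0:
        return MRMSEResult(value=2.0 * r * r, k1=0, k2=n, k3=0, r=r)

    dr = truth[:, None, 0] - evolved[None, :, 0]
    dc = truth[:, None, 1] - evolved[None, :, 1]
    in_window = (np.abs(dr) <= r) & (np.abs(dc) <= r)
    d2 = dr * dr + dc * dc

    selected = np.zeros(m, dtype=bool)
    matched_d2_sum = 0.0
    k1 = 0
    d2_masked = np.where(in_window, d2, np.inf)
    best = np.argmin(d2_masked, axis=1)
    has_match = in_window[np.arange(n), best]
    for i in np.nonzero(has_match)[0]:
        j = best[i]
        matched_d2_sum += d2[i, j]
        selected[j] = True
        k1 += 1
    k2 = n - k1
    evolved_sees_truth = in_window.any(axis=0)
    k3 = int(np.count_nonzero(~selected & ~evolved_sees_truth))

    denom = k1 + k2 + k3
    value = (matched_d2_sum + 2.0 * (k2 + k3) * r * r) / denom
    return MRMSEResult(value=float(value), k1=k1, k2=k2, k3=k3, r=r)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    total = int(mask_a.sum()) + int(mask_b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / total


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel boundary point set of a binary mask, as an (n, 2) array."""
    contours = mask_to_contours(mask)
    if not contours:
        return np.empty((0, 2))
    return np.vstack([c.points for c in contours])


def mask_mrmse(truth_mask: np.ndarray, pred_mask: np.ndarray, r: float = 12.0) -> MRMSEResult:
    """MRMSE between two masks, both boundaries traced the identical way."""
    return mrmse(boundary_points(truth_mask), boundary_points(pred_mask), r=r)
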