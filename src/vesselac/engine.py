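"""Level-set evolution: narrowband updates, steady-point freezing, stopping.

One iteration does, in order: recompute the local fitting means f1/f2 on the
narrowband, evaluate the localized-region force plus the VVF force, take an
explicit Euler step of phi on the band, refresh the per-pixel
sign-stability counters, rebuild the band, and freeze pixels whose
segmentation label has been stable long enough.

Acceleration is strictly an optimization, not a model change:

* the band restriction reuses the exact full-grid computation path, so a
  banded step equals the full step at band pixels bitwise;
* frozen pixels are removed from the band permanently; the freeze guard
  (|phi| >= rho/2) keeps pixels sitting on the contour itself from being
  frozen while their position is still settling.

The run stops when the fraction of band pixels changing sign stays below
``stop_frac`` for ``stop_patience`` consecutive iterations, when the band
empties (everything frozen or no zero crossing left), or at ``max_iters``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter

from .calculus import KernelWindow, gaussian_kernel, grad
from .config import RunConfig
from .image import Contour, default_sigma, extract_zero_contour
from .initialize import InitParams, init_level_set, rough_vessel_mask
from .region import EnergyWeights, compute_fitting_means, lrf_force, total_energy
from .vesselness import VesselnessField, multiscale_vesselness, vvf_direction, vvf_force, vvf_speed

__all__ = [
    "EvolutionState",
    "SegmentationResult",
    "build_narrowband",
    "evolve_step",
    "update_freeze_labels",
    "run",
]


@dataclass
class EvolutionState:
    """Mutable state of one evolution: phi plus the acceleration bookkeeping."""

    phi: np.ndarray
    band: np.ndarray  # bool mask of active pixels
    frozen: np.ndarray  # bool mask, permanent
    steady_history: np.ndarray  # consecutive iterations without motion
    prev_sign: np.ndarray  # phi < 0 after the last step
    iteration: int = 0
    sign_change_fractions: list = field(default_factory=list)
    energy_trace: list = field(default_factory=list)


def build_narrowband(
    phi: np.ndarray, band_width: int, frozen: np.ndarray | None = None
) -> np.ndarray:
    """Non-frozen pixels within Chebyshev distance ``band_width`` of a sign change.

    A sign change is any 4-adjacent pair of pixels with differing sign of
    phi; pixels exactly on the zero set count as well.
    """
    phi = np.asarray(phi, dtype=float)
    sg = np.sign(phi)
    edge = sg == 0
    horiz = sg[:, 1:] != sg[:, :-1]
    vert = sg[1:, :] != sg[:-1, :]
    edge[:, 1:] |= horiz
    edge[:, :-1] |= horiz
    edge[1:, :] |= vert
    edge[:-1, :] |= vert
    band = maximum_filter(edge, size=2 * band_width + 1, mode="constant", cval=False)
    if frozen is not None:
        band &= ~frozen
    return band


def _vvf_cache(vess: VesselnessField, cfg: RunConfig):
    """phi-independent VVF pieces: gated direction and speed, computed once."""
    fR = vvf_speed(vess.R, cfg.eps_v)
    return vess, fR


def evolve_step(
    state: EvolutionState,
    image: np.ndarray,
    kernel: KernelWindow,
    vvf_cache,
    cfg: RunConfig,
) -> EvolutionState:
    """One explicit Euler step of phi on the current band (in place).

    ``vvf_cache`` is the pair (VesselnessField, f_eps(R)) or None to disable
    the VVF term. The sign alignment of the VVF is refreshed every step
    because it depends on grad(phi).
    """
    if state.phi.shape != image.shape or state.band.shape != image.shape:
        raise ValueError("state and image shapes are inconsistent")
    if np.any(state.band & state.frozen):
        raise ValueError("inconsistent state: band overlaps frozen pixels")

    band_before = state.band
    pts = np.nonzero(band_before)
    update = np.zeros(0)
    if pts[0].size > 0:
        fits = compute_fitting_means(image, state.phi, kernel, cfg.eps_h)
        weights = EnergyWeights(lambda1=cfg.lambda1, lambda2=cfg.lambda2, v=cfg.v, mu=cfg.mu)
        force = lrf_force(image, state.phi, fits, kernel, cfg.eps_h, weights)
        update = force[pts]
        if vvf_cache is not None and cfg.lam_vvf != 0.0:
            vess, fR = vvf_cache
            gphi = grad(state.phi)
            V = vvf_direction(vess, gphi, cfg.tau)
            fv = vvf_force(V, fR, gphi, cfg.lam_vvf)
            update = update + fv[pts]
        state.phi[pts] += cfg.dt * update

    new_sign = state.phi < 0
    changed = new_sign ^ state.prev_sign
    n_band = int(band_before.sum())
    frac = float(changed[band_before].sum()) / n_band if n_band else 0.0
    state.sign_change_fractions.append(frac)
    moved = changed.copy()
    if pts[0].size > 0:
        moved[pts] |= np.abs(cfg.dt * update) >= cfg.steady_tol
    state.steady_history = np.where(moved, 0, state.steady_history + 1)
    state.prev_sign = new_sign
    state.band = build_narrowband(state.phi, cfg.band_width, state.frozen)
    state.iteration += 1
    return state


def update_freeze_labels(state: EvolutionState, M: int | None, rho: float) -> EvolutionState:
    """Permanently freeze band pixels steady for M iterations with |phi| >= rho/2.

    A pixel is steady in an iteration when its sign did not change and its
    update stayed below ``steady_tol`` — "did not move" at sub-pixel
    resolution, so advancing fronts are never frozen ahead of themselves.
    The |phi| >= rho/2 guard keeps pixels sitting on the contour itself
    active even when their position has settled.
    """
    if M is None:
        return state
    newly = state.band & (state.steady_history >= M) & (np.abs(state.phi) >= 0.5 * rho)
    if np.any(newly):
        state.frozen |= newly
        state.band &= ~newly
    return state


@dataclass
class SegmentationResult:
    phi: np.ndarray
    contours: list
    mask: np.ndarray  # phi < 0
    energy_trace: list
    iterations: int
    stop_reason: str
    init_mask: np.ndarray
    frozen: np.ndarray
    vesselness: VesselnessField | None


def _initial_state(phi: np.ndarray, cfg: RunConfig) -> EvolutionState:
    frozen = np.zeros(phi.shape, dtype=bool)
    return EvolutionState(
        phi=phi,
        band=build_narrowband(phi, cfg.band_width, frozen),
        frozen=frozen,
        steady_history=np.zeros(phi.shape, dtype=np.int64),
        prev_sign=phi < 0,
    )


def run(
    image: np.ndarray,
    cfg: RunConfig | None = None,
    init_mask: np.ndarray | None = None,
    compute_energy: bool = True,
    log=None,
) -> SegmentationResult:
    """Full segmentation: vesselness -> initialization -> evolution to convergence.

    Parameters
    ----------
    image : 2-D float image, expected normalized to [0, 1].
    cfg : model parameters; defaults are the published operating point.
    init_mask : optional user-supplied initial mask, bypassing the automatic
        vesselness-based initialization.
    compute_energy : record the total energy once per iteration (diagnostic).
    log : optional callable receiving one text line per iteration.
    """
    cfg = cfg or RunConfig()
    image = np.asarray(image, dtype=float)
    work = 1.0 - image if cfg.dark_vessels else image

    sigma = cfg.sigma if cfg.sigma is not None else default_sigma(*work.shape)
    kernel = gaussian_kernel(sigma)
    weights = EnergyWeights(lambda1=cfg.lambda1, lambda2=cfg.lambda2, v=cfg.v, mu=cfg.mu)

    vess = None
    if init_mask is None or cfg.lam_vvf != 0.0:
        vess = multiscale_vesselness(
            work, scales=cfg.scales, alpha=cfg.alpha, beta=cfg.beta,
            tau=cfg.tau, eps_v=cfg.eps_v,
        )
    if init_mask is None:
        params = InitParams(
            rho=cfg.rho, init_threshold=cfg.init_threshold, min_object_px=cfg.min_object_px
        )
        mask0 = rough_vessel_mask(work, vess, params)
    else:
        mask0 = np.asarray(init_mask, dtype=bool)
        if mask0.shape != work.shape:
            raise ValueError("init_mask shape differs from image")
    phi = init_level_set(mask0, cfg.rho)

    state = _initial_state(phi, cfg)
    cache = _vvf_cache(vess, cfg) if (vess is not None and cfg.lam_vvf != 0.0) else None

    if log:
        log(f"sigma={sigma} kernel_radius={kernel.radius} params={cfg.to_dict()}")

    stop_reason = "max_iters"
    for _ in range(cfg.max_iters):
        if not np.any(state.band):
            stop_reason = "band_empty"
            break
        evolve_step(state, work, kernel, cache, cfg)
        update_freeze_labels(state, cfg.freeze_patience, cfg.rho)
        if compute_energy:
            state.energy_trace.append(
                total_energy(work, state.phi, kernel, cfg.eps_h, weights)
            )
        if log:
            energy = state.energy_trace[-1] if state.energy_trace else float("nan")
            log(
                f"iter={state.iteration} band={int(state.band.sum())} "
                f"frozen={int(state.frozen.sum())} "
                f"sign_change_frac={state.sign_change_fractions[-1]:.3e} "
                f"energy={energy:.6f}"
            )
        recent = state.sign_change_fractions[-cfg.stop_patience :]
        if len(recent) >= cfg.stop_patience and all(f < cfg.stop_frac for f in recent):
            stop_reason = "converged"
            break

    return SegmentationResult(
        phi=state.phi,
        contours=extract_zero_contour(state.phi),
        mask=state.phi < 0,
        energy_trace=state.energy_trace,
        iterations=state.iteration,
        stop_reason=stop_reason,
        init_mask=mask0,
        frozen=state.frozen,
        vesselness=vess,
    )
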