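"""Iterative spatial-angular Richardson-Lucy tomography with optional DAO.

The classic sLFM reconstruction baseline: the Poisson maximum-likelihood
multiplicative update

    g^{k+1} = g^k . backproject( M / forwardproject(g^k) )

cycled over angle subsets (a ptychographic schedule). With digital adaptive
optics (DAO) enabled, each iteration registers the forward projections
against the measured views (defocus excluded) and shifts the projections
before forming the ratio, correcting sample-induced aberrations on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpatialAngularStack, Volume
from .noise import poisson_nll
from .predao import DisparityField, _ncc_shift, exclude_defocus
from .psf import AngularPSFStack
from .refocus import shift_view
from .simulate import (
    backproject,
    forward_project_all,
    project_to_measurement,
    upsample_from_measurement,
)

__all__ = ["TomographyConfig", "rl_step", "reconstruct_tomography"]

FLOOR = 1e-8


@dataclass
class TomographyConfig:
    iterations: int = 30
    angles_per_subset: int = 7
    dao: bool = False
    dao_start: int = 2
    positivity_floor: float = FLOOR
    init: str = "mean"  # uniform positive constant = mean(M)
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def _measurement_at_recon(views: np.ndarray, npix: int, S: int) -> np.ndarray:
    if npix > S:
        return upsample_from_measurement(views, npix, S)
    return views


def rl_step(
    volume: np.ndarray,
    meas_views: np.ndarray,
    psfs: AngularPSFStack,
    angles,
    floor: float = FLOOR,
    disparities: np.ndarray | None = None,
) -> np.ndarray:
    """One multiplicative RL update over an angle subset.

    ``meas_views`` are the measured views at reconstruction sampling,
    indexed like the PSF angles. Ratio pixels where the forward projection
    vanishes are set to 1 (no update there). ``disparities`` optionally
    shifts each projection before the ratio (DAO correction).
    """
    angles = list(angles)
    g = np.maximum(volume, floor)
    proj = forward_project_all(g, psfs, angles)
    if disparities is not None:
        for i, a in enumerate(angles):
            dy, dx = disparities[i]
            if dy or dx:
                proj[i] = shift_view(proj[i], -dy, -dx)
    M = meas_views[angles]
    ratio = np.where(proj > floor, M / np.maximum(proj, floor), 1.0)
    update = backproject(ratio.astype(np.float32), psfs, angles)
    norm = backproject(np.ones_like(ratio), psfs, angles)
    update = np.where(norm > floor, update / np.maximum(norm, floor), 1.0)
    out = g * update
    return np.maximum(out, floor).astype(np.float32)


def reconstruct_tomography(
    stack: SpatialAngularStack,
    psfs: AngularPSFStack,
    config: TomographyConfig | None = None,
    S: int | None = None,
) -> Volume:
    """Richardson-Lucy spatial-angular tomography.

    Initializes with a uniform positive constant (mean of the measurement),
    upsamples the measured views to reconstruction sampling when Npix > S,
    and cycles seeded random angle-subset permutations. Early-stops with a
    warning if the Poisson NLL increases five iterations in a row.
    """
    config = config or TomographyConfig()
    grid = psfs.grid
    npix = grid.npix
    views = stack.views
    if S is not None and npix > S:
        meas = _measurement_at_recon(views, npix, S)
    else:
        meas = views
    meas = np.maximum(meas, 0.0).astype(np.float32)
    D = len(psfs.z_planes)
    H, W = meas.shape[-2:]
    g = np.full((D, H, W), max(float(views.mean()), FLOOR) / D, np.float32)
    if config.iterations == 0:
        return Volume(g, psfs.z_planes)
    A = meas.shape[0]
    subset = min(config.angles_per_subset, A)
    rng = np.random.default_rng(config.seed)
    bad_streak = 0
    prev_nll = np.inf
    it = 0
    while it < config.iterations:
        order = rng.permutation(A)
        for s0 in range(0, A, subset):
            if it >= config.iterations:
                break
            angles = order[s0 : s0 + subset]
            disparities = None
            if config.dao and it >= config.dao_start:
                disparities = _dao_disparities(g, meas, psfs, angles)
            g = rl_step(
                g, meas, psfs, angles, config.positivity_floor, disparities
            )
            it += 1
        proj = forward_project_all(g, psfs)
        nll = poisson_nll(np.maximum(proj, FLOOR), meas)
        if nll > prev_nll + 1e-9:
            bad_streak += 1
            if bad_streak >= 5:
                import logging

                logging.getLogger(__name__).warning(
                    "tomography NLL increased 5 consecutive epochs; early stop"
                )
                break
        else:
            bad_streak = 0
        prev_nll = nll
    return Volume(g, psfs.z_planes)


def _dao_disparities(g, meas, psfs, angles):
    """Per-iteration DAO: register projections to measurements, drop defocus."""
    proj = forward_project_all(g, psfs, list(angles))
    coords = psfs.grid.coordinates()[list(angles)]
    shifts = np.zeros((len(angles), 2))
    conf = np.zeros(len(angles))
    for i, a in enumerate(angles):
        (dy, dx), p = _ncc_shift(meas[a], proj[i], max_shift=6)
        shifts[i] = (dy, dx)
        conf[i] = p
    field = DisparityField(shifts, conf, coords)
    try:
        residual, _ = exclude_defocus(field)
        return residual.shifts
    except ValueError:
        return shifts
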