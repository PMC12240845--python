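"""Forward image formation and the 'bubtub' synthetic dataset generator.

The ideal measurement of angle u_j is the depth integral of per-plane 2D
convolutions, P(x, u_j) = sum_z g(x, z) * H(x, z, u_j), rendered at
reconstruction sampling and then area-averaged down by Npix/S to the
measurement pixel size. Real cameras add mixed Poisson-Gaussian (MPG)
noise: M = Poisson(photon_scale * M') + N(mu, sigma^2).

The bubtub generator rasterizes three structure families — bubbles (hollow
shells), beads (solid spheres) and tubes (smooth random 3D curves with a
tube radius) — with randomized densities, diameters, intensities and
optical aberrations, and renders paired (ground truth, noisy measurement)
data for self-supervised training experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .core import (
    AngularGrid,
    RawScanFrames,
    SpatialAngularStack,
    Volume,
    scan_positions,
    unrealign,
)
from .psf import AngularPSFStack, ZernikeCoeffs, geometric_psf

__all__ = [
    "NoiseModel",
    "BubtubConfig",
    "forward_project",
    "forward_project_all",
    "backproject",
    "project_to_measurement",
    "upsample_from_measurement",
    "add_mpg_noise",
    "generate_bubtub",
    "simulate_measurement",
]


@dataclass
class NoiseModel:
    """Mixed Poisson-Gaussian camera model.

    ``photon_scale`` converts volume intensity units to expected photon
    counts; ``mu``/``sigma`` are the Gaussian read-noise mean and s.d. in
    counts.
    """

    mu: float = 0.0
    sigma: float = 0.0
    photon_scale: float = 1.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")


def forward_project(
    volume: Volume | np.ndarray, psfs: AngularPSFStack, angle: int
) -> np.ndarray:
    """Project a volume along one angle: sum_z g(:, z) * H(:, z, u_j).

    2D convolution with 'same' zero padding per depth plane; linear in the
    volume.
    """
    vox = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    if vox.shape[0] != psfs.kernels.shape[1]:
        raise ValueError(
            f"volume depth {vox.shape[0]} != PSF z-planes {psfs.kernels.shape[1]}"
        )
    out = fftconvolve(vox, psfs.kernels[angle], mode="same", axes=(-2, -1))
    return out.sum(axis=0).astype(np.float32)


def forward_project_all(
    volume: Volume | np.ndarray, psfs: AngularPSFStack, angles=None
) -> np.ndarray:
    """Projections for several angles at once, shape (A, H, W)."""
    vox = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    if angles is None:
        angles = range(psfs.kernels.shape[0])
    angles = list(angles)
    if vox.shape[0] != psfs.kernels.shape[1]:
        raise ValueError("volume depth does not match PSF z-planes")
    big = np.broadcast_to(vox[None], (len(angles),) + vox.shape)
    out = fftconvolve(
        big, psfs.kernels[angles], mode="same", axes=(-2, -1)
    ).sum(axis=1)
    return out.astype(np.float32)


def backproject(images: np.ndarray, psfs: AngularPSFStack, angles=None) -> np.ndarray:
    """Adjoint of :func:`forward_project_all`: correlate with H(-x, z, u).

    ``images`` is (A, H, W) at reconstruction sampling; returns a volume
    (D, H, W) summed over the given angles.
    """
    images = np.asarray(images)
    if angles is None:
        angles = range(psfs.kernels.shape[0])
    angles = list(angles)
    flipped = psfs.kernels[angles][:, :, ::-1, ::-1]
    D = flipped.shape[1]
    big = np.broadcast_to(images[:, None], (len(angles), D) + images.shape[-2:])
    out = fftconvolve(big, flipped, mode="same", axes=(-2, -1)).sum(axis=0)
    return out.astype(np.float32)


def project_to_measurement(projection: np.ndarray, npix: int = 13, S: int = 3) -> np.ndarray:
    """Area-average downscale from reconstruction to measurement sampling.

    The rational factor Npix/S (13/3 by default) is applied exactly by
    S-fold pixel replication followed by Npix-block averaging. Flat fields
    are invariant; the area-weighted integral (sum * pixel_area) is
    conserved exactly.
    """
    if npix <= S:
        raise ValueError("downscale factor Npix/S must be > 1")
    proj = np.asarray(projection)
    h, w = proj.shape[-2:]
    if (h * S) % npix or (w * S) % npix:
        raise ValueError(
            f"input sides {(h, w)} * {S}/{npix} are not integral; cannot downscale"
        )
    oh, ow = h * S // npix, w * S // npix
    rep = np.repeat(np.repeat(proj, S, axis=-2), S, axis=-1)
    rep = rep.reshape(*proj.shape[:-2], oh, npix, ow, npix)
    return rep.mean(axis=(-3, -1)).astype(np.float32)


def upsample_from_measurement(image: np.ndarray, npix: int = 13, S: int = 3) -> np.ndarray:
    """Adjoint-style upscale by Npix/S: Npix-fold replication, S-block mean."""
    img = np.asarray(image)
    h, w = img.shape[-2:]
    oh, ow = h * npix // S, w * npix // S
    rep = np.repeat(np.repeat(img, npix, axis=-2), npix, axis=-1)
    rep = rep.reshape(*img.shape[:-2], oh, S, ow, S)
    return rep.mean(axis=(-3, -1)).astype(np.float32)


def add_mpg_noise(clean: np.ndarray, noise: NoiseModel, seed: int) -> np.ndarray:
    """Draw M = Poisson(photon_scale * M') + N(mu, sigma^2), elementwise."""
    clean = np.asarray(clean)
    if (clean < 0).any():
        raise ValueError("clean input must be non-negative for Poisson noise")
    rng = np.random.default_rng(seed)
    shot = rng.poisson(clean * noise.photon_scale).astype(np.float32)
    if noise.sigma > 0 or noise.mu != 0:
        shot = shot + rng.normal(noise.mu, noise.sigma, clean.shape).astype(np.float32)
    return shot


# ---------------------------------------------------------------------------
# bubtub phantom generation

@dataclass
class BubtubConfig:
    """Study conditions for one bubtub sample.

    Counts and radii are sampled uniformly in the given ranges; structures
    reaching outside the volume are clipped. Aberrations are sampled as
    random Zernike vectors with r.m.s. drawn from ``aberration_rms_range``
    (wavelengths). A seed fully determines the output.
    """

    shape: tuple = (21, 99, 99)
    n_bubbles: tuple = (1, 4)
    n_beads: tuple = (2, 8)
    n_tubes: tuple = (1, 3)
    bubble_radius: tuple = (4.0, 10.0)
    bubble_wall: tuple = (1.0, 2.0)
    bead_radius: tuple = (1.0, 3.5)
    tube_radius: tuple = (1.0, 2.5)
    intensity: tuple = (0.5, 1.0)
    aberration_rms_range: tuple = (0.0, 0.0)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(0.0, 2.0, 100.0))
    seed: int = 0


def _soft_ball(shape, center, radius, aa: float = 1.0) -> np.ndarray:
    """Anti-aliased solid sphere mask via a smoothed signed distance."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    return np.clip((radius - d) / aa + 0.5, 0.0, 1.0)


def _soft_shell(shape, center, radius, wall, aa: float = 1.0) -> np.ndarray:
    outer = _soft_ball(shape, center, radius, aa)
    inner = _soft_ball(shape, center, max(radius - wall, 0.0), aa)
    return np.clip(outer - inner, 0.0, 1.0)


def _random_tube(shape, radius, rng, n_ctrl: int = 4) -> np.ndarray:
    """Rasterize a smooth random 3D curve with a tube radius.

    Control points are interpolated with a cubic-smooth dense polyline; the
    tube is the union of small balls along the curve (distance transform of
    the polyline raster, thresholded softly).
    """
    D, H, W = shape
    ctrl = np.stack(
        [
            rng.uniform(0.15 * D, 0.85 * D, n_ctrl),
            rng.uniform(0.1 * H, 0.9 * H, n_ctrl),
            rng.uniform(0.1 * W, 0.9 * W, n_ctrl),
        ],
        axis=1,
    )
    from scipy.interpolate import CubicSpline

    t = np.linspace(0, 1, n_ctrl)
    cs = CubicSpline(t, ctrl, axis=0)
    dense = cs(np.linspace(0, 1, 40 * n_ctrl))
    raster = np.zeros(shape, bool)
    idx = np.round(dense).astype(int)
    keep = (
        (idx[:, 0] >= 0) & (idx[:, 0] < D)
        & (idx[:, 1] >= 0) & (idx[:, 1] < H)
        & (idx[:, 2] >= 0) & (idx[:, 2] < W)
    )
    idx = idx[keep]
    raster[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not raster.any():
        return np.zeros(shape, np.float32)
    dist = ndimage.distance_transform_edt(~raster)
    return np.clip(radius - dist + 0.5, 0.0, 1.0).astype(np.float32)


def bubtub_volume(config: BubtubConfig, rng) -> np.ndarray:
    """Rasterize bubbles, beads and tubes into a non-negative volume."""
    shape = tuple(config.shape)
    vol = np.zeros(shape, np.float32)

    def _rand_center():
        return (
            rng.uniform(0, shape[0] - 1),
            rng.uniform(0, shape[1] - 1),
            rng.uniform(0, shape[2] - 1),
        )

    for _ in range(rng.integers(config.n_bubbles[0], config.n_bubbles[1] + 1)):
        r = rng.uniform(*config.bubble_radius)
        w = rng.uniform(*config.bubble_wall)
        vol += rng.uniform(*config.intensity) * _soft_shell(shape, _rand_center(), r, w)
    for _ in range(rng.integers(config.n_beads[0], config.n_beads[1] + 1)):
        r = rng.uniform(*config.bead_radius)
        vol += rng.uniform(*config.intensity) * _soft_ball(shape, _rand_center(), r)
    for _ in range(rng.integers(config.n_tubes[0], config.n_tubes[1] + 1)):
        r = rng.uniform(*config.tube_radius)
        vol += rng.uniform(*config.intensity) * _random_tube(shape, r, rng)
    return vol


def generate_bubtub(
    config: BubtubConfig,
    psfs: AngularPSFStack,
    npix: int | None = None,
    S: int | None = None,
    pupil=None,
):
    """Render one bubtub sample: (ground-truth Volume, measurement stack, meta).

    The volume is projected along every selected angle with the provided
    PSFs, downscaled to measurement sampling when Npix > S, and corrupted
    with MPG noise. When ``pupil`` is given and the config's
    ``aberration_rms_range`` is nonzero, an optical aberration is sampled
    (low-order-dominated Zernike prior) and the wave-optics PSFs are
    rebuilt under it. Everything needed to regenerate the sample (seed,
    aberration, noise model) is recorded in the metadata dict.
    """
    rng = np.random.default_rng(config.seed)
    vol = bubtub_volume(config, rng)
    if vol.shape[0] != len(psfs.z_planes):
        raise ValueError("config depth does not match PSF z-planes")
    aberration = None
    if pupil is not None and config.aberration_rms_range[1] > 0:
        from .psf import ZernikeCoeffs, waveoptics_psf

        rms = float(rng.uniform(*config.aberration_rms_range))
        if rms > 0:
            aberration = ZernikeCoeffs.sample(rms, rng)
            psfs = waveoptics_psf(
                pupil, psfs.grid, psfs.z_planes, aberration=aberration
            )
    grid = psfs.grid
    if npix is None:
        npix = grid.npix
    proj = forward_project_all(vol, psfs)
    if S is not None and npix > S:
        meas = project_to_measurement(proj, npix, S)
    else:
        meas = proj
    noise_seed = int(rng.integers(0, 2**31 - 1))
    noisy = add_mpg_noise(np.maximum(meas, 0.0), config.noise, noise_seed)
    stack = SpatialAngularStack(noisy, grid)
    meta = {
        "seed": config.seed,
        "noise_seed": noise_seed,
        "noise": {
            "mu": config.noise.mu,
            "sigma": config.noise.sigma,
            "photon_scale": config.noise.photon_scale,
        },
        "zernike": None
        if psfs.zernike is None
        else psfs.zernike.coefficients.tolist(),
        "sampled_aberration_rms": None if aberration is None else aberration.rms,
        "psf_model": psfs.model,
    }
    volume = Volume(vol, psfs.z_planes)
    return volume, stack, meta


def simulate_measurement(
    volume: Volume,
    psfs: AngularPSFStack,
    S: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
    as_raw: bool = False,
):
    """Render a volume into a spatial-angular stack and optionally raw frames.

    Every selected angle is projected at reconstruction sampling and
    downscaled to S-times-microlens sampling; noise is applied at
    measurement sampling. With ``as_raw`` the stack is re-interleaved into
    S x S scan frames (requires the full angular grid).
    """
    grid = psfs.grid
    npix = grid.npix
    proj = forward_project_all(volume, psfs)
    if npix > S:
        meas = project_to_measurement(proj, npix, S)
    else:
        meas = proj
    if noise is not None:
        meas = add_mpg_noise(np.maximum(meas, 0.0), noise, seed)
    stack = SpatialAngularStack(meas, grid)
    if as_raw:
        return unrealign(stack, S)
    return stack
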