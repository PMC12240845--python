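"""One-shot digital adaptive optics (preDAO).

Optical aberrations deflect rays passing through different pupil
sub-apertures, so each angular view of an aberrated light field is locally
shifted relative to the center view. preDAO estimates those per-view
disparities by windowed normalized cross-correlation, removes the component
linear in the angular coordinate (global defocus, disp = beta * u, which
encodes focus error rather than aberration), corrects the views by warping
with the residual disparity, and interprets the residual as the local
wavefront gradient at each view's pupil position to recover Zernike mode
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SpatialAngularStack
from .psf import DEFAULT_MODES, ZernikeCoeffs, zernike_modes
from .refocus import shift_view

__all__ = [
    "DisparityField",
    "estimate_disparities",
    "exclude_defocus",
    "correct_views",
    "fit_wavefront",
    "synthesize_disparities",
]


@dataclass
class DisparityField:
    """Per-view shifts relative to the center view.

    ``shifts`` is (A, 2) for global mode or (A, ty, tx, 2) for tiled mode,
    in pixels (dy, dx); ``confidence`` holds the correlation peak value per
    entry. The center view's disparity is identically (0, 0).
    """

    shifts: np.ndarray
    confidence: np.ndarray
    coords: np.ndarray  # angular coordinates (A, 2)
    tile_size: int | None = None
    beta: float | None = None  # defocus coefficient, px per unit angle

    @property
    def is_tiled(self) -> bool:
        return self.shifts.ndim == 4


def _hann2d(shape) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _upsampled_corr(F: np.ndarray, shape, center, radius: float, up: int):
    """Cross-correlation on a fine lattice around ``center`` by matrix DFT."""
    H, W = shape
    fy = np.fft.fftfreq(H)
    fx = np.fft.rfftfreq(W)
    ys = center[0] + np.arange(-radius * up, radius * up + 1) / up
    xs = center[1] + np.arange(-radius * up, radius * up + 1) / up
    Ey = np.exp(2j * np.pi * np.outer(ys, fy))  # (ny, H)
    Ex = np.exp(2j * np.pi * np.outer(fx, xs))  # (Wr, nx)
    # account for rfft symmetry: double all but the DC (and Nyquist) columns
    weights = np.full(F.shape[1], 2.0)
    weights[0] = 1.0
    if W % 2 == 0:
        weights[-1] = 1.0
    corr = (Ey @ (F * weights) @ Ex).real
    return corr, ys, xs


def _ncc_shift(img: np.ndarray, ref: np.ndarray, max_shift: int | None = None,
               upsample: int = 16):
    """Subpixel shift of ``img`` relative to ``ref`` by FFT cross-correlation.

    Both images are mean-subtracted, Hann-windowed and zero-padded (to
    suppress circular wrap); the integer correlation peak is refined on an
    ``upsample``-times finer lattice evaluated by matrix DFT. Returns
    ((dy, dx), peak) where positive dy means ``img`` content sits at larger
    y than ``ref``. A flat tile (zero variance) returns ((0, 0), 0).
    """
    img = np.asarray(img, float)
    ref = np.asarray(ref, float)
    w = _hann2d(img.shape)
    a = (img - img.mean()) * w
    b = (ref - ref.mean()) * w
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return (0.0, 0.0), 0.0
    a /= na
    b /= nb
    H, W = img.shape
    s = (2 * H, 2 * W)
    F = np.fft.rfft2(a, s) * np.conj(np.fft.rfft2(b, s))
    corr = np.fft.fftshift(np.fft.irfft2(F, s=s))
    cy, cx = s[0] // 2, s[1] // 2
    if max_shift is None:
        max_shift = min(H, W) // 2 - 1
    sub = corr[cy - max_shift : cy + max_shift + 1, cx - max_shift : cx + max_shift + 1]
    py, px = np.unravel_index(np.argmax(sub), sub.shape)
    peak = float(sub[py, px])
    dy0, dx0 = float(py - max_shift), float(px - max_shift)
    fine, ys, xs = _upsampled_corr(F, s, (dy0, dx0), 0.75, upsample)
    fy, fx = np.unravel_index(np.argmax(fine), fine.shape)
    return (float(ys[fy]), float(xs[fx])), peak


def estimate_disparities(
    stack: SpatialAngularStack,
    tile_size: int | None = None,
    overlap: float = 0.5,
    max_shift: int | None = 8,
) -> DisparityField:
    """Estimate per-view (optionally tiled) disparities against the center view.

    Global mode (``tile_size=None``) returns one (dy, dx) per view; tiled
    mode computes per-tile shifts with the given fractional overlap and a
    confidence equal to the correlation peak value.
    """
    views = stack.views
    if views.shape[0] < 2:
        raise ValueError("need at least two views to estimate disparities")
    coords = stack.grid.coordinates()
    ref = stack.center_view()
    A = views.shape[0]
    if tile_size is None:
        shifts = np.zeros((A, 2))
        conf = np.zeros(A)
        for a in range(A):
            if (coords[a] == 0).all():
                conf[a] = 1.0
                continue
            (dy, dx), p = _ncc_shift(views[a], ref, max_shift)
            shifts[a] = (dy, dx)
            conf[a] = p
        return DisparityField(shifts, conf, coords)
    H, W = views.shape[-2:]
    step = max(1, int(tile_size * (1 - overlap)))
    ys = list(range(0, max(H - tile_size, 0) + 1, step)) or [0]
    xs = list(range(0, max(W - tile_size, 0) + 1, step)) or [0]
    shifts = np.zeros((A, len(ys), len(xs), 2))
    conf = np.zeros((A, len(ys), len(xs)))
    for a in range(A):
        if (coords[a] == 0).all():
            conf[a] = 1.0
            continue
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                sl = (slice(y0, y0 + tile_size), slice(x0, x0 + tile_size))
                (dy, dx), p = _ncc_shift(views[a][sl], ref[sl], max_shift)
                shifts[a, i, j] = (dy, dx)
                conf[a, i, j] = p
    return DisparityField(shifts, conf, coords, tile_size=tile_size)


def exclude_defocus(disp: DisparityField):
    """Split disparities into a defocus part beta*u and an aberration residual.

    A single scalar beta is fitted jointly over both axes by least squares:
    beta = sum_j d_j . u_j / sum_j |u_j|^2 (tile-averaged shifts in tiled
    mode). Returns (residual DisparityField, beta).
    """
    coords = disp.coords.astype(float)
    if np.linalg.matrix_rank(coords) < 2:
        raise ValueError("angle set does not span both angular axes")
    if disp.is_tiled:
        mean_shifts = disp.shifts.mean(axis=(1, 2))
    else:
        mean_shifts = disp.shifts
    num = float((mean_shifts * coords).sum())
    den = float((coords * coords).sum())
    beta = num / den if den > 0 else 0.0
    if disp.is_tiled:
        residual = disp.shifts - beta * coords[:, None, None, :]
    else:
        residual = disp.shifts - beta * coords
    return (
        DisparityField(residual, disp.confidence, disp.coords, disp.tile_size, beta),
        beta,
    )


def _dense_disparity(disp: DisparityField, shape) -> np.ndarray:
    """Bilinearly blend tiled shifts into a dense (A, H, W, 2) field."""
    H, W = shape
    A = disp.shifts.shape[0]
    if not disp.is_tiled:
        return np.broadcast_to(disp.shifts[:, None, None, :], (A, H, W, 2)).copy()
    ty, tx = disp.shifts.shape[1:3]
    dense = np.empty((A, H, W, 2), float)
    yy = np.linspace(0, ty - 1, H)
    xx = np.linspace(0, tx - 1, W)
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    for a in range(A):
        for c in range(2):
            dense[a, :, :, c] = ndimage.map_coordinates(
                disp.shifts[a, :, :, c], [gy, gx], order=1, mode="nearest"
            )
    return dense


def correct_views(stack: SpatialAngularStack, disp: DisparityField) -> SpatialAngularStack:
    """Warp each view by its residual disparity: M(x + disp(x, u), u).

    Global shifts use spline translation; tiled fields are bilinearly
    blended to a dense displacement and applied with map_coordinates.
    """
    views = stack.views
    H, W = views.shape[-2:]
    out = np.empty_like(views)
    if not disp.is_tiled:
        for a in range(views.shape[0]):
            dy, dx = disp.shifts[a]
            if dy == 0 and dx == 0:
                out[a] = views[a]
            else:
                # sample at x + disp: inverse translate by -disp
                out[a] = shift_view(views[a], -dy, -dx)
        return SpatialAngularStack(out, stack.grid, stack.pixel_pitch, stack.timestamp)
    dense = _dense_disparity(disp, (H, W))
    gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    for a in range(views.shape[0]):
        out[a] = ndimage.map_coordinates(
            views[a],
            [gy + dense[a, :, :, 0], gx + dense[a, :, :, 1]],
            order=1,
            mode="constant",
        )
    return SpatialAngularStack(out, stack.grid, stack.pixel_pitch, stack.timestamp)


def _gradient_design(coords: np.ndarray, half_extent: int, modes,
                     sampling: int = 65):
    """Patch-averaged Zernike gradient design matrix, one view per row pair.

    The centroid displacement of a sub-aperture PSF equals the
    energy-weighted *mean* of the wavefront gradient over that view's pupil
    patch (exact for a uniform-amplitude pupil), so the design matrix
    averages the analytic gradients over each patch: view u covers the
    square of width 2/Npix centered at u * 2/Npix on the unit disk,
    intersected with the disk — the same layout as :func:`slfm.psf.make_pupil`.
    """
    npix = 2 * half_extent + 1
    c = np.linspace(-1 + 1 / sampling, 1 - 1 / sampling, sampling)
    rho_x, rho_y = np.meshgrid(c, c, indexing="ij")
    disk = rho_x**2 + rho_y**2 <= 1.0
    _, gx, gy = zernike_modes(modes, rho_x, rho_y, gradients=True)
    width = 2.0 / npix
    A = len(coords)
    G = np.zeros((2 * A, len(modes)))
    for a, (u1, u2) in enumerate(coords):
        m = (
            (np.abs(rho_x - u1 * width) <= width / 2)
            & (np.abs(rho_y - u2 * width) <= width / 2)
            & disk
        )
        if not m.any():
            continue
        G[a] = gx[:, m].mean(axis=1)
        G[A + a] = gy[:, m].mean(axis=1)
    return G


def fit_wavefront(
    disp: DisparityField,
    half_extent: int,
    modes=DEFAULT_MODES,
    slope_scale: float = 1.0,
) -> ZernikeCoeffs:
    """Least-squares Zernike decomposition of the residual disparity field.

    Treats the (defocus-excluded, tile-averaged) per-view disparity as the
    wavefront gradient sampled at that view's pupil location and solves
    ``disp = slope_scale * grad(W)`` for the mode amplitudes. The defocus
    mode is included in the regression so residual defocus leakage is
    absorbed, but its amplitude is reported with the rest.
    """
    shifts = disp.shifts.mean(axis=(1, 2)) if disp.is_tiled else disp.shifts
    coords = disp.coords.astype(float)
    G = _gradient_design(coords, half_extent, modes) * slope_scale
    A = len(coords)
    # the measured disparities had their isotropic linear-in-u (defocus)
    # component removed; apply the identical projection to every design
    # column so the regression stays consistent — the defocus mode's column
    # collapses to ~0 (its amplitude is indistinguishable from focus error
    # and is carried by beta, not by the fit)
    # disparities are measured *relative to the center view*, whose own
    # patch-mean gradient is generally nonzero: absorb that per-axis offset
    # with tip/tilt nuisance columns (their gradients are constant)
    ones = np.ones(A)
    zeros = np.zeros(A)
    tip = np.concatenate([ones, zeros])
    tilt = np.concatenate([zeros, ones])
    Gfull = np.column_stack([tip, tilt, G])
    den = float((coords * coords).sum())
    if den > 0:
        beta_cols = (Gfull[:A] * coords[:, :1]).sum(axis=0) + (
            Gfull[A:] * coords[:, 1:2]
        ).sum(axis=0)
        beta_cols /= den
        Gfull = Gfull - np.concatenate(
            [coords[:, :1] * beta_cols, coords[:, 1:2] * beta_cols]
        )
    b = np.concatenate([shifts[:, 0], shifts[:, 1]])
    sol, *_ = np.linalg.lstsq(Gfull, b, rcond=None)
    c = sol[2:]
    # conditioning of the effective (retained-rank) problem: the projected
    # defocus column is identically ~0 and is excluded by the lstsq cutoff
    s = np.linalg.svd(Gfull, compute_uv=False)
    kept = s[s > s.max() * 1e-10]
    cond = kept.max() / kept.min()
    if cond > 1e6:
        import logging

        logging.getLogger(__name__).warning(
            "wavefront fit ill-conditioned (cond=%.2e)", cond
        )
    return ZernikeCoeffs(c, modes)


def synthesize_disparities(
    coeffs: ZernikeCoeffs, coords: np.ndarray, half_extent: int,
    slope_scale: float = 1.0,
) -> np.ndarray:
    """Forward model of :func:`fit_wavefront`: per-view shifts (A, 2)."""
    G = _gradient_design(coords, half_extent, coeffs.mode_indices) * slope_scale
    b = G @ coeffs.coefficients
    A = len(coords)
    return np.stack([b[:A], b[A:]], axis=1)
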