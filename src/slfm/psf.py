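"""Angular PSF models H(x, z, u) for spatial-angular light-field imaging.

Two models are provided:

* ``geometric_psf`` — the delta-shift approximation delta(x - alpha*z*u):
  each angular view sees a point at depth z displaced laterally by
  alpha*z*u pixels. Kernels are bilinearly interpolated unit impulses with
  exactly unit mass.
* ``waveoptics_psf`` — a scalar Debye/Fourier pupil model: the (optionally
  Zernike-aberrated) pupil is masked by each angle's sub-aperture, a defocus
  phase is applied per depth, and the intensity PSF is obtained by Fourier
  propagation to the image plane. High-NA vectorial effects are ignored.

Zernike polynomials use the OSA/ANSI single index; by default the 18 modes
3..20 (piston, tip and tilt excluded) parameterize aberrations. Modes are
represented internally as exact bivariate polynomials, so x/y wavefront
gradients are analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AngularGrid

__all__ = [
    "ZernikeCoeffs",
    "Pupil",
    "AngularPSFStack",
    "zernike_modes",
    "zernike_basis",
    "geometric_psf",
    "waveoptics_psf",
    "make_pupil",
    "fit_alpha",
    "save_psf_stack",
    "load_psf_stack",
    "DEFAULT_MODES",
]

DEFAULT_MODES = tuple(range(3, 21))  # 18 modes, OSA/ANSI indices


@dataclass
class ZernikeCoeffs:
    """Amplitudes (wavelengths r.m.s.) of OSA/ANSI Zernike modes.

    With the orthonormal basis used here, the r.m.s. of the synthesized
    wavefront over the unit disk equals the 2-norm of the coefficients.
    """

    coefficients: np.ndarray
    mode_indices: tuple = DEFAULT_MODES

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        self.mode_indices = tuple(self.mode_indices)
        if len(self.coefficients) != len(self.mode_indices):
            raise ValueError("coefficient/mode length mismatch")
        if 0 in self.mode_indices:
            raise ValueError("piston (mode 0) is always excluded")

    @property
    def rms(self) -> float:
        return float(np.linalg.norm(self.coefficients))

    @classmethod
    def zeros(cls, modes=DEFAULT_MODES) -> "ZernikeCoeffs":
        return cls(np.zeros(len(modes)), modes)

    @classmethod
    def random(cls, rms: float, rng, modes=DEFAULT_MODES) -> "ZernikeCoeffs":
        c = rng.standard_normal(len(modes))
        c *= rms / np.linalg.norm(c)
        return cls(c, modes)

    @classmethod
    def sample(cls, rms: float, rng, modes=DEFAULT_MODES,
               zero_defocus: bool = True) -> "ZernikeCoeffs":
        """Sample a low-order-dominated aberration at the given r.m.s.

        Mode amplitudes fall off with radial order n like 2/(n(n+1)),
        emulating the smooth wavefronts induced by refractive-index
        heterogeneity in tissue (high orders carry little power). With
        ``zero_defocus`` the defocus mode is zeroed: a global focus shift is
        indistinguishable from the choice of focal plane and is handled by
        the refocusing machinery, not treated as an aberration.
        """
        n_orders = np.array([_osa_to_nm(j)[0] for j in modes], float)
        c = rng.standard_normal(len(modes)) * 2.0 / (n_orders * (n_orders + 1))
        if zero_defocus and 4 in modes:
            c[list(modes).index(4)] = 0.0
        c *= rms / np.linalg.norm(c)
        return cls(c, modes)


def _osa_to_nm(j: int):
    """OSA/ANSI single index -> (n, m)."""
    n = int((math.sqrt(8 * j + 1) - 1) // 2)
    m = 2 * j - n * (n + 2)
    return n, m


def _zernike_poly(j: int) -> np.ndarray:
    """Cartesian coefficient matrix C with Z_j(x, y) = sum C[p, q] x^p y^q.

    Built from the radial polynomial R_n^|m| and the angular factor written as
    a polynomial in x, y (r^|m| cos|m|t = Re[(x+iy)^|m|], r^|m| sin|m|t =
    Im[(x+iy)^|m|]); remaining even powers of r become (x^2+y^2)^k.
    Normalized so that the basis is orthonormal over the unit disk
    (N = sqrt(2(n+1)) for m != 0, sqrt(n+1) for m = 0).
    """
    n, m = _osa_to_nm(j)
    am = abs(m)
    size = n + 1
    C = np.zeros((size, size))
    # angular factor as polynomial in (x, y)
    ang = np.zeros((am + 1, am + 1))
    for k in range(am + 1):
        coef = math.comb(am, k)
        # (x + iy)^am term x^(am-k) (iy)^k
        if m >= 0:  # cosine: real part -> even k
            if k % 4 == 0:
                ang[am - k, k] += coef
            elif k % 4 == 2:
                ang[am - k, k] -= coef
        else:  # sine: imaginary part -> odd k
            if k % 4 == 1:
                ang[am - k, k] += coef
            elif k % 4 == 3:
                ang[am - k, k] -= coef
    for s in range((n - am) // 2 + 1):
        r_coef = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + am) // 2 - s)
                * math.factorial((n - am) // 2 - s)
            )
        )
        # r^(n-2s-am) = (x^2+y^2)^e with e = (n-2s-am)/2
        e = (n - 2 * s - am) // 2
        for t in range(e + 1):
            c2 = math.comb(e, t)
            # x^(2(e-t)) y^(2t) times angular polynomial
            px, py = 2 * (e - t), 2 * t
            C[px : px + am + 1, py : py + am + 1] += r_coef * c2 * ang
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
    return C * norm


def _polyval2d(C: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval2d(x, y, C)


def _polyder2d(C: np.ndarray, axis: int) -> np.ndarray:
    if axis == 0:
        p = np.arange(1, C.shape[0])
        return C[1:, :] * p[:, None]
    p = np.arange(1, C.shape[1])
    return C[:, 1:] * p[None, :]


def zernike_modes(mode_indices, x: np.ndarray, y: np.ndarray, gradients: bool = False):
    """Evaluate orthonormal Zernike modes (and analytic d/dx, d/dy) at (x, y).

    ``x``/``y`` are unit-disk coordinates of any shape; returns an array
    (n_modes, *shape), or a tuple (Z, dZdx, dZdy) if ``gradients``.
    """
    Z, Gx, Gy = [], [], []
    for j in mode_indices:
        C = _zernike_poly(j)
        Z.append(_polyval2d(C, x, y))
        if gradients:
            Gx.append(_polyval2d(_polyder2d(C, 0), x, y))
            Gy.append(_polyval2d(_polyder2d(C, 1), x, y))
    Z = np.stack(Z)
    if gradients:
        return Z, np.stack(Gx), np.stack(Gy)
    return Z


def zernike_basis(mode_indices=DEFAULT_MODES, grid_size: int = 64, gradients: bool = False):
    """Zernike basis images sampled on a unit-disk grid.

    Returns (basis, mask) or (basis, dZdx, dZdy, mask). Basis images are
    orthonormal over the sampled disk up to pixelization of the disk edge;
    the Gram error decays like 1/grid_size (<= 1e-3 at 512).
    """
    if grid_size < 16:
        raise ValueError("grid_size too coarse (< 16 px) for Zernike sampling")
    c = np.linspace(-1 + 1 / grid_size, 1 - 1 / grid_size, grid_size)
    x, y = np.meshgrid(c, c, indexing="ij")
    mask = x * x + y * y <= 1.0
    out = zernike_modes(mode_indices, x, y, gradients=gradients)
    if gradients:
        Z, Gx, Gy = out
        return Z * mask, Gx * mask, Gy * mask, mask
    return out * mask, mask


@dataclass
class Pupil:
    """Sampled pupil disk with per-angle sub-aperture masks.

    ``rho_x/rho_y`` are unit-disk pupil coordinates; sub-aperture masks tile
    the pupil bounding square into npix x npix patches (one per angular
    coordinate u), intersected with the disk.
    """

    NA: float
    wavelength: float  # nm
    n: float
    grid_size: int
    rho_x: np.ndarray
    rho_y: np.ndarray
    disk: np.ndarray
    subapertures: dict  # (u1, u2) -> bool mask

    def aberration_phase(self, coeffs: ZernikeCoeffs) -> np.ndarray:
        """Pupil phase (radians) of a wavefront given in wavelengths r.m.s."""
        Z = zernike_modes(coeffs.mode_indices, self.rho_x, self.rho_y)
        w = np.tensordot(coeffs.coefficients, Z, axes=1)  # wavelengths
        return 2 * np.pi * w * self.disk


def make_pupil(
    NA: float = 1.4,
    wavelength: float = 525.0,
    n: float = 1.515,
    grid: AngularGrid | None = None,
    grid_size: int = 65,
) -> Pupil:
    """Build a sampled pupil with a square sub-aperture layout.

    The npix x npix layout maps each angular coordinate u to the pupil patch
    centered at u / (half_extent + 1/2); the union of patches covers the disk.
    """
    if not 0 < NA < n:
        raise ValueError(f"require 0 < NA < n, got NA={NA}, n={n}")
    if grid is None:
        grid = AngularGrid()
    c = np.linspace(-1 + 1 / grid_size, 1 - 1 / grid_size, grid_size)
    rho_x, rho_y = np.meshgrid(c, c, indexing="ij")
    disk = rho_x**2 + rho_y**2 <= 1.0
    npix = grid.npix
    h = grid.half_extent
    width = 2.0 / npix  # patch width in unit-disk coordinates
    subs = {}
    for u1, u2 in grid.coordinates(selected_only=False):
        cx, cy = u1 * width, u2 * width
        m = (
            (np.abs(rho_x - cx) <= width / 2)
            & (np.abs(rho_y - cy) <= width / 2)
            & disk
        )
        subs[(int(u1), int(u2))] = m
    covered = np.zeros_like(disk)
    for m in subs.values():
        covered |= m
    uncovered = (disk & ~covered).sum() / max(disk.sum(), 1)
    if uncovered > 0.05:
        import logging

        logging.getLogger(__name__).warning(
            "sub-aperture layout leaves %.1f%% of the pupil uncovered", 100 * uncovered
        )
    return Pupil(NA, wavelength, n, grid_size, rho_x, rho_y, disk, subs)


@dataclass
class AngularPSFStack:
    """Per-angle, per-depth 2D kernels on the reconstruction grid.

    ``kernels`` has shape (A, D, k, k) with A the selected angle count and D
    the number of z-planes; ``alpha`` is the lateral shift per unit depth per
    unit angle (pixels), exact for geometric kernels and fitted from
    centroids for wave-optics kernels.
    """

    kernels: np.ndarray
    grid: AngularGrid
    z_planes: np.ndarray
    alpha: float
    model: str = "geometric"
    zernike: ZernikeCoeffs | None = None

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, np.float32)
        self.z_planes = np.asarray(self.z_planes, float)
        if self.kernels.ndim != 4:
            raise ValueError("kernels must be (angle, z, ky, kx)")
        if self.kernels.shape[0] != self.grid.n_selected:
            raise ValueError("kernel angle count != selected view count")
        if self.kernels.shape[1] != len(self.z_planes):
            raise ValueError("kernel depth != len(z_planes)")

    @property
    def support(self) -> int:
        return self.kernels.shape[-1]


def geometric_psf(
    grid: AngularGrid,
    z_planes,
    alpha: float,
    support: int | None = None,
) -> AngularPSFStack:
    """Delta-shift PSFs: a unit impulse displaced by alpha * z * u per view.

    Sub-pixel displacements are bilinearly split over the four neighbouring
    pixels, so every kernel has mass exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    z_planes = np.asarray(z_planes, float)
    coords = grid.coordinates()
    max_shift = float(np.abs(alpha * z_planes[:, None, None] * coords[None]).max())
    needed = 2 * int(np.ceil(max_shift)) + 3
    if support is None:
        support = needed
    elif support < needed:
        raise ValueError(
            f"kernel support {support} too small; displacement needs >= {needed}"
        )
    if support % 2 == 0:
        support += 1
    c = support // 2
    A, D = len(coords), len(z_planes)
    kernels = np.zeros((A, D, support, support), np.float32)
    for a, (u1, u2) in enumerate(coords):
        for d, z in enumerate(z_planes):
            dy, dx = alpha * z * u1, alpha * z * u2
            iy, ix = int(np.floor(dy)), int(np.floor(dx))
            fy, fx = dy - iy, dx - ix
            for oy, wy in ((0, 1 - fy), (1, fy)):
                for ox, wx in ((0, 1 - fx), (1, fx)):
                    w = wy * wx
                    if w:
                        kernels[a, d, c + iy + oy, c + ix + ox] += w
    return AngularPSFStack(kernels, grid, z_planes, float(alpha), model="geometric")


def _crop_to_energy(kernels: np.ndarray, frac: float = 0.999) -> np.ndarray:
    """Truncate to the smallest odd square retaining ``frac`` of total energy."""
    k = kernels.shape[-1]
    c = k // 2
    total = kernels.sum()
    for half in range(1, c + 1):
        sl = slice(c - half, c + half + 1)
        if kernels[..., sl, sl].sum() >= frac * total:
            return kernels[..., sl, sl].copy()
    return kernels


def waveoptics_psf(
    pupil: Pupil,
    grid: AngularGrid,
    z_planes,
    aberration: ZernikeCoeffs | None = None,
    pixel_pitch: float | None = None,
    fft_size: int = 256,
    energy_frac: float = 0.999,
) -> AngularPSFStack:
    """Scalar Debye/Fourier angular PSFs.

    For each depth z the defocus phase k*z*sqrt(n^2 - NA^2 rho^2) is applied
    to the (optionally aberrated) pupil, each angle's sub-aperture is masked
    and the intensity PSF is |FFT|^2 on the image plane. Kernels are
    normalized so the z=0 center-view kernel has unit mass while relative
    energy across z and angle is preserved; support is truncated to the
    smallest odd square holding ``energy_frac`` of the energy.

    ``pixel_pitch`` is the image-plane sampling in nm; the default
    lambda / (4 NA) satisfies Nyquist for the full aperture.
    """
    NA, lam, n = pupil.NA, pupil.wavelength, pupil.n
    if NA >= n:
        raise ValueError("NA must be < n")
    if pixel_pitch is None:
        pixel_pitch = lam / (4 * NA)
    if pixel_pitch > lam / (2 * NA):
        raise ValueError(
            f"pixel_pitch {pixel_pitch} undersamples the diffraction limit "
            f"{lam / (2 * NA):.1f} nm"
        )
    z_planes = np.asarray(z_planes, float)
    N = pupil.grid_size
    # pupil frequency sampling: rho=1 corresponds to NA/lambda cycles/nm.
    # FFT of size M with pupil pixel dnu = 2*NA/(lam*N) gives image pixel
    # dx = 1/(M*dnu); choose M >= fft_size to reach the requested pitch.
    dnu = (2 * NA / lam) / N
    M = max(fft_size, int(np.ceil(1.0 / (pixel_pitch * dnu))))
    dx = 1.0 / (M * dnu)
    rho2 = pupil.rho_x**2 + pupil.rho_y**2
    # sign fixes the z-axis orientation so that positive u shifts map to
    # positive lateral shift at positive z, matching the geometric model
    kz = -2 * np.pi / lam * np.sqrt(np.maximum(n**2 - NA**2 * rho2, 0.0))
    phase_ab = pupil.aberration_phase(aberration) if aberration is not None else 0.0
    coords = grid.coordinates()
    A, D = len(coords), len(z_planes)
    full = np.empty((A, D, M, M), np.float32)
    for d, z in enumerate(z_planes):
        field = pupil.disk * np.exp(1j * (kz * z + phase_ab))
        for a, (u1, u2) in enumerate(coords):
            apod = field * pupil.subapertures[(int(u1), int(u2))]
            buf = np.zeros((M, M), complex)
            buf[:N, :N] = apod
            psf = np.abs(np.fft.fftshift(np.fft.fft2(buf))) ** 2
            full[a, d] = psf
    kernels = _crop_to_energy(full, energy_frac)
    center = grid.center_index()
    d0 = int(np.argmin(np.abs(z_planes)))
    norm = kernels[center, d0].sum()
    kernels = kernels / norm
    alpha = fit_alpha(kernels, coords, z_planes)
    stack = AngularPSFStack(
        kernels, grid, z_planes, alpha, model="waveoptics", zernike=aberration
    )
    stack.pixel_pitch = dx  # nm, recorded for resolution checks
    return stack


def full_aperture_psf(pupil: Pupil, z: float = 0.0, fft_size: int = 256):
    """Coherent full-pupil intensity PSF at depth z (no sub-aperture mask).

    Returns (psf, pixel_pitch_nm). At z = 0 its lateral FWHM approaches the
    Rayleigh limit 0.61 lambda / NA; the incoherent all-angle sum of
    sub-aperture PSFs is substantially wider (each view only sees a pupil
    patch), which is exactly why tomographic deconvolution is needed.
    """
    NA, lam, n = pupil.NA, pupil.wavelength, pupil.n
    N = pupil.grid_size
    dnu = (2 * NA / lam) / N
    M = max(fft_size, 2 * N)
    dx = 1.0 / (M * dnu)
    rho2 = pupil.rho_x**2 + pupil.rho_y**2
    kz = -2 * np.pi / lam * np.sqrt(np.maximum(n**2 - NA**2 * rho2, 0.0))
    field = pupil.disk * np.exp(1j * kz * z)
    buf = np.zeros((M, M), complex)
    buf[:N, :N] = field
    psf = np.abs(np.fft.fftshift(np.fft.fft2(buf))) ** 2
    return psf / psf.sum(), dx


def kernel_centroids(kernels: np.ndarray) -> np.ndarray:
    """Centroid (dy, dx) of each (angle, z) kernel relative to its center."""
    A, D, k, _ = kernels.shape
    c = k // 2
    idx = np.arange(k) - c
    mass = kernels.sum(axis=(-2, -1))
    cy = (kernels.sum(axis=-1) * idx).sum(axis=-1) / mass
    cx = (kernels.sum(axis=-2) * idx).sum(axis=-1) / mass
    return np.stack([cy, cx], axis=-1)


def fit_alpha(kernels: np.ndarray, coords: np.ndarray, z_planes: np.ndarray) -> float:
    """Least-squares slope of centroid displacement vs z*u across all views."""
    cent = kernel_centroids(kernels)  # (A, D, 2)
    zu = z_planes[None, :, None] * coords[:, None, :]  # (A, D, 2)
    num = float((cent * zu).sum())
    den = float((zu * zu).sum())
    return num / den if den > 0 else 1.0


def save_psf_stack(path, stack: AngularPSFStack) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("H", data=stack.kernels)
        d.attrs["half_extent"] = stack.grid.half_extent
        d.attrs["selection_mask"] = stack.grid.selection_mask.astype(np.uint8)
        d.attrs["z_planes"] = stack.z_planes
        d.attrs["alpha"] = stack.alpha
        d.attrs["model"] = stack.model
        if stack.zernike is not None:
            d.attrs["zernike"] = stack.zernike.coefficients
            d.attrs["zernike_modes"] = stack.zernike.mode_indices


def load_psf_stack(path) -> AngularPSFStack:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["H"]
        grid = AngularGrid(
            int(d.attrs["half_extent"]), np.asarray(d.attrs["selection_mask"], bool)
        )
        zern = None
        if "zernike" in d.attrs:
            zern = ZernikeCoeffs(
                np.asarray(d.attrs["zernike"]), tuple(d.attrs["zernike_modes"])
            )
        return AngularPSFStack(
            d[...], grid, np.asarray(d.attrs["z_planes"]), float(d.attrs["alpha"]),
            model=str(d.attrs["model"]), zernike=zern,
        )
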