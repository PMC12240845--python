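"""Evaluation metrics, resolution characterization and throughput accounting.

The similarity metrics follow the conventions used for benchmarking sLFM
reconstructions: RMSE, PSNR as 10*log10(peak(X)^2 / MSE), and a five-scale
MS-SSIM whose per-scale exponents are Gaussian-weighted around scale 3 and
whose SSIM stabilizing constants derive from the *reference maximum*
(0.01*max(X))^2 and (0.03*max(X))^2 rather than a nominal dynamic range —
note this makes the metric asymmetric in (X, Y) by design. Local SSIM maps
use sliding Gaussian windows (11 px, s.d. 1.5), 2D for images and 3D for
stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

__all__ = [
    "rmse",
    "psnr",
    "ssim",
    "ms_ssim",
    "fwhm_profile",
    "throughput",
    "dff0",
    "diffraction_limits",
    "MetricsReport",
    "evaluate_pair",
]

PSNR_INF = float("inf")


def rmse(X: np.ndarray, Y: np.ndarray) -> float:
    """Root-mean-square error sqrt(sum (X - Y)^2 / K)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("shape mismatch")
    if X.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(((X - Y) ** 2).mean()))


def psnr(X: np.ndarray, Y: np.ndarray) -> float:
    """Peak signal-to-noise ratio 10*log10(max(X)^2 / MSE), dB.

    Identical images return +inf.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("shape mismatch")
    mse = ((X - Y) ** 2).mean()
    if mse == 0:
        return PSNR_INF
    peak = float(np.abs(X).max())
    return float(10 * np.log10(peak**2 / mse))


def _gaussian_window(ndim: int, size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - size // 2
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    g1 /= g1.sum()
    w = g1
    for _ in range(ndim - 1):
        w = np.multiply.outer(w, g1)
    return w


def _filter(img: np.ndarray, w: np.ndarray) -> np.ndarray:
    return ndimage.convolve(img, w, mode="reflect")


def ssim(
    X: np.ndarray,
    Y: np.ndarray,
    max_ref: float | None = None,
    standard_constants: bool = False,
    data_range: float | None = None,
) -> float:
    """Mean local SSIM with Gaussian windows (11 px, s.d. 1.5).

    By default the stabilizing constants use ``max(X)`` of the reference;
    ``standard_constants`` switches to the conventional data-range form.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("shape mismatch")
    if max_ref is None:
        max_ref = float(X.max())
    if standard_constants:
        L = data_range if data_range is not None else float(X.max() - X.min())
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    else:
        if max_ref <= 0:
            raise ValueError("all-zero (or non-positive) reference: max(X) = 0")
        c1, c2 = (0.01 * max_ref) ** 2, (0.03 * max_ref) ** 2
    w = _gaussian_window(X.ndim)
    mx = _filter(X, w)
    my = _filter(Y, w)
    mxx = _filter(X * X, w)
    myy = _filter(Y * Y, w)
    mxy = _filter(X * Y, w)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    num = (2 * mx * my + c1) * (2 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return float((num / den).mean())


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2-fold average pooling on every axis (trailing odd pixels dropped)."""
    for ax in range(img.ndim):
        n = img.shape[ax] // 2
        sl = [slice(None)] * img.ndim
        sl[ax] = slice(0, 2 * n)
        img = img[tuple(sl)]
        shape = list(img.shape)
        shape[ax : ax + 1] = [n, 2]
        img = img.reshape(shape).mean(axis=ax + 1)
    return img


def ms_ssim(X: np.ndarray, Y: np.ndarray, scales: int = 5,
            standard_constants: bool = False) -> float:
    """Multiscale SSIM: prod_s SSIM(X_s, Y_s)^w_s, w_s prop. to e^{-(s-3)^2/2}.

    X_s, Y_s are 2^(s-1)-fold downsampled; weights are normalized to sum to
    one. If the field is too small for 11-px windows at the top scale the
    scale count is reduced with a warning.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    min_side = min(X.shape)
    usable = scales
    while usable > 1 and min_side // 2 ** (usable - 1) < 11:
        usable -= 1
    if usable < scales:
        import logging

        logging.getLogger(__name__).warning(
            "field too small for %d scales; using %d", scales, usable
        )
    s_idx = np.arange(1, usable + 1)
    w = np.exp(-((s_idx - 3.0) ** 2) / 2.0)
    w /= w.sum()
    vals = []
    Xs, Ys = X, Y
    for s in range(usable):
        if s > 0:
            Xs = _downsample2(Xs)
            Ys = _downsample2(Ys)
        vals.append(ssim(Xs, Ys, standard_constants=standard_constants))
    vals = np.asarray(vals)
    sign = np.sign(vals)
    return float(np.prod(sign * np.abs(vals) ** w))


def fwhm_profile(profile: np.ndarray, spacing: float = 1.0) -> float:
    """FWHM of a 1D profile via least-squares Gaussian fit.

    Fits A*exp(-(x-c)^2 / (2 s^2)) + b and returns 2*sqrt(2 ln 2)*s*spacing;
    NaN (with a warning) if the fit fails or the profile is flat.
    """
    y = np.asarray(profile, float)
    x = np.arange(len(y), dtype=float)
    if y.max() - y.min() <= 0:
        import logging

        logging.getLogger(__name__).warning("flat profile; FWHM undefined")
        return float("nan")

    def gauss(x, A, c, s, b):
        return A * np.exp(-((x - c) ** 2) / (2 * s**2)) + b

    p0 = [y.max() - y.min(), float(np.argmax(y)), max(len(y) / 8.0, 1.0), y.min()]
    try:
        popt, _ = curve_fit(gauss, x, y, p0=p0, maxfev=10000)
    except RuntimeError:
        import logging

        logging.getLogger(__name__).warning("Gaussian fit failed; FWHM = NaN")
        return float("nan")
    s = abs(popt[2])
    fwhm = float(2.0 * np.sqrt(2.0 * np.log(2.0)) * s * spacing)
    if fwhm > len(y) * spacing:
        # a width wider than the sampled support is not a measurement
        import logging

        logging.getLogger(__name__).warning(
            "fitted FWHM %.1f exceeds the profile support; returning NaN", fwhm
        )
        return float("nan")
    return fwhm


@dataclass
class ThroughputSpec:
    """Axial blocks of a volume with their average resolutions.

    ``D`` = (Dx, Dy, Dz) spatial ranges in um; ``r_xy``/``r_z`` per-block
    average lateral/axial resolutions in um; ``t_v`` seconds per volume.
    """

    D: tuple
    r_xy: np.ndarray
    r_z: np.ndarray
    t_v: float

    def __post_init__(self):
        self.r_xy = np.atleast_1d(np.asarray(self.r_xy, float))
        self.r_z = np.atleast_1d(np.asarray(self.r_z, float))
        if len(self.r_xy) != len(self.r_z):
            raise ValueError("r_xy and r_z must have one entry per block")
        if (
            min(self.D) <= 0
            or (self.r_xy <= 0).any()
            or (self.r_z <= 0).any()
            or self.t_v <= 0
        ):
            raise ValueError("all throughput fields must be positive")


def throughput(spec: ThroughputSpec):
    """(information content in bits, processing throughput in bits/s).

    Content = sum_p 16 * Dx*Dy*Dz / (r_xy_p^2 * r_z_p); throughput divides
    by the per-volume processing time t_v.
    """
    Dx, Dy, Dz = spec.D
    content = float((16.0 * Dx * Dy * Dz / (spec.r_xy**2 * spec.r_z)).sum())
    return content, content / spec.t_v


def dff0(trace: np.ndarray, baseline: str = "mean") -> np.ndarray:
    """Relative fluorescence change (F - F0)/F0 with F0 = mean(F)."""
    F = np.asarray(trace, float)
    if baseline != "mean":
        raise ValueError("only the mean-baseline rule is defined")
    F0 = F.mean()
    if F0 == 0:
        raise ValueError("zero baseline F0")
    return (F - F0) / F0


def diffraction_limits(NA: float, wavelength: float = 525.0, n: float = 1.515):
    """(lateral, axial) diffraction-limited resolution in nm.

    lateral = 0.61*lambda/NA (Rayleigh), axial = n*lambda/NA^2 (Abbe).
    """
    if NA <= 0:
        raise ValueError("NA must be > 0")
    return 0.61 * wavelength / NA, n * wavelength / NA**2


@dataclass
class MetricsReport:
    rmse: float
    psnr: float
    ms_ssim: float


def evaluate_pair(reference: np.ndarray, estimate: np.ndarray) -> MetricsReport:
    return MetricsReport(
        rmse=rmse(reference, estimate),
        psnr=psnr(reference, estimate),
        ms_ssim=ms_ssim(reference, estimate),
    )
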