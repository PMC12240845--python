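"""Camera noise calibration and the NLL-MPG loss.

The measurement model is M = Poisson(P) + N(mu, sigma^2) with latent photon
count tau. Marginalizing tau gives the mixed Poisson-Gaussian likelihood

    p(M | P) = sum_tau P^tau e^-P / tau! * N(M - tau; mu, sigma^2),

whose negative log is the NLL-MPG loss, evaluated per pixel with a windowed
logsumexp over tau. In the sigma -> 0 limit the Gaussian collapses to
tau = M - mu and the loss degenerates to the exact Poisson NLL
P - M log P + log M!, whose stationarity condition through the forward
projector reproduces the multiplicative Richardson-Lucy tomography update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import SpatialAngularStack

__all__ = [
    "GaussianCalibration",
    "calibrate_gaussian",
    "nll_mpg",
    "nll_mpg_grad",
    "poisson_nll",
    "baseline_loss",
]

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


@dataclass
class GaussianCalibration:
    """Read-noise parameters (counts) and their provenance."""

    mu: float
    sigma: float
    source: str = "dark_frames"
    exposure: str | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def calibrate_gaussian(
    frames: np.ndarray,
    exposure: str | None = None,
) -> GaussianCalibration:
    """Estimate (mu, sigma) from dark frames (no illumination).

    Robust location/scale: median and 1.4826 * MAD over all pixels, so hot
    pixels or residual signal do not bias the estimate. For calibration from
    the dark corner views of a light-field measurement see
    :func:`calibrate_from_corners`.
    """
    data = np.asarray(frames, float).ravel()
    source = "dark_frames"
    if data.size == 0:
        raise ValueError("empty calibration input")
    mu = float(np.median(data))
    sigma = float(1.4826 * np.median(np.abs(data - mu)))
    return GaussianCalibration(mu, sigma, source, exposure)


def calibrate_from_corners(full_stack: SpatialAngularStack, keep_mask: np.ndarray,
                           exposure: str | None = None) -> GaussianCalibration:
    """Calibrate from the dark corner views excluded by ``keep_mask``.

    ``full_stack`` holds all grid views; ``keep_mask`` is the selection that
    will be used for reconstruction. Only views *outside* it contribute.
    """
    grid_mask = full_stack.grid.selection_mask
    keep_mask = np.asarray(keep_mask, bool)
    corner = grid_mask & ~keep_mask
    if not corner.any():
        raise ValueError("no corner views outside the selection mask")
    take = corner.ravel()[grid_mask.ravel()]
    data = full_stack.views[take]
    cal = calibrate_gaussian(frames=data, exposure=exposure)
    return GaussianCalibration(cal.mu, cal.sigma, "corner_views", exposure)


def _tau_lattice(M: np.ndarray, mu: float, sigma: float):
    """Per-pixel integer tau lattice, shape (..., n_tau).

    The Gaussian factor exp(-(M - mu - tau)^2 / 2 sigma^2) confines the
    posterior over tau to M - mu +/- 6 sigma regardless of P, so a common
    half-width K = ceil(6 sigma) + 8 around each pixel's own center
    floor(M - mu) captures the mixture to below float64 resolution while
    keeping the lattice size independent of the brightness range. Lattices
    are clipped to tau >= 0 by shifting, not truncating.
    """
    K = int(np.ceil(6.0 * sigma)) + 8
    center = np.floor(M - mu).astype(np.int64)
    lo = np.maximum(center - K, 0)
    offsets = np.arange(2 * K + 1, dtype=np.int64)
    return (lo[..., None] + offsets).astype(float)


def poisson_nll(P: np.ndarray, M: np.ndarray, reduction: str = "mean") -> float:
    """Exact Poisson NLL: P - M log P + log Gamma(M + 1)."""
    P = np.asarray(P, float)
    M = np.asarray(M, float)
    val = P - M * np.log(np.maximum(P, 1e-30)) + gammaln(M + 1.0)
    return _reduce(val, reduction)


def _reduce(val, reduction):
    if reduction == "mean":
        return float(val.mean())
    if reduction == "sum":
        return float(val.sum())
    if reduction == "none":
        return val
    raise ValueError(f"unknown reduction {reduction!r}")


def _log_poisson_term(P: np.ndarray, tau: np.ndarray, stirling: bool) -> np.ndarray:
    """log [ P^tau e^-P / tau! ], exact (lgamma) or Stirling form."""
    logP = np.log(np.maximum(P, 1e-30))
    if not stirling:
        return tau * logP - P - gammaln(tau + 1.0)
    # Stirling: tau! ~ sqrt(2 pi tau) (tau/e)^tau ; tau=0 handled exactly
    out = np.where(
        tau > 0,
        tau * (logP - np.log(np.maximum(tau, 1.0))) + tau - P
        - 0.5 * np.log(2 * np.pi * np.maximum(tau, 1.0)),
        -P,
    )
    return out


def _mpg_logliks(P, M, mu, sigma, stirling):
    """Per-(pixel, tau) log joint and the tau lattice; shapes (..., n_tau).

    The Gaussian mixing weights are normalized over the integer tau lattice
    (theta-function normalizer) rather than with the continuous 1/(sqrt(2
    pi) sigma): the two agree to machine precision for sigma >~ 0.7, and
    the lattice form makes the mixture a proper pmf whose sigma -> 0 limit
    is exactly the Poisson NLL.
    """
    tau = _tau_lattice(M, mu, sigma)
    P = P[..., None]
    M = M[..., None]
    lp = _log_poisson_term(P, tau, stirling)
    lg = -((M - mu - tau) ** 2) / (2 * sigma**2)
    logZ = logsumexp(lg, axis=-1, keepdims=True)
    return lp + lg - logZ, tau


def nll_mpg(
    P: np.ndarray,
    M: np.ndarray,
    mu: float = 0.0,
    sigma: float = 0.0,
    reduction: str = "mean",
    stirling: bool = False,
) -> float:
    """Negative log-likelihood of M under Poisson(P) + N(mu, sigma^2).

    ``P`` must be non-negative. With ``sigma == 0`` the exact Poisson NLL is
    used (tau pinned to M - mu). Non-integer measurements are handled
    naturally: tau runs over integers while M enters only the Gaussian term.
    """
    P = np.asarray(P, float)
    M = np.asarray(M, float)
    if P.shape != M.shape:
        raise ValueError("prediction/measurement shape mismatch")
    if (P < 0).any():
        raise ValueError("prediction must be non-negative")
    if sigma <= 0:
        return poisson_nll(P, np.maximum(M - mu, 0.0), reduction)
    logw, _ = _mpg_logliks(P, M, mu, sigma, stirling)
    ll = logsumexp(logw, axis=-1)
    return _reduce(-ll, reduction)


def nll_mpg_grad(
    P: np.ndarray,
    M: np.ndarray,
    mu: float = 0.0,
    sigma: float = 0.0,
    stirling: bool = False,
):
    """Value (per pixel) and analytic gradient d(NLL)/dP.

    d/dP of -log sum_tau w_tau(P) is 1 - E[tau | M, P] / P, with the
    posterior expectation under the tau mixture weights.
    """
    P = np.asarray(P, float)
    M = np.asarray(M, float)
    if (P < 0).any():
        raise ValueError("prediction must be non-negative")
    if sigma <= 0:
        Meff = np.maximum(M - mu, 0.0)
        val = P - Meff * np.log(np.maximum(P, 1e-30)) + gammaln(Meff + 1.0)
        grad = 1.0 - Meff / np.maximum(P, 1e-12)
        return val, grad
    logw, tau = _mpg_logliks(P, M, mu, sigma, stirling)
    ll = logsumexp(logw, axis=-1)
    w = np.exp(logw - ll[..., None])
    tau_mean = (w * tau).sum(axis=-1)
    grad = 1.0 - tau_mean / np.maximum(P, 1e-12)
    return -ll, grad


def baseline_loss(prediction: np.ndarray, target: np.ndarray, kind: str = "L1") -> float:
    """Standard L1 / L2 losses used as comparison points for NLL-MPG."""
    p = np.asarray(prediction, float)
    t = np.asarray(target, float)
    if kind == "L1":
        return float(np.abs(p - t).mean())
    if kind == "L2":
        return float(((p - t) ** 2).mean())
    raise ValueError(f"unknown loss kind {kind!r}")
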