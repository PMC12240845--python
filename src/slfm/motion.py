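"""Time-weighted motion-artifact correction for scanned light fields.

An sLFM measurement at one timestamp is assembled from T = S^2 sequentially
scanned frames; sample motion during the scan produces checkerboard/stripe
artifacts. The classic time-weighted (TW) algorithm blends the sharp
assembled measurement M with a temporally weighted average of the
individual scan frames, each cubic-upsampled to the dense grid
(ShiftCubic):

    M_TW = r M + (1 - r) sum_t [ r^|t - T/2| / sum_tt r^|tt - T/2| ]
                           ShiftCubic(M_L(t), S)

The coefficient r in (0, 1] trades sharpness (r -> 1) against motion
suppression (r -> 0). TW-Net replaces the global scalar with a
content-aware coefficient map r(x) predicted per view by a small
convolutional network trained self-supervised: MSE against the temporally
smoothed estimate plus a negative-log regularizer that pushes r toward 1
wherever the scene is static.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import RawScanFrames, SpatialAngularStack
from . import nn

__all__ = [
    "TWCoefficientMap",
    "shift_cubic",
    "extract_lowres_views",
    "smooth_estimate",
    "time_weighted",
    "TWNet",
    "twnet_train",
    "twnet_apply",
]

R_EPS = 1e-3


@dataclass
class TWCoefficientMap:
    """Per-pixel time-weighted coefficients in [eps, 1].

    ``maps`` is (A, 3*H, 3*W) at the net's output sampling (3x the view
    sampling); ``at_view_sampling`` area-averages back to the (A, H, W)
    grid on which the TW blend operates.
    """

    maps: np.ndarray
    upsample: int = 3

    def __post_init__(self):
        self.maps = np.clip(np.asarray(self.maps, np.float32), R_EPS, 1.0)

    def at_view_sampling(self) -> np.ndarray:
        u = self.upsample
        A, h, w = self.maps.shape
        return self.maps.reshape(A, h // u, u, w // u, u).mean(axis=(2, 4))


def shift_cubic(frame: np.ndarray, pos, S: int = 3) -> np.ndarray:
    """Upsample one scan frame S-fold with cubic splines at its scan offset.

    Low-res sample (i, j) of a frame acquired at scan position (si, sj)
    lives at dense coordinate (S*i + si, S*j + sj); the dense grid is
    evaluated by cubic spline interpolation of the low-res samples.
    """
    frame = np.asarray(frame, np.float32)
    si, sj = pos
    H, W = frame.shape
    yy = (np.arange(S * H) - si) / S
    xx = (np.arange(S * W) - sj) / S
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    return ndimage.map_coordinates(
        frame, [gy, gx], order=3, mode="nearest"
    ).astype(np.float32)


def extract_lowres_views(stack: SpatialAngularStack, raw: RawScanFrames) -> np.ndarray:
    """Per-scan-time low-res views M_L(x, u, t), shape (T, A, H, W).

    Pulled from the assembled stack by sub-sampling each view at the scan
    lattice (equivalent to realigning each raw frame separately).
    """
    S = raw.S
    T = S * S
    A, sh, sw = stack.views.shape
    out = np.empty((T, A, sh // S, sw // S), np.float32)
    for t, (si, sj) in enumerate(raw.positions):
        out[t] = stack.views[:, si::S, sj::S]
    return out


def _temporal_weights(r, T: int):
    """Inverse-distance weights r^|t - T/2| normalized over t = 0..T-1.

    ``r`` may be a scalar or a per-pixel map; the scan-period center is
    T/2 (4.5 for T = 9). r is clamped to [eps, 1].
    """
    t = np.arange(T, dtype=np.float32)
    dist = np.abs(t - T / 2.0)
    r = np.clip(r, R_EPS, 1.0)
    if np.isscalar(r) or np.ndim(r) == 0:
        w = np.power(float(r), dist)
        return w / w.sum()
    w = np.power(np.asarray(r, np.float32)[None, ...], dist.reshape(-1, *([1] * np.ndim(r))))
    return w / w.sum(axis=0, keepdims=True)


def smooth_estimate(
    lowres: np.ndarray, positions: np.ndarray, S: int, r=0.5
) -> np.ndarray:
    """Temporally weighted ShiftCubic average, shape (A, S*H, S*W)."""
    T, A, H, W = lowres.shape
    w = _temporal_weights(r, T)
    per_pixel = not (np.isscalar(r) or np.ndim(r) == 0)
    out = np.zeros((A, S * H, S * W), np.float32)
    for t in range(T):
        wt = w[t] if per_pixel else float(w[t])
        for a in range(A):
            up = shift_cubic(lowres[t, a], positions[t], S)
            if per_pixel:
                out[a] += w[t, a] * up
            else:
                out[a] += wt * up
    return out


def time_weighted(
    stack: SpatialAngularStack,
    raw: RawScanFrames,
    r,
) -> SpatialAngularStack:
    """Apply the time-weighted blend with a scalar r or a TWCoefficientMap."""
    if isinstance(r, TWCoefficientMap):
        r_map = r.at_view_sampling()
        if r_map.shape != stack.views.shape:
            raise ValueError("coefficient map shape does not match stack views")
        return _time_weighted_impl(stack, raw, r_map)
    r = float(r)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    if r < R_EPS:
        import logging

        logging.getLogger(__name__).info("clamping r=%g to %g", r, R_EPS)
        r = R_EPS
    if r == 1.0:
        return SpatialAngularStack(
            stack.views.copy(), stack.grid, stack.pixel_pitch, stack.timestamp
        )
    return _time_weighted_impl(stack, raw, r)


def _time_weighted_impl(stack, raw, r):
    S = raw.S
    lowres = extract_lowres_views(stack, raw)
    smooth = smooth_estimate(lowres, raw.positions, S, r)
    out = r * stack.views + (1.0 - r) * smooth
    return SpatialAngularStack(
        out.astype(np.float32), stack.grid, stack.pixel_pitch, stack.timestamp
    )


# ---------------------------------------------------------------------------
# TW-Net

class TWNet:
    """Lightweight per-view coefficient-map network.

    Maps a single-view patch (1, H, W) to a sigmoid coefficient map
    (1, 3H, 3W); a 153-px input yields a 459-px map. Five conv layers
    around a 3x linear upsampling, ~19k parameters.
    """

    def __init__(self, seed: int = 0, width: int = 24):
        rng = np.random.default_rng(seed)
        self.model = nn.Sequential(
            nn.Conv2d(1, width, 3, rng), nn.LeakyReLU(),
            nn.Conv2d(width, width, 3, rng), nn.LeakyReLU(),
            nn.Conv2d(width, width, 3, rng), nn.LeakyReLU(),
            nn.Upsample2d(3, 1),
            nn.Conv2d(width, 16, 3, rng), nn.LeakyReLU(),
            nn.Conv2d(16, 1, 3, rng),
            nn.Sigmoid(),
        )

    def n_params(self) -> int:
        return self.model.n_params()

    def predict(self, view: np.ndarray) -> np.ndarray:
        """Coefficient map (3H, 3W) for one view (H, W)."""
        out = self.model.forward(np.asarray(view, np.float32)[None])
        return np.clip(out[0], R_EPS, 1.0)

    def state_dict(self):
        return self.model.state_dict()

    def load_state_dict(self, state):
        self.model.load_state_dict(state)


def _downsample_mean(x: np.ndarray, f: int) -> np.ndarray:
    h, w = x.shape
    return x.reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def twnet_train(
    dataset,
    seed: int = 0,
    epochs: int = 2,
    lr: float = 2e-3,
    lam: float = 0.05,
    width: int = 24,
    smooth_r: float = 0.5,
) -> TWNet:
    """Self-supervised TW-Net training.

    ``dataset`` is a sequence of (stack, raw) pairs. For every view the
    target is the temporally smoothed estimate D (ShiftCubic average with
    reference weighting ``smooth_r``); the loss is

        mean( (TW(M, r(x)) - D)^2 ) + lam * mean( -log r(x) )

    whose per-pixel stationarity 2 r d^2 = lam / r (d = M - D) drives r
    toward 1 in static regions and down where the scan frames disagree.
    Deterministic under ``seed``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    net = TWNet(seed=seed, width=width)
    opt = nn.Adam(net.model, lr=lr)
    rng = np.random.default_rng(seed + 1)
    # precompute per-sample view inputs and smooth targets
    samples = []
    for stack, raw in dataset:
        lowres = extract_lowres_views(stack, raw)
        D = smooth_estimate(lowres, raw.positions, raw.S, smooth_r)
        for a in range(stack.views.shape[0]):
            samples.append((stack.views[a], D[a]))
    for _ in range(epochs):
        order = rng.permutation(len(samples))
        for idx in order:
            M, D = samples[idx]
            # rms normalization keeps the MSE / -log r balance scene-free
            scale = max(float(np.sqrt((M**2).mean())), 1e-6)
            x = (M / scale)[None].astype(np.float32)
            rmap3 = net.model.forward(x)[0]  # (3H, 3W)
            rmap = np.clip(_downsample_mean(rmap3, 3), R_EPS, 1.0)
            d = (M - D) / scale
            resid = rmap * d  # (TW - D) / scale
            n = resid.size
            # d(MSE)/dr + d(lam * -log r)/dr, averaged per pixel
            grad_r = (2.0 * resid * d - lam / rmap) / n
            # spread through the 3x area mean
            grad3 = np.repeat(np.repeat(grad_r, 3, 0), 3, 1) / 9.0
            opt.zero_grad()
            net.model.backward(grad3[None].astype(np.float32))
            opt.step()
    return net


def twnet_apply(
    stack: SpatialAngularStack, raw: RawScanFrames, net: TWNet
):
    """Infer coefficient maps for every view and apply the TW blend.

    Returns (corrected stack, TWCoefficientMap). Deterministic given the
    trained weights.
    """
    A, H, W = stack.views.shape
    maps = np.empty((A, 3 * H, 3 * W), np.float32)
    for a in range(A):
        view = stack.views[a]
        scale = max(float(np.sqrt((view**2).mean())), 1e-6)
        maps[a] = net.predict(view / scale)
    cmap = TWCoefficientMap(maps)
    corrected = time_weighted(stack, raw, cmap)
    return corrected, cmap
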