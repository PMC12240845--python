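"""Digital refocusing: depth decomposition and classic integrated refocus.

Shift-and-sum refocusing synthesizes focus at depth z by resampling each
angular view at x + alpha*z*u, cancelling the forward displacement of a
depth-z point (which this package's PSF convention places at +alpha*z*u),
and averaging over angles. The *depth decomposition* used as the network
front end performs only the shift step, g_a(x, u, z) = M(x + alpha*z*u, u),
preserving the angular dimension for learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SpatialAngularStack, Volume

__all__ = ["RefocusedStack", "depth_decompose", "refocus_integrate", "shift_view"]


def shift_view(view: np.ndarray, dy: float, dx: float, order: int = 1) -> np.ndarray:
    """Translate a 2D image by (dy, dx) with spline interpolation, zero fill."""
    return ndimage.shift(view, (dy, dx), order=order, mode="constant", cval=0.0)


@dataclass
class RefocusedStack:
    """Per-angle, per-depth shifted views g_a(x, u, z), shape (A, D, H, W)."""

    data: np.ndarray
    z_planes: np.ndarray
    alpha: float
    coords: np.ndarray  # angular coordinates (A, 2)
    interpolation: str = "bilinear"

    @property
    def shape(self):
        return self.data.shape


def depth_decompose(
    stack: SpatialAngularStack,
    z_planes,
    alpha: float,
    order: int = 1,
) -> RefocusedStack:
    """Resample every view at x + alpha*z*u per depth; no angular integration.

    The shift direction is the one that re-centers the image of a depth-z
    point (forward displacement +alpha*z*u). A 49 x H' x W' input with D
    planes becomes 49 x D x H' x W'. Sub-pixel shifts use bilinear
    interpolation by default (``order=1``; cubic with ``order=3``).
    """
    z_planes = np.asarray(z_planes, float)
    coords = stack.grid.coordinates()
    A = stack.views.shape[0]
    D = len(z_planes)
    H, W = stack.views.shape[-2:]
    max_shift = float(np.abs(alpha * z_planes[:, None, None] * coords[None]).max())
    if max_shift >= min(H, W):
        raise ValueError(
            f"refocus shift {max_shift:.1f} px exceeds image size {(H, W)}"
        )
    out = np.empty((A, D, H, W), np.float32)
    for a, (u1, u2) in enumerate(coords):
        view = stack.views[a]
        for d, z in enumerate(z_planes):
            if z == 0 or (u1 == 0 and u2 == 0):
                if alpha * z * u1 == 0 and alpha * z * u2 == 0:
                    out[a, d] = view
                    continue
            out[a, d] = shift_view(view, -alpha * z * u1, -alpha * z * u2, order=order)
    return RefocusedStack(
        out, z_planes, float(alpha), coords,
        interpolation={1: "bilinear", 3: "cubic"}.get(order, f"spline{order}"),
    )


def refocus_integrate(rstack: RefocusedStack) -> Volume:
    """Classic refocused volume: mean over angles per depth (blurry baseline)."""
    return Volume(rstack.data.mean(axis=0), rstack.z_planes)
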