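"""Core data model for scanning light-field microscopy (sLFM).

An sLFM acquisition samples a 4D phase space M(x, u): a lateral spatial
coordinate x = (y, x) and an angular coordinate u = (u1, u2) given by the
pixel position behind each microlens. With an Npix x Npix = 13 x 13 pixel
microlens and S x S = 3 x 3 sub-pitch galvo scanning, the T = S^2 raw camera
frames (each Npix*H x Npix*W) are *realigned* into Npix^2 spatial-angular
views of size S*H x S*W. Arrays are ordered (depth, y, x); angular offsets
are integers with (0, 0) on the optical axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "AngularGrid",
    "RawScanFrames",
    "SpatialAngularStack",
    "Volume",
    "realign",
    "unrealign",
    "select_views",
    "scan_positions",
]

_DTYPE = np.float32


def _as_float(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype == _DTYPE:
        return a
    return a.astype(_DTYPE)


@dataclass(frozen=True)
class AngularGrid:
    """Square lattice of angular coordinates behind one microlens.

    ``half_extent`` is 6 for the standard 13 x 13 system. ``selection_mask``
    marks the views kept for processing; the central view (0, 0) is always
    part of any non-empty selection.
    """

    half_extent: int = 6
    selection_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.half_extent < 0:
            raise ValueError("half_extent must be >= 0")
        n = self.npix
        if self.selection_mask is None:
            object.__setattr__(self, "selection_mask", np.ones((n, n), bool))
        else:
            mask = np.asarray(self.selection_mask, bool)
            if mask.shape != (n, n):
                raise ValueError(f"selection_mask must be {(n, n)}, got {mask.shape}")
            if mask.any() and not mask[self.half_extent, self.half_extent]:
                raise ValueError("center view (0,0) must be selected")
            object.__setattr__(self, "selection_mask", mask)

    @property
    def npix(self) -> int:
        return 2 * self.half_extent + 1

    @property
    def n_selected(self) -> int:
        return int(self.selection_mask.sum())

    def coordinates(self, selected_only: bool = True) -> np.ndarray:
        """Integer angular offsets (u1, u2), row-major over the grid."""
        h = self.half_extent
        u1, u2 = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
        coords = np.stack([u1.ravel(), u2.ravel()], axis=1)
        if selected_only:
            coords = coords[self.selection_mask.ravel()]
        return coords

    def center_index(self) -> int:
        """Index of the (0,0) view among the selected views."""
        coords = self.coordinates()
        (idx,) = np.nonzero((coords == 0).all(axis=1))
        return int(idx[0])

    def with_selection(self, mask: np.ndarray) -> "AngularGrid":
        return AngularGrid(self.half_extent, mask)


def scan_positions(S: int) -> np.ndarray:
    """Row-major (si, sj) lattice positions of an S x S scan, shape (S*S, 2)."""
    si, sj = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
    return np.stack([si.ravel(), sj.ravel()], axis=1)


@dataclass
class RawScanFrames:
    """T = S^2 raw camera frames, one per galvo scan position.

    ``frames`` has shape (T, Npix*H, Npix*W); ``positions[t]`` is the
    sub-pitch lattice offset (si, sj) of frame t.
    """

    frames: np.ndarray
    positions: np.ndarray
    half_extent: int = 6

    def __post_init__(self):
        self.frames = _as_float(self.frames)
        self.positions = np.asarray(self.positions, int)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, height, width)")
        T = self.frames.shape[0]
        S = int(round(np.sqrt(T)))
        if S * S != T:
            raise ValueError(f"frame count T={T} is not a perfect square")
        if self.positions.shape != (T, 2):
            raise ValueError("positions must be (T, 2)")
        lattice = {tuple(p) for p in self.positions}
        if lattice != {(i, j) for i in range(S) for j in range(S)}:
            raise ValueError("positions must be a bijection onto the SxS lattice")

    @property
    def S(self) -> int:
        return int(round(np.sqrt(self.frames.shape[0])))

    @property
    def npix(self) -> int:
        return 2 * self.half_extent + 1


@dataclass
class SpatialAngularStack:
    """Realigned spatial-angular views M(x, u).

    ``views`` has shape (A, S*H, S*W) with A the number of selected angles in
    ``grid``, row-major over the selected (u1, u2).
    """

    views: np.ndarray
    grid: AngularGrid
    pixel_pitch: float = 1.0
    timestamp: float = 0.0

    def __post_init__(self):
        self.views = _as_float(self.views)
        if self.views.ndim != 3:
            raise ValueError("views must be (A, height, width)")
        if self.views.shape[0] != self.grid.n_selected:
            raise ValueError(
                f"view count {self.views.shape[0]} != selected angles {self.grid.n_selected}"
            )
        if not np.isfinite(self.views).all():
            raise ValueError("views contain non-finite values")

    @property
    def shape(self):
        return self.views.shape

    def center_view(self) -> np.ndarray:
        return self.views[self.grid.center_index()]


@dataclass
class Volume:
    """A 3D sample estimate g(x, z) on a (depth, y, x) voxel grid."""

    voxels: np.ndarray
    z_planes: np.ndarray
    lateral_pitch: float = 1.0

    def __post_init__(self):
        self.voxels = _as_float(self.voxels)
        self.z_planes = np.asarray(self.z_planes, float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be (depth, height, width)")
        if self.voxels.shape[0] != len(self.z_planes):
            raise ValueError(
                f"depth {self.voxels.shape[0]} != len(z_planes) {len(self.z_planes)}"
            )

    @property
    def shape(self):
        return self.voxels.shape


def realign(raw: RawScanFrames, grid: AngularGrid | None = None) -> SpatialAngularStack:
    """Permute raw scanned frames into spatial-angular views.

    View (u1, u2) at spatial index (S*i + si, S*j + sj) equals raw frame at
    scan position (si, sj), microlens (i, j), intra-lens pixel
    (u1 + half_extent, u2 + half_extent). Pure index permutation, bit-exact.
    """
    if grid is None:
        grid = AngularGrid(raw.half_extent)
    if grid.half_extent != raw.half_extent:
        raise ValueError("grid half_extent does not match raw frames")
    npix = raw.npix
    T, fh, fw = raw.frames.shape
    if fh % npix or fw % npix:
        raise ValueError(
            f"frame sides ({fh}, {fw}) not divisible by microlens size {npix}"
        )
    S = raw.S
    H, W = fh // npix, fw // npix
    # (T, H, npix, W, npix) -> angle-major lens-resolved layout
    f = raw.frames.reshape(T, H, npix, W, npix)
    views = np.empty((npix * npix, S * H, S * W), dtype=f.dtype)
    # per-angle image: lens index (i, j) interleaved with scan offset (si, sj)
    per_angle = np.transpose(f, (2, 4, 0, 1, 3))  # (npix, npix, T, H, W)
    per_angle = per_angle.reshape(npix * npix, T, H, W)
    for t in range(T):
        si, sj = raw.positions[t]
        views[:, si::S, sj::S] = per_angle[:, t]
    stack = SpatialAngularStack(views, AngularGrid(grid.half_extent))
    if not grid.selection_mask.all():
        stack = select_views(stack, mask=grid.selection_mask)
    return stack


def unrealign(stack: SpatialAngularStack, S: int) -> RawScanFrames:
    """Exact inverse of :func:`realign`; requires the full angular grid."""
    grid = stack.grid
    if not grid.selection_mask.all():
        raise ValueError("unrealign requires the full angular grid (no views dropped)")
    npix = grid.npix
    A, sh, sw = stack.views.shape
    if sh % S or sw % S:
        raise ValueError(f"view sides ({sh}, {sw}) not divisible by S={S}")
    H, W = sh // S, sw // S
    positions = scan_positions(S)
    T = S * S
    frames = np.empty((T, npix * H, npix * W), dtype=stack.views.dtype)
    f = frames.reshape(T, H, npix, W, npix)
    per_angle = stack.views.reshape(npix, npix, sh, sw)
    for t, (si, sj) in enumerate(positions):
        sub = per_angle[:, :, si::S, sj::S]  # (npix, npix, H, W)
        f[t] = np.transpose(sub, (2, 0, 3, 1))
    return RawScanFrames(frames, positions, grid.half_extent)


def _selection_from_rule(grid: AngularGrid, rule: str, k: int | None, radius: float | None):
    h = grid.half_extent
    u1, u2 = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    if rule == "central_square":
        if k is None:
            k = 7
        if k % 2 == 0:
            raise ValueError("central_square size must be odd")
        half = k // 2
        mask = (np.abs(u1) <= half) & (np.abs(u2) <= half)
    elif rule == "disk":
        if radius is None:
            raise ValueError("disk rule requires a radius")
        mask = u1 * u1 + u2 * u2 <= radius * radius
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if not mask.any():
        raise ValueError("selection rule selects zero views")
    return mask


def select_views(
    stack: SpatialAngularStack,
    rule: str = "central_square",
    k: int | None = None,
    radius: float | None = None,
    mask: np.ndarray | None = None,
) -> SpatialAngularStack:
    """Keep the views near the microlens center (default: central 7x7 = 49).

    Idempotent for a fixed rule: applying the same rule to an already selected
    stack returns the intersection, which equals the selection itself.
    """
    grid = stack.grid
    if mask is None:
        mask = _selection_from_rule(grid, rule, k, radius)
    else:
        mask = np.asarray(mask, bool)
    new_mask = grid.selection_mask & mask
    if not new_mask.any():
        raise ValueError("selection rule selects zero views")
    keep = new_mask.ravel()[grid.selection_mask.ravel()]
    return SpatialAngularStack(
        stack.views[keep],
        grid.with_selection(new_mask),
        pixel_pitch=stack.pixel_pitch,
        timestamp=stack.timestamp,
    )


# ---------------------------------------------------------------------------
# TIFF I/O — multi-page TIFF with JSON axis metadata in the description tag.

def save_stack(path, stack: SpatialAngularStack) -> None:
    meta = {
        "kind": "spatial_angular_stack",
        "half_extent": stack.grid.half_extent,
        "selection_mask": stack.grid.selection_mask.astype(int).tolist(),
        "pixel_pitch": stack.pixel_pitch,
        "timestamp": stack.timestamp,
    }
    tifffile.imwrite(path, stack.views, description=json.dumps(meta))


def load_stack(path) -> SpatialAngularStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    grid = AngularGrid(meta["half_extent"], np.asarray(meta["selection_mask"], bool))
    return SpatialAngularStack(
        data, grid, pixel_pitch=meta.get("pixel_pitch", 1.0),
        timestamp=meta.get("timestamp", 0.0),
    )


def save_raw_frames(path, raw: RawScanFrames) -> None:
    meta = {
        "kind": "raw_scan_frames",
        "half_extent": raw.half_extent,
        "positions": raw.positions.tolist(),
    }
    tifffile.imwrite(path, raw.frames, description=json.dumps(meta))


def load_raw_frames(path) -> RawScanFrames:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return RawScanFrames(data, np.asarray(meta["positions"]), meta["half_extent"])


def save_volume(path, vol: Volume) -> None:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("volume", data=vol.voxels)
            d.attrs["z_planes"] = vol.z_planes
            d.attrs["lateral_pitch"] = vol.lateral_pitch
    else:
        meta = {
            "kind": "volume",
            "z_planes": vol.z_planes.tolist(),
            "lateral_pitch": vol.lateral_pitch,
        }
        tifffile.imwrite(path, vol.voxels, description=json.dumps(meta))


def load_volume(path) -> Volume:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            d = f["volume"]
            return Volume(d[...], d.attrs["z_planes"], float(d.attrs["lateral_pitch"]))
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return Volume(data, np.asarray(meta["z_planes"]), meta.get("lateral_pitch", 1.0))
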