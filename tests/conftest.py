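import numpy as np
import pytest

from slfm.core import AngularGrid, RawScanFrames, scan_positions
from slfm.psf import geometric_psf
from slfm.simulate import BubtubConfig, NoiseModel, generate_bubtub


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid5():
    """5x5 angular grid (half_extent 2) used for desk-scale tests."""
    return AngularGrid(2)


@pytest.fixture
def grid13():
    """The full 13x13 grid of the standard system."""
    return AngularGrid(6)


@pytest.fixture
def mini_psfs(grid5):
    """Geometric PSFs for the desk-scale geometry: 21 planes, alpha 0.35."""
    z = np.linspace(-10, 10, 21)
    return geometric_psf(grid5, z, 0.35)


@pytest.fixture
def raw_frames_random(rng):
    """Random 3x3-scan raw frames for a 13x13 system with 2x3 microlenses."""
    frames = rng.random((9, 26, 39)).astype(np.float32)
    return RawScanFrames(frames, scan_positions(3), half_extent=6)


def make_bubtub(psfs, seed, noise=None, **overrides):
    """One desk-scale bubtub sample rendered through the given PSFs."""
    cfg = BubtubConfig(
        shape=(len(psfs.z_planes), 33, 33),
        n_bubbles=(1, 2),
        n_beads=(1, 4),
        n_tubes=(1, 2),
        bubble_radius=(3, 7),
        bead_radius=(1, 2.5),
        tube_radius=(1, 1.8),
        noise=noise or NoiseModel(0.0, 2.0, 60.0),
        seed=seed,
        **overrides,
    )
    return generate_bubtub(cfg, psfs)
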