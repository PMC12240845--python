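"""Time-weighted motion correction: ShiftCubic, the TW blend, and TW-Net."""

import numpy as np
import pytest

from slfm.core import AngularGrid, RawScanFrames, SpatialAngularStack, Volume, realign, scan_positions, unrealign
from slfm.motion import (
    TWCoefficientMap,
    TWNet,
    extract_lowres_views,
    shift_cubic,
    smooth_estimate,
    time_weighted,
    twnet_apply,
    twnet_train,
)
from slfm.psf import geometric_psf
from slfm.simulate import simulate_measurement


@pytest.fixture
def static_scene(mini_psfs):
    """A static textured volume rendered to a 3x3-scanned acquisition.

    Uses a 3x3 angular grid with S=3 so the raw/stack round trip is exact.
    """
    grid = AngularGrid(1)
    z = np.linspace(-3, 3, 7)
    psfs = geometric_psf(grid, z, 0.4)
    rng = np.random.default_rng(5)
    from scipy.ndimage import gaussian_filter

    vol = gaussian_filter(rng.random((7, 24, 24)), (0.5, 3.0, 3.0)).astype(np.float32)
    stack = simulate_measurement(Volume(vol, z), psfs, S=3)
    raw = unrealign(stack, 3)
    return stack, raw


class TestShiftCubic:
    def test_constant_frame_invariant(self):
        out = shift_cubic(np.full((10, 10), 2.5, np.float32), (1, 2), 3)
        np.testing.assert_allclose(out, 2.5, rtol=1e-5)

    def test_zero_offset_pure_upsample(self):
        """pos=(0,0): plain 3x cubic interpolation through the samples."""
        frame = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        up = shift_cubic(frame, (0, 0), 3)
        assert up.shape == (24, 24)
        np.testing.assert_allclose(up[::3, ::3], frame, atol=1e-5)

    def test_bandlimited_sinusoid_accuracy(self):
        """Interpolation error on a smooth sinusoid is below 1% RMS."""
        y, x = np.mgrid[0:16, 0:16].astype(float)
        frame = np.sin(2 * np.pi * y / 16) * np.cos(2 * np.pi * x / 16)
        up = shift_cubic(frame.astype(np.float32), (1, 2), 3)
        yy = (np.arange(48) - 1) / 3.0
        xx = (np.arange(48) - 2) / 3.0
        gy, gx = np.meshgrid(yy, xx, indexing="ij")
        want = np.sin(2 * np.pi * gy / 16) * np.cos(2 * np.pi * gx / 16)
        inner = (slice(6, -6), slice(6, -6))
        err = np.sqrt(np.mean((up[inner] - want[inner]) ** 2))
        assert err <= 0.01


class TestTimeWeighted:
    def test_r1_identity_bit_exact(self, static_scene):
        stack, raw = static_scene
        out = time_weighted(stack, raw, 1.0)
        np.testing.assert_array_equal(out.views, stack.views)

    def test_static_scene_invariance(self, static_scene):
        """A static sample is nearly unchanged for any r (interpolation
        only; the field border is excluded — scan interpolants cannot
        represent the hard field-of-view edge)."""
        stack, raw = static_scene
        inner = (slice(None), slice(4, -4), slice(4, -4))
        for r in (0.2, 0.5, 0.8):
            out = time_weighted(stack, raw, r)
            rms = np.sqrt(np.mean((out.views[inner] - stack.views[inner]) ** 2))
            scale = np.sqrt(np.mean(stack.views[inner] ** 2))
            assert rms / scale <= 0.01

    def test_r_out_of_range_rejected(self, static_scene):
        stack, raw = static_scene
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            time_weighted(stack, raw, 1.5)

    def test_artifact_energy_monotone_in_r(self):
        """Simulated intra-scan motion: high-frequency artifact energy
        (residual vs the motion-free reference) decreases as r drops."""
        grid = AngularGrid(1)
        z = np.linspace(-3, 3, 7)
        psfs = geometric_psf(grid, z, 0.4)
        rng = np.random.default_rng(7)
        from scipy.ndimage import gaussian_filter, shift as ndshift

        vol = gaussian_filter(rng.random((7, 24, 24)), (0.5, 2.5, 2.5)).astype(
            np.float32
        )
        clean = simulate_measurement(Volume(vol, z), psfs, S=3)
        # re-render each scan frame from a laterally drifting volume
        raw_clean = unrealign(clean, 3)
        frames = raw_clean.frames.copy()
        for t in range(9):
            drift = 2.4 * t / 8.0
            moved = np.stack([ndshift(vol[d], (drift, 0), order=1) for d in range(7)])
            mstack = simulate_measurement(Volume(moved, z), psfs, S=3)
            frames[t] = unrealign(mstack, 3).frames[t]
        raw = RawScanFrames(frames, raw_clean.positions, 1)
        stack = realign(raw)
        energies = []
        for r in (1.0, 0.8, 0.6, 0.4, 0.2):
            out = time_weighted(stack, raw, r)
            resid = out.views - clean.views
            # high-frequency (checkerboard) component of the residual
            hf = resid - np.stack([gaussian_filter(v, 1.5) for v in resid])
            energies.append(float((hf**2).sum()))
        assert all(a > b for a, b in zip(energies, energies[1:]))


class TestTWNet:
    def test_map_shape_contract(self):
        """153-px single-view input -> 459-px coefficient map."""
        net = TWNet(seed=0)
        out = net.predict(np.zeros((153, 153), np.float32))
        assert out.shape == (459, 459)

    def test_static_data_learns_large_r(self, static_scene):
        stack, raw = static_scene
        net = twnet_train([(stack, raw)], seed=0, epochs=3, lr=5e-3)
        _, cmap = twnet_apply(stack, raw, net)
        assert float(cmap.maps.mean()) >= 0.9

    def test_moving_region_gets_smaller_r(self):
        """r is lower inside a locally moving region than outside."""
        grid = AngularGrid(1)
        z = np.linspace(-3, 3, 7)
        psfs = geometric_psf(grid, z, 0.4)
        rng = np.random.default_rng(11)
        from scipy.ndimage import gaussian_filter, shift as ndshift

        vol = gaussian_filter(rng.random((7, 24, 24)), (0.5, 2.5, 2.5)).astype(
            np.float32
        )
        clean = simulate_measurement(Volume(vol, z), psfs, S=3)
        raw_clean = unrealign(clean, 3)
        frames = raw_clean.frames.copy()
        for t in range(9):
            moved = vol.copy()
            # move only the central block of the sample
            drift = 2.0 * t / 8.0
            moved[:, 7:17, 7:17] = np.stack(
                [ndshift(vol[d, 7:17, 7:17], (drift, drift), order=1) for d in range(7)]
            )
            mstack = simulate_measurement(Volume(moved, z), psfs, S=3)
            frames[t] = unrealign(mstack, 3).frames[t]
        raw = RawScanFrames(frames, raw_clean.positions, 1)
        stack = realign(raw)
        net = twnet_train([(stack, raw)], seed=1, epochs=8, lr=2e-3)
        _, cmap = twnet_apply(stack, raw, net)
        r_view = cmap.at_view_sampling()
        inside = r_view[:, 8:16, 8:16].mean()
        outside_mask = np.ones((24, 24), bool)
        outside_mask[5:20, 5:20] = False  # guard band around the moving block
        outside = r_view[:, outside_mask].mean()
        assert inside < outside

    def test_apply_deterministic_and_shape_preserving(self, static_scene):
        stack, raw = static_scene
        net = twnet_train([(stack, raw)], seed=0, epochs=1)
        out1, m1 = twnet_apply(stack, raw, net)
        out2, m2 = twnet_apply(stack, raw, net)
        np.testing.assert_array_equal(out1.views, out2.views)
        np.testing.assert_array_equal(m1.maps, m2.maps)
        assert out1.views.shape == stack.views.shape

    def test_idempotent_on_static_data(self, static_scene):
        stack, raw = static_scene
        net = twnet_train([(stack, raw)], seed=0, epochs=2, lr=5e-3)
        once, _ = twnet_apply(stack, raw, net)
        raw_once = unrealign(once, 3)
        twice, _ = twnet_apply(once, raw_once, net)
        rms = np.sqrt(np.mean((twice.views - once.views) ** 2))
        scale = np.sqrt(np.mean(once.views**2))
        assert rms / scale <= 0.005

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            twnet_train([], seed=0)

    def test_coefficient_map_clamped(self):
        cmap = TWCoefficientMap(np.full((1, 6, 6), -3.0))
        assert cmap.maps.min() >= 1e-3
        assert cmap.maps.max() <= 1.0
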