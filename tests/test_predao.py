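"""One-shot digital adaptive optics: disparities, defocus exclusion, wavefront."""

import numpy as np
import pytest
from scipy import ndimage

from slfm.core import AngularGrid, SpatialAngularStack
from slfm.predao import (
    correct_views,
    estimate_disparities,
    exclude_defocus,
    fit_wavefront,
    synthesize_disparities,
    DisparityField,
)
from slfm.psf import DEFAULT_MODES, ZernikeCoeffs


def _texture(rng, n=64, smooth=3.0):
    """Smooth random texture with enough structure for correlation."""
    t = rng.random((n, n))
    return ndimage.gaussian_filter(t, smooth).astype(np.float32)


def _shifted_stack(grid, base, shifts):
    """Views built by warping one texture with known per-view shifts."""
    views = np.stack(
        [
            ndimage.shift(base, (dy, dx), order=3, mode="nearest").astype(np.float32)
            for dy, dx in shifts
        ]
    )
    return SpatialAngularStack(views, grid)


class TestEstimateDisparities:
    def test_identical_views_zero(self, grid5, rng):
        base = _texture(rng)
        stack = SpatialAngularStack(np.repeat(base[None], 25, 0), grid5)
        disp = estimate_disparities(stack)
        np.testing.assert_allclose(disp.shifts, 0.0, atol=1e-3)

    def test_integer_shifts_recovered(self, grid5, rng):
        """Circularly shifted views (true translations) up to +/-5 px."""
        base = _texture(rng, smooth=2.0)
        true = rng.integers(-5, 6, (25, 2)).astype(float)
        true[AngularGrid(2).center_index()] = 0
        views = np.stack(
            [np.roll(base, (int(dy), int(dx)), (0, 1)) for dy, dx in true]
        )
        stack = SpatialAngularStack(views, grid5)
        disp = estimate_disparities(stack)
        rmse = np.sqrt(((disp.shifts - true) ** 2).mean())
        assert rmse <= 0.25

    def test_subpixel_shifts_within_quarter_pixel(self, grid5, rng):
        """Fractional shifts realized by spline-warping a larger texture."""
        big = ndimage.gaussian_filter(rng.random((128, 128)), 2.0).astype(np.float32)
        true = rng.uniform(-1.0, 1.0, (25, 2))
        true[AngularGrid(2).center_index()] = 0
        views = np.stack(
            [ndimage.shift(big, (dy, dx), order=3)[32:96, 32:96] for dy, dx in true]
        )
        stack = SpatialAngularStack(views, grid5)
        disp = estimate_disparities(stack)
        rmse = np.sqrt(((disp.shifts - true) ** 2).mean())
        assert rmse <= 0.25

    def test_flat_tile_zero_confidence(self, grid5):
        views = np.zeros((25, 32, 32), np.float32)
        stack = SpatialAngularStack(views, grid5)
        disp = estimate_disparities(stack)
        off_center = [a for a in range(25) if a != stack.grid.center_index()]
        assert (disp.confidence[off_center] == 0).all()

    def test_single_view_rejected(self, rng):
        stack = SpatialAngularStack(
            rng.random((1, 16, 16)).astype(np.float32), AngularGrid(0)
        )
        with pytest.raises(ValueError, match="two views"):
            estimate_disparities(stack)


class TestExcludeDefocus:
    def test_pure_defocus_removed(self, grid5):
        coords = AngularGrid(2).coordinates().astype(float)
        disp = DisparityField(2.0 * coords, np.ones(25), coords)
        residual, beta = exclude_defocus(disp)
        assert beta == pytest.approx(2.0)
        np.testing.assert_allclose(residual.shifts, 0.0, atol=1e-12)

    def test_zero_disparities_beta_zero(self, grid5):
        coords = AngularGrid(2).coordinates().astype(float)
        disp = DisparityField(np.zeros((25, 2)), np.ones(25), coords)
        _, beta = exclude_defocus(disp)
        assert beta == 0.0

    def test_coma_residual_preserved(self, grid5):
        """defocus + coma-like pattern: the linear part is removed exactly."""
        coords = AngularGrid(2).coordinates().astype(float)
        coma = ZernikeCoeffs.zeros()
        c = np.array(coma.coefficients)
        c[list(DEFAULT_MODES).index(7)] = 0.4  # vertical coma
        coma = ZernikeCoeffs(c)
        coma_shifts = synthesize_disparities(coma, coords, 2)
        # project out any linear-in-u component the coma gradient contains
        beta_c = float((coma_shifts * coords).sum() / (coords * coords).sum())
        coma_resid = coma_shifts - beta_c * coords
        disp = DisparityField(1.5 * coords + coma_resid, np.ones(25), coords)
        residual, beta = exclude_defocus(disp)
        assert beta == pytest.approx(1.5, abs=1e-9)
        np.testing.assert_allclose(residual.shifts, coma_resid, atol=1e-6)

    def test_rank_deficient_angles_rejected(self):
        coords = np.array([[0, 0], [1, 0], [2, 0]], float)  # one axis only
        disp = DisparityField(np.zeros((3, 2)), np.ones(3), coords)
        with pytest.raises(ValueError, match="span"):
            exclude_defocus(disp)


class TestCorrectViews:
    def test_zero_residual_identity(self, grid5, rng):
        stack = SpatialAngularStack(rng.random((25, 16, 16)).astype(np.float32), grid5)
        coords = grid5.coordinates().astype(float)
        disp = DisparityField(np.zeros((25, 2)), np.ones(25), coords)
        out = correct_views(stack, disp)
        np.testing.assert_array_equal(out.views, stack.views)

    def test_correction_reduces_registration_error(self, grid5, rng):
        base = _texture(rng)
        true = rng.uniform(-3, 3, (25, 2))
        true[grid5.center_index()] = 0
        stack = _shifted_stack(grid5, base, true)
        disp = estimate_disparities(stack)
        corrected = correct_views(stack, disp)
        disp2 = estimate_disparities(corrected)
        before = np.abs(disp.shifts).mean()
        after = np.abs(disp2.shifts).mean()
        assert before >= 4 * after

    def test_warp_roundtrip_near_identity(self, grid5, rng):
        base = _texture(rng)
        stack = SpatialAngularStack(np.repeat(base[None], 25, 0), grid5)
        coords = grid5.coordinates().astype(float)
        shifts = rng.uniform(-2, 2, (25, 2))
        shifts[grid5.center_index()] = 0
        d = DisparityField(shifts, np.ones(25), coords)
        dneg = DisparityField(-shifts, np.ones(25), coords)
        back = correct_views(correct_views(stack, d), dneg)
        inner = (slice(None), slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(back.views[inner], stack.views[inner], atol=5e-3)


class TestFitWavefront:
    def test_noiseless_recovery_exact(self, grid5, rng):
        """Defocus-free coefficients round-trip through synth + exclusion."""
        coords = grid5.coordinates().astype(float)
        true = ZernikeCoeffs.random(0.8, rng)
        c = np.array(true.coefficients)
        c[list(DEFAULT_MODES).index(4)] = 0.0  # defocus belongs to beta
        true = ZernikeCoeffs(c)
        shifts = synthesize_disparities(true, coords, 2)
        residual, _ = exclude_defocus(DisparityField(shifts, np.ones(25), coords))
        fitted = fit_wavefront(residual, half_extent=2)
        assert np.abs(fitted.coefficients - true.coefficients).max() <= 1e-6

    def test_zero_residual_zero_coefficients(self, grid5):
        coords = grid5.coordinates().astype(float)
        fitted = fit_wavefront(
            DisparityField(np.zeros((25, 2)), np.ones(25), coords), half_extent=2
        )
        np.testing.assert_allclose(fitted.coefficients, 0.0, atol=1e-12)

    def test_linearity(self, grid5, rng):
        coords = grid5.coordinates().astype(float)
        true = ZernikeCoeffs.random(0.5, rng)
        s1 = synthesize_disparities(true, coords, 2)
        r1, _ = exclude_defocus(DisparityField(s1, np.ones(25), coords))
        r2, _ = exclude_defocus(DisparityField(2 * s1, np.ones(25), coords))
        f1 = fit_wavefront(r1, 2)
        f2 = fit_wavefront(r2, 2)
        np.testing.assert_allclose(f2.coefficients, 2 * f1.coefficients, atol=1e-8)


class TestEndToEndAberrationRecovery:
    def test_mode_amplitudes_correlate_with_truth(self, rng):
        """Wave-optics render under a 1-wavelength r.m.s. aberration on the
        13x13 system (central 49 views): preDAO-estimated mode amplitudes
        track the ground truth."""
        from slfm.core import Volume
        from slfm.psf import make_pupil, waveoptics_psf
        from slfm.simulate import BubtubConfig, bubtub_volume, simulate_measurement

        full = AngularGrid(6)
        sel = np.zeros((13, 13), bool)
        sel[3:10, 3:10] = True
        grid = full.with_selection(sel)
        pupil = make_pupil(1.4, 525.0, 1.515, full, 65)
        true = ZernikeCoeffs.sample(1.0, np.random.default_rng(100))
        z = np.array([0.0])
        psfs_ab = waveoptics_psf(
            pupil, grid, z, aberration=true, fft_size=256,
            pixel_pitch=525 / (2 * 1.4),
        )
        cfg = BubtubConfig(shape=(1, 192, 192), n_bubbles=(4, 4), n_beads=(14, 14),
                           n_tubes=(4, 4), bead_radius=(1.5, 3.0), seed=8)
        vol = bubtub_volume(cfg, np.random.default_rng(8))
        stack = simulate_measurement(Volume(vol, z), psfs_ab, S=13)
        disp = estimate_disparities(stack, max_shift=60)
        residual, beta = exclude_defocus(disp)
        fitted = fit_wavefront(residual, half_extent=6)
        r = np.corrcoef(fitted.coefficients, true.coefficients)[0, 1]
        assert r >= 0.9
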