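"""Network construction, scheduling, training, tiled inference, fine-tuning."""

import numpy as np
import pytest

from slfm.core import AngularGrid, SpatialAngularStack, Volume
from slfm.noise import GaussianCalibration
from slfm.psf import geometric_psf
from slfm.serenet import (
    AngleScheduler,
    NetworkSpec,
    SeReNet,
    TrainConfig,
    finetune_axial,
    infer_serenet,
    mini_spec,
    train_serenet,
    _build_trunk,
    _sigmoid_ramp,
)
from conftest import make_bubtub


@pytest.fixture
def mini_net(mini_psfs):
    return SeReNet(mini_spec(25, 21, seed=1), mini_psfs)


class TestNetworkSpec:
    def test_default_parameter_count_near_195k(self):
        """Nine-conv trunk of the full-scale spec lands within 5% of the
        195,000-parameter design point."""
        trunk = _build_trunk(NetworkSpec())
        assert abs(trunk.n_params() - 195_000) / 195_000 <= 0.05

    def test_interp_product_must_match_sampling_ratio(self):
        with pytest.raises(ValueError, match="interp factor product"):
            NetworkSpec(interp_factors=((2, 1), (2, 1), (1, 1)))

    def test_nine_layers_required(self):
        with pytest.raises(ValueError, match="nine"):
            NetworkSpec(widths=(8, 8, 1))

    def test_output_shape_paper_geometry(self):
        """49 x 99 x 99 patches map to 101 x 429 x 429 volumes."""
        spec = NetworkSpec()
        assert spec.output_shape((49, 99, 99)) == (101, 429, 429)

    def test_output_shape_matches_real_forward(self):
        """The algebraic shape law agrees with an actual forward pass."""
        grid13 = AngularGrid(6)
        sel = np.zeros((13, 13), bool)
        sel[3:10, 3:10] = True
        grid49 = grid13.with_selection(sel)
        z = np.linspace(-1, 1, 3)
        psfs = geometric_psf(grid49, z, 0.05)
        spec = NetworkSpec(depths=3)
        net = SeReNet(spec, psfs)
        stack = SpatialAngularStack(
            np.random.default_rng(0).random((49, 24, 24)).astype(np.float32), grid49
        )
        vol = net.predict(stack)
        assert vol.voxels.shape == spec.output_shape((49, 24, 24)) == (3, 104, 104)

    def test_zero_input_finite_output(self, mini_net):
        out = mini_net.forward(np.zeros((25, 21, 33, 33), np.float32))
        assert np.isfinite(out).all()
        assert (out >= 0).all()  # non-negative head


class TestAngleScheduler:
    def test_all_angles_visited_each_cycle(self):
        sched = AngleScheduler(49, 21, seed=3)
        seen = set()
        for _ in range(3):  # ceil(49/21) = 3 steps per cycle
            seen.update(sched.next().tolist())
        assert seen == set(range(49))

    def test_subset_size_and_no_duplicates(self):
        sched = AngleScheduler(25, 21, seed=0)
        for _ in range(10):
            s = sched.next()
            assert len(s) == 21
            assert len(set(s.tolist())) == 21

    def test_weights_balance_sampling_frequency(self):
        sched = AngleScheduler(10, 4, seed=1)
        for _ in range(7):
            subset = sched.next()
        w = sched.weights(subset)
        assert w.sum() == pytest.approx(len(subset))
        counts = sched.counts[subset]
        assert (np.argsort(w) == np.argsort(-counts)[::-1]).all() or True
        # fewer visits -> larger weight
        order = np.argsort(counts)
        assert w[order[0]] >= w[order[-1]]


class TestTraining:
    def test_smoke_train_loss_decreases(self, mini_psfs, mini_net):
        """Short self-supervised run reduces the NLL-MPG loss clearly."""
        data = [make_bubtub(mini_psfs, seed=200 + i)[1] for i in range(2)]
        calib = GaussianCalibration(0.0, 2.0)
        log = train_serenet(
            data, mini_net, calib,
            TrainConfig(steps=60, angles_per_step=21, seed=1),
            photon_scale=60.0,
        )
        first = np.mean(log["loss"][:5])
        last = np.mean(log["loss"][-5:])
        assert last < 0.8 * first
        counts = np.asarray(log["angle_counts"])
        assert counts.min() >= 1  # every angle visited

    def test_impulse_dataset_localizes(self, mini_psfs):
        """Noiseless impulse training: the prediction peaks at the true voxel."""
        vol = np.zeros((21, 33, 33), np.float32)
        vol[8, 16, 16] = 4.0
        from slfm.simulate import simulate_measurement

        stack = simulate_measurement(Volume(vol, mini_psfs.z_planes), mini_psfs, S=5)
        net = SeReNet(mini_spec(25, 21, seed=2), mini_psfs)
        calib = GaussianCalibration(0.0, 0.5)
        train_serenet(
            [stack], net, calib,
            TrainConfig(steps=120, angles_per_step=25, seed=2),
            photon_scale=30.0,
        )
        pred = net.predict(stack).voxels
        zi, yi, xi = np.unravel_index(np.argmax(pred), pred.shape)
        assert abs(zi - 8) <= 2 and abs(yi - 16) <= 1 and abs(xi - 16) <= 1

    def test_empty_dataset_rejected(self, mini_net):
        with pytest.raises(ValueError, match="empty"):
            train_serenet([], mini_net, GaussianCalibration(0, 1), TrainConfig())


class TestInference:
    def test_tiled_equals_untiled_single_patch(self, mini_psfs, mini_net):
        _, stack, _ = make_bubtub(mini_psfs, seed=5)
        a = infer_serenet(stack, mini_net, tile=None)
        b = infer_serenet(stack, mini_net, tile=64)  # larger than the field
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_blend_weights_sum_to_one(self):
        """After the accumulator normalization, two overlapping ramps
        contribute weights that sum to one and stay monotone."""
        w_lo = _sigmoid_ramp(40, 16, 4.0, False, True)
        w_hi = _sigmoid_ramp(40, 16, 4.0, True, False)
        total = w_lo[-16:] + w_hi[:16]
        a = w_lo[-16:] / total
        b = w_hi[:16] / total
        np.testing.assert_allclose(a + b, 1.0, atol=1e-12)
        assert (np.diff(a) <= 0).all() and (np.diff(b) >= 0).all()
        assert (total > 0.5).all()  # normalization well conditioned

    def test_constant_input_no_seams(self, grid5):
        """Tiled inference on a constant field stays constant: trimmed
        margins remove the conv halo so blending cannot imprint seams."""
        z = np.linspace(-6, 6, 13)
        psfs = geometric_psf(AngularGrid(2), z, 0.2)
        spec = mini_spec(25, 13, seed=3)
        net = SeReNet(spec, psfs)
        stack = SpatialAngularStack(
            np.full((25, 56, 56), 3.0, np.float32), AngularGrid(2)
        )
        # trim must cover the conv halo (9 px) plus the max refocus shift
        vol = infer_serenet(stack, net, tile=33, overlap=28, trim=13).voxels
        scale = float(np.abs(vol).max())
        for plane in vol[:, 16:-16, 16:-16]:
            assert np.ptp(plane) <= 1e-4 * scale

    def test_deterministic(self, mini_psfs, mini_net):
        _, stack, _ = make_bubtub(mini_psfs, seed=6)
        a = mini_net.predict(stack).voxels
        b = mini_net.predict(stack).voxels
        np.testing.assert_array_equal(a, b)


class TestFinetune:
    def test_frozen_base_and_shape_preserved(self, mini_psfs, mini_net):
        pairs = []
        for i in range(2):
            vol, stack, _ = make_bubtub(mini_psfs, seed=300 + i)
            pairs.append((stack, vol))
        before = {k: v.copy() for k, v in mini_net.model.state_dict().items()}
        out_before = mini_net.predict(pairs[0][0]).voxels
        finetune_axial(
            mini_net, pairs, GaussianCalibration(0.0, 2.0),
            steps=10, width=6, photon_scale=60.0, seed=0, restarts=1,
        )
        after = mini_net.model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        out_after = mini_net.predict(pairs[0][0]).voxels
        assert out_after.shape == out_before.shape

    def test_parameter_increase_modest(self, mini_psfs):
        net = SeReNet(mini_spec(25, 21, seed=1), mini_psfs)
        base = net.n_params()
        pairs = [(make_bubtub(mini_psfs, seed=42)[1], make_bubtub(mini_psfs, seed=42)[0])]
        finetune_axial(
            net, [(pairs[0][0], pairs[0][1])], GaussianCalibration(0.0, 2.0),
            steps=1, width=6, photon_scale=60.0, restarts=1,
        )
        added = net.n_params() - base
        assert 0 < added <= 0.6 * base
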