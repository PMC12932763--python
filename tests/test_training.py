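import numpy as np
import pytest

from icsfilter.geometry import ImageVolume
from icsfilter.icsnet import ICSNet
from icsfilter.projector import SystemMatrixView
from icsfilter.skewnorm import SkewNormParams, evaluate_kernel
from icsfilter.training import (RAdam, TrainConfig, TrainingSample,
                                _SampleContext, generate_training_set,
                                kernel_gradient, l1_normalize,
                                load_training_set, optimize_kernel,
                                smooth_l1, train)


class TestSmoothL1:
    @pytest.mark.parametrize("d,expected", [(0.5, 0.125), (1.0, 0.5),
                                            (-3.0, 2.5), (0.0, 0.0),
                                            (-0.2, 0.02)])
    def test_branch_values(self, d, expected):
        per, total = smooth_l1(np.array([d]), np.array([0.0]))
        assert per[0] == pytest.approx(expected)
        assert total == pytest.approx(expected)

    def test_continuity_at_the_knee(self):
        eps = 1e-9
        below, _ = smooth_l1(np.array([1.0 - eps]), np.array([0.0]))
        above, _ = smooth_l1(np.array([1.0 + eps]), np.array([0.0]))
        assert abs(below[0] - above[0]) < 1e-8

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            l1_normalize(np.zeros(5))


class TestGenerateTrainingSet:
    def test_deterministic_and_in_fov(self, tiny_geometry, lyso_table):
        vol = ImageVolume((9, 9, 9), 2.0)
        cfg = TrainConfig(n_samples=6, n_pairs=5000, folds=2, seed=42)
        a = generate_training_set(cfg, tiny_geometry, lyso_table, vol)
        b = generate_training_set(cfg, tiny_geometry, lyso_table, vol)
        assert len(a) == 6
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.position, sb.position)
            np.testing.assert_array_equal(sa.y_true, sb.y_true)
            assert np.all(np.abs(sa.position) <= vol.half_extents)
            assert sa.y_true.sum() <= sa.n_pairs

    def test_incremental_serialization_resumes(self, tiny_geometry,
                                               lyso_table, tmp_path):
        vol = ImageVolume((9, 9, 9), 2.0)
        cfg = TrainConfig(n_samples=4, n_pairs=5000, folds=2, seed=42)
        path = tmp_path / "train.h5"
        full = generate_training_set(cfg, tiny_geometry, lyso_table, vol,
                                     out_path=path)
        resumed = load_training_set(path)
        assert len(resumed) == 4
        for sa, sb in zip(full, resumed):
            np.testing.assert_allclose(sa.y_true, sb.y_true)

    def test_histogram_total_bounded_by_pairs(self):
        with pytest.raises(ValueError):
            TrainingSample(np.zeros(3), np.full(10, 5.0), 10, 0)


class TestKernelGradient:
    def test_zero_at_the_loss_minimum(self, toy_view, rng):
        y = rng.random(toy_view.geometry.n_lors) + 0.01
        g = kernel_gradient(y, y, toy_view, [0.0, 0.0, 0.0])
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_matches_finite_differences(self, tiny_view, rng):
        """The backprojected LOR-space gradient equals brute-force central
        differences of the scalar loss -- exact because forward and
        backprojection are an adjoint pair."""
        pos = np.array([1.0, -2.0, 0.5])
        y_true = rng.random(tiny_view.geometry.n_lors) + 0.1
        ctx = _SampleContext(TrainingSample(pos, y_true, 10 ** 9, 0),
                             tiny_view)
        k = rng.random((11, 11, 11))
        k /= k.sum()
        loss, gk = ctx.loss_and_kernel_grad(k)
        worst = 0.0
        for i in rng.choice(k.size, 20, replace=False):
            h = 1e-6
            up = k.ravel().copy()
            up[i] += h
            dn = k.ravel().copy()
            dn[i] -= h
            lu, _ = ctx.loss_and_kernel_grad(up.reshape(k.shape))
            ld, _ = ctx.loss_and_kernel_grad(dn.reshape(k.shape))
            fd = (lu - ld) / (2 * h)
            if abs(fd) > 1e-12:
                worst = max(worst, abs(fd - gk.ravel()[i]) / abs(fd))
        assert worst < 1e-3

    def test_scale_invariance_through_l1_normalization(self, tiny_view, rng):
        pos = np.array([1.0, -2.0, 0.5])
        y_true = rng.random(tiny_view.geometry.n_lors) + 0.1
        k = rng.random((11, 11, 11))
        k /= k.sum()
        g1 = kernel_gradient(tiny_view.forward_project(
            _place(k, pos, tiny_view)).counts, y_true, tiny_view, pos)
        g2 = kernel_gradient(tiny_view.forward_project(
            _place(k, pos, tiny_view)).counts, 10.0 * y_true, tiny_view, pos)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_patch_beyond_volume_is_zero_padded(self, tiny_view):
        # near-corner position: the 11^3 patch exceeds the 9^3 volume
        g = kernel_gradient(np.ones(tiny_view.geometry.n_lors),
                            np.ones(tiny_view.geometry.n_lors) * 2,
                            tiny_view, [-7.0, -7.0, -7.0])
        assert g.shape == (11, 11, 11)


def _place(kernel, pos, view):
    vol = view.template.copy_with(np.zeros(view.template.shape))
    ci = view.template.voxel_index(pos)
    for a in range(11):
        for b in range(11):
            for c in range(11):
                i, j, k2 = ci[0] + a - 5, ci[1] + b - 5, ci[2] + c - 5
                if all(0 <= v < s for v, s in zip((i, j, k2), vol.shape)):
                    vol.values[i, j, k2] += kernel[a, b, c]
    return vol


class TestRAdam:
    def test_minimizes_quadratic(self):
        x = np.array([5.0, -3.0])
        opt = RAdam([x], lr=0.1)
        for _ in range(500):
            opt.step([2 * x])
        assert np.abs(x).max() < 0.05

    def test_early_steps_fall_back_to_momentum(self):
        # with few steps the variance rectification is inactive (rho <= 4)
        x = np.array([1.0])
        opt = RAdam([x], lr=0.01)
        opt.step([np.array([1.0])])
        assert opt.t == 1
        assert x[0] < 1.0


@pytest.fixture(scope="module")
def train_setup(tiny_geometry, lyso_table):
    vol = ImageVolume((9, 9, 9), 2.0)
    view = SystemMatrixView(tiny_geometry, vol)
    cfg = TrainConfig(n_samples=10, n_pairs=20000, epochs=1,
                      learning_rate=1e-3, batch_size=4, folds=5, seed=3)
    samples = generate_training_set(cfg, tiny_geometry, lyso_table, vol)
    return view, cfg, samples


class TestTrain:
    @pytest.fixture
    def setup(self, train_setup):
        return train_setup

    def test_loss_decreases_in_most_seeds(self, setup):
        view, cfg, samples = setup
        cfg2 = TrainConfig(**{**cfg.__dict__, "epochs": 2})
        wins = 0
        for seed in range(5):
            net = ICSNet("direct", view.template.half_extents, seed=seed)
            trained, _ = train(net, samples, view, cfg2, cross_validate=False)
            h = trained.history
            if h[-1]["train_loss"] <= h[0]["train_loss"]:
                wins += 1
        assert wins >= 4

    def test_fold_assignment_is_a_partition(self, setup):
        view, cfg, samples = setup
        net = ICSNet("skewnorm", view.template.half_extents, seed=0)
        _, curves = train(net, samples, view, cfg, cross_validate=True)
        assert len(curves) == cfg.folds
        # recompute the partition the trainer uses
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(len(samples))
        folds = np.array_split(perm, cfg.folds)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(len(samples)))

    def test_insufficient_samples_rejected(self, setup):
        view, cfg, samples = setup
        with pytest.raises(ValueError):
            train(ICSNet("direct"), samples[:3], view, cfg)


class TestKernelRecovery:
    @pytest.mark.timeout(300)
    def test_head_training_recovers_a_known_blur(self):
        """On a synthetic acquisition whose mislocation is an exactly known
        (and realizable) blur, head training on one repeated sample recovers
        the generating kernel -- the exact loss optimum of noise-free data --
        and matches the loss of a direct kernel-space fit.

        The geometry must offer enough LORs to pin the 11^3 kernel; a ring
        with only tens of crystals leaves the problem under-determined.
        """
        from icsfilter.geometry import ScannerGeometry

        geometry = ScannerGeometry(ring_radius=15.0, n_crystals_transaxial=32,
                                   n_rings=4, crystal_pitch_transaxial=2.9,
                                   crystal_pitch_axial=3.0, crystal_depth=5.0,
                                   axial_fov=12.0)
        vol = ImageVolume((9, 9, 9), 2.0)
        view = SystemMatrixView(geometry, vol)
        pos = np.array([0.5, 0.5, 0.5])
        true_kernel = evaluate_kernel(SkewNormParams(
            (0.8, -0.5, 0.0), (1.2, 0.9, 1.1), (1.5, 0.0, -1.0), 0.0))
        y_true = view.forward_project(_place(true_kernel, pos, view)).counts
        sample = TrainingSample(pos, y_true, int(y_true.sum()) + 1, 0)
        ctx = _SampleContext(sample, view)
        cfg = TrainConfig(n_samples=8, n_pairs=1, epochs=1200,
                          learning_rate=5e-3, batch_size=8, folds=2, seed=1)
        trained, _ = train(ICSNet("skewnorm", vol.half_extents, seed=1),
                           [sample] * 8, view, cfg, cross_validate=False)
        k_net = trained.predict_kernel(ctx.input_position)
        assert 0.5 * np.abs(k_net - true_kernel).sum() < 0.1
        loss_net, _ = ctx.loss_and_kernel_grad(k_net)
        k_fit = optimize_kernel(y_true, view, pos, iters=2000, lr=0.02)
        loss_fit, _ = ctx.loss_and_kernel_grad(k_fit)
        assert loss_net <= loss_fit * 1.01 + 1e-12
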