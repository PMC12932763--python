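import numpy as np
import pytest

from icsfilter.geometry import ImageVolume, LORHistogram
from icsfilter.icsnet import ICSNet
from icsfilter.mc import LORBlur, estimate_pair_lor_blur
from icsfilter.phantoms import nrmse
from icsfilter.reconstruction import (KernelStore, LORSpaceCorrection,
                                      OSEMConfig, PairLORSpaceCorrection,
                                      apply_filter, delta_kernel_store,
                                      evaluate_experiment,
                                      lor_space_corrected_reconstruct,
                                      osem_reconstruct,
                                      poisson_log_likelihood,
                                      precompute_kernels, subset_indices)


@pytest.fixture(scope="module")
def noiseless(toy_view):
    rng = np.random.default_rng(5)
    x_star = rng.random(toy_view.template.shape)
    y = LORHistogram(toy_view.geometry.geometry_hash(),
                     toy_view.matrix @ x_star.ravel())
    return x_star, y


class TestSubsets:
    def test_partition(self, toy_geometry):
        subs = subset_indices(toy_geometry, 4)
        joined = np.sort(np.concatenate(subs))
        np.testing.assert_array_equal(joined, np.arange(toy_geometry.n_lors))

    def test_single_subset_is_everything(self, toy_geometry):
        subs = subset_indices(toy_geometry, 1)
        assert subs[0].size == toy_geometry.n_lors


class TestOSEM:
    def test_noiseless_fixed_point(self, toy_view, noiseless):
        """On noiseless data y = A x*, the EM multiplier at x* is exactly 1
        for every voxel the system senses."""
        x_star, y = noiseless
        A = toy_view.matrix
        sens = np.asarray(A.sum(axis=0)).ravel()
        xt = x_star.ravel()
        mult = (A.T @ (y.counts / np.maximum(A @ xt, 1e-12))) \
            / np.maximum(sens, 1e-12)
        covered = sens > 0
        np.testing.assert_allclose(mult[covered], 1.0, atol=1e-6)

    def test_mlem_likelihood_monotone(self, toy_view, noiseless):
        _, y = noiseless
        cfg = OSEMConfig(n_subsets=1, n_iterations=1, filter_mode="none")
        x = toy_view.template.copy_with(np.ones(toy_view.template.shape))
        ll_prev = -np.inf
        for _ in range(20):
            xr = osem_from(toy_view, y, x)
            ll = poisson_log_likelihood(y, toy_view, xr)
            assert ll >= ll_prev - 1e-9 * abs(ll_prev)
            ll_prev = ll
            x = xr

    def test_iterates_nonnegative_finite(self, toy_view, noiseless):
        _, y = noiseless
        cfg = OSEMConfig(n_subsets=4, n_iterations=4, filter_mode="none")
        x = osem_reconstruct(y, toy_view, cfg)
        assert np.all(np.isfinite(x.values))
        assert np.all(x.values >= 0)

    def test_all_zero_histogram_returns_zero_image(self, toy_view):
        y = LORHistogram.zeros(toy_view.geometry)
        x = osem_reconstruct(y, toy_view, OSEMConfig(filter_mode="none"))
        assert x.values.sum() == 0

    def test_kernel_store_mode_requires_store(self, toy_view, noiseless):
        _, y = noiseless
        with pytest.raises(ValueError):
            osem_reconstruct(y, toy_view,
                             OSEMConfig(filter_mode="kernel-store"))


def osem_from(view, y, x0):
    """Single MLEM update used by the likelihood-monotonicity check."""
    A = view.matrix
    sens = np.maximum(np.asarray(A.sum(axis=0)).ravel(), 1e-12)
    x = x0.values.ravel()
    x = x * (A.T @ (y.counts / np.maximum(A @ x, 1e-12))) / sens
    return view.template.copy_with(x.reshape(view.template.shape))


class TestApplyFilter:
    def test_delta_store_is_identity(self, tiny_volume, rng):
        store = delta_kernel_store(tiny_volume)
        x = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        np.testing.assert_array_equal(apply_filter(x, store).values, x.values)

    def test_activity_preserved(self, tiny_volume, rng):
        net = ICSNet("skewnorm", tiny_volume.half_extents, seed=0)
        store = precompute_kernels(net, tiny_volume, mode="octant")
        x = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        out = apply_filter(x, store)
        assert out.values.sum() == pytest.approx(x.values.sum(), rel=1e-6)

    def test_matches_dense_matrix_oracle(self, tiny_volume, rng):
        nvox = int(np.prod(tiny_volume.shape))
        bank = rng.random((nvox, 1331)).astype(np.float32)
        bank /= bank.sum(axis=1, keepdims=True)
        store = KernelStore(tiny_volume, bank, np.arange(nvox),
                            np.zeros(nvox, dtype=np.uint8), "dense")
        x = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        out = apply_filter(x, store).values
        # explicit scatter with per-voxel truncation renormalization
        ref = np.zeros(tiny_volume.shape)
        for v in range(nvox):
            i, j, k = np.unravel_index(v, tiny_volume.shape)
            kern = bank[v].astype(float).reshape(11, 11, 11)
            s = 0.0
            for a in range(11):
                for b in range(11):
                    for c in range(11):
                        t = (i + a - 5, j + b - 5, k + c - 5)
                        if all(0 <= tt < 9 for tt in t):
                            s += kern[a, b, c]
            for a in range(11):
                for b in range(11):
                    for c in range(11):
                        t = (i + a - 5, j + b - 5, k + c - 5)
                        if all(0 <= tt < 9 for tt in t):
                            ref[t] += x.values[i, j, k] * kern[a, b, c] / s
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_adjoint_identity(self, tiny_volume, rng):
        net = ICSNet("skewnorm", tiny_volume.half_extents, seed=1)
        store = precompute_kernels(net, tiny_volume, mode="octant")
        u = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        w = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        lhs = (apply_filter(u, store).values * w.values).sum()
        rhs = (u.values * apply_filter(w, store, adjoint=True).values).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_template_mismatch_rejected(self, tiny_volume):
        store = delta_kernel_store(tiny_volume)
        with pytest.raises(ValueError):
            apply_filter(ImageVolume((4, 4, 4), 1.0), store)


class TestKernelStore:
    def test_octant_matches_dense_for_symmetric_network(self, tiny_volume):
        net = ICSNet("direct", tiny_volume.half_extents, seed=0)
        dense = precompute_kernels(net, tiny_volume, mode="dense")
        octant = precompute_kernels(net, tiny_volume, mode="octant")
        nvox = int(np.prod(tiny_volume.shape))
        for v in range(0, nvox, 53):
            np.testing.assert_allclose(dense.kernel_at(v),
                                       octant.kernel_at(v), atol=1e-12)

    def test_every_kernel_sums_to_one(self, tiny_volume):
        net = ICSNet("skewnorm", tiny_volume.half_extents, seed=2)
        store = precompute_kernels(net, tiny_volume, mode="octant")
        for v in (0, 100, 400, 728):
            assert store.kernel_at(v).sum() == pytest.approx(1.0, abs=1e-5)

    def test_dense_storage_arithmetic(self, tiny_volume):
        net = ICSNet("direct", tiny_volume.half_extents)
        store = precompute_kernels(net, tiny_volume, mode="dense")
        assert store.nbytes() == 9 * 9 * 9 * 1331 * 4

    def test_storage_cap_suggests_octant(self, tiny_volume):
        net = ICSNet("direct", tiny_volume.half_extents)
        with pytest.raises(ValueError, match="octant"):
            precompute_kernels(net, tiny_volume, mode="dense", max_bytes=1000)


class TestLORSpaceReference:
    def test_delta_blur_matches_plain_osem(self, toy_view, noiseless):
        _, y = noiseless
        nr = toy_view.geometry.n_rings
        probs = np.zeros((1, 2 * nr - 1))
        probs[0, nr - 1] = 1.0
        blur = LORBlur(np.array([0]), np.arange(-(nr - 1), nr), probs)
        cfg = OSEMConfig(n_subsets=4, n_iterations=3,
                         filter_mode="lor-space-reference")
        a = lor_space_corrected_reconstruct(y, toy_view, cfg, blur)
        b = osem_reconstruct(y, toy_view, OSEMConfig(
            n_subsets=4, n_iterations=3, filter_mode="none"))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-12)

    def test_pair_blur_preserves_counts_and_adjoint(self, toy_geometry,
                                                    toy_view, lyso_table,
                                                    rng):
        blur = estimate_pair_lor_blur(toy_geometry, lyso_table, 50000, seed=4)
        corr = PairLORSpaceCorrection(toy_view, blur)
        u = rng.random(toy_geometry.n_lors)
        w = rng.random(toy_geometry.n_lors)
        Bu = corr.apply(u)
        assert Bu.sum() == pytest.approx(u.sum(), rel=1e-12)
        assert (Bu @ w) == pytest.approx(u @ corr.apply(w, adjoint=True),
                                         rel=1e-6)

    def test_marginal_blur_adjoint(self, toy_geometry, toy_view, lyso_table,
                                   rng):
        from icsfilter.mc import estimate_lor_blur
        blur = estimate_lor_blur(toy_geometry, lyso_table, 50000, seed=4)
        corr = LORSpaceCorrection(toy_view, blur)
        u = rng.random(toy_geometry.n_lors)
        w = rng.random(toy_geometry.n_lors)
        assert (corr.apply(u) @ w) == pytest.approx(
            u @ corr.apply(w, adjoint=True), rel=1e-6)


class TestEvaluate:
    def test_reference_against_itself_is_zero(self, tiny_volume, rng):
        ref = tiny_volume.copy_with(rng.random(tiny_volume.shape) + 0.1)
        out = evaluate_experiment({"self": ref}, ref)
        assert out["self"] == 0.0

    def test_labels_preserved_and_delegates_to_nrmse(self, tiny_volume, rng):
        ref = tiny_volume.copy_with(rng.random(tiny_volume.shape) + 0.1)
        a = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        b = tiny_volume.copy_with(rng.random(tiny_volume.shape))
        out = evaluate_experiment({"methodA": a, "methodB": b}, ref)
        assert list(out) == ["methodA", "methodB"]
        assert out["methodA"] == pytest.approx(100 * nrmse(a, ref))

    def test_missing_reference_rejected(self, tiny_volume):
        with pytest.raises(ValueError):
            evaluate_experiment({}, None)
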