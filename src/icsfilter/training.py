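"""Training of the filter-prediction networks on simulated LOR data.

A training sample is (position, ICS-affected LOR histogram of a point source
at that position).  The network's kernel prediction is placed in the image
volume at the sample's voxel, geometrically forward projected, L1-normalized,
and compared to the L1-normalized measured histogram with the smooth-L1
(Huber) loss.  The gradient with respect to the kernel is obtained by
backprojecting the LOR-space loss gradient -- exact here because forward and
backprojection are a matched adjoint pair -- and chained analytically into
the network head.  Optimization uses RAdam (rectified Adam).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import ImageVolume, LORHistogram, ScannerGeometry
from .icsnet import ICSNet
from .mc import AttenuationTable, simulate_point_source
from .projector import SystemMatrixView
from .skewnorm import KERNEL_HALF, KERNEL_SIZE

log = logging.getLogger(__name__)


# ==================================================================== config
@dataclass
class TrainConfig:
    """Desk-scale defaults; the reference protocol used 500 samples at 1e8
    pairs each -- both are plain config fields here."""

    n_samples: int = 50
    n_pairs: int = 10 ** 6
    epochs: int = 50
    learning_rate: float = 1e-5
    batch_size: int = 8
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2 (80/20 splits need >= 2)")
        if self.n_samples < self.folds:
            raise ValueError("need at least `folds` samples")


@dataclass
class TrainingSample:
    position: np.ndarray
    y_true: np.ndarray      # raw LOR counts
    n_pairs: int
    seed: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.y_true = np.asarray(self.y_true, dtype=float)
        if self.y_true.sum() > self.n_pairs:
            raise ValueError("histogram total exceeds simulated pair count")


# ============================================================ data generation
def generate_training_set(config: TrainConfig, geometry: ScannerGeometry,
                          table: AttenuationTable, template: ImageVolume,
                          out_path=None) -> list[TrainingSample]:
    """Point-source samples at positions uniform in the image-volume box.

    Deterministic under ``config.seed``; with ``out_path`` the samples are
    written incrementally to HDF5 so an interrupted run can resume.
    """
    rng = np.random.default_rng(config.seed)
    # sample inside the volume box clipped to the scanner bore, so every
    # position is a valid emission point
    he = np.minimum(template.half_extents,
                    [0.95 * geometry.ring_radius,
                     0.95 * geometry.ring_radius,
                     0.5 * geometry.axial_extent - 1e-6])
    samples: list[TrainingSample] = []
    start = 0
    f = None
    if out_path is not None:
        f = h5py.File(out_path, "a")
        if "positions" not in f:
            f.create_dataset("positions", (config.n_samples, 3), dtype="f8")
            f.create_dataset("counts", (config.n_samples, geometry.n_lors),
                             dtype="f4")
            f.create_dataset("seeds", (config.n_samples,), dtype="i8")
            f.attrs["n_done"] = 0
            f.attrs["geometry_id"] = geometry.geometry_hash()
            f.attrs["n_pairs"] = config.n_pairs
        start = int(f.attrs["n_done"])
        for i in range(start):
            samples.append(TrainingSample(f["positions"][i], f["counts"][i],
                                          config.n_pairs, int(f["seeds"][i])))
    for i in range(config.n_samples):
        # draw position + sub-seed for every index to keep the stream aligned
        pos = template.origin + (rng.random(3) * 2.0 - 1.0) * he
        sub = int(rng.integers(0, 2 ** 31 - 1))
        if i < start:
            continue
        hist = simulate_point_source(pos, config.n_pairs, geometry, table, sub)
        while hist.total == 0:
            sub = int(rng.integers(0, 2 ** 31 - 1))
            log.warning("sample %d had zero counts; regenerating with seed %d",
                        i, sub)
            hist = simulate_point_source(pos, config.n_pairs, geometry,
                                         table, sub)
        samples.append(TrainingSample(pos, hist.counts, config.n_pairs, sub))
        if f is not None:
            f["positions"][i] = pos
            f["counts"][i] = hist.counts
            f["seeds"][i] = sub
            f.attrs["n_done"] = i + 1
    if f is not None:
        f.close()
    return samples


def load_training_set(path) -> list[TrainingSample]:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_done"])
        n_pairs = int(f.attrs["n_pairs"])
        return [TrainingSample(f["positions"][i], f["counts"][i], n_pairs,
                               int(f["seeds"][i])) for i in range(n)]


# ===================================================================== loss
def smooth_l1(y_pred, y_true):
    """Per-LOR smooth-L1 losses and their total.

    Inputs are the L1-normalized LOR images; raw histograms are rejected via
    the zero-norm check only (callers normalize with ``l1_normalize``).
    """
    d = np.asarray(y_pred, float) - np.asarray(y_true, float)
    a = np.abs(d)
    per = np.where(a < 1.0, 0.5 * d * d, a - 0.5)
    return per, float(per.sum())


def smooth_l1_grad(y_pred, y_true):
    d = np.asarray(y_pred, float) - np.asarray(y_true, float)
    return np.where(np.abs(d) < 1.0, d, np.sign(d))


def l1_normalize(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = np.abs(y).sum()
    if n <= 0:
        raise ValueError("cannot L1-normalize an all-zero LOR image")
    return y / n


def normalized_loss_grad_wrt_raw(y_raw, y_true_normalized):
    """d(total smooth-L1 loss)/d(raw y_pred), including the L1-normalization
    Jacobian (exact for non-negative y_raw)."""
    n = y_raw.sum()
    if n <= 0:
        raise ValueError("zero-norm prediction")
    y_hat = y_raw / n
    g = smooth_l1_grad(y_hat, y_true_normalized)
    return (g - g @ y_hat) / n


# ==================================================== kernel-space gradient
def _patch_voxel_indices(template: ImageVolume, position):
    """Flat voxel indices of the 11^3 patch centered on the source voxel;
    -1 marks out-of-volume patch cells (their columns are dropped)."""
    ci, cj, ck = template.voxel_index(position)
    nx, ny, nz = template.shape
    offs = np.arange(-KERNEL_HALF, KERNEL_HALF + 1)
    ii, jj, kk = np.meshgrid(ci + offs, cj + offs, ck + offs, indexing="ij")
    inside = ((ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny)
              & (kk >= 0) & (kk < nz))
    flat = (ii * ny + jj) * nz + kk
    return np.where(inside, flat, -1).ravel(), inside.ravel()


def kernel_gradient(y_pred: LORHistogram | np.ndarray,
                    y_true: LORHistogram | np.ndarray,
                    view: SystemMatrixView, position) -> np.ndarray:
    """Gradient of the normalized smooth-L1 loss w.r.t. the 11^3 kernel,
    via backprojection of the LOR-space gradient (the adjoint route)."""
    y_p = y_pred.counts if isinstance(y_pred, LORHistogram) else np.asarray(y_pred, float)
    y_t = y_true.counts if isinstance(y_true, LORHistogram) else np.asarray(y_true, float)
    d_raw = normalized_loss_grad_wrt_raw(y_p, l1_normalize(y_t))
    grad_vol = view.back_project(d_raw)
    flat, inside = _patch_voxel_indices(view.template, position)
    if not inside.all():
        log.warning("kernel patch at %s exceeds the volume; zero-padding",
                    np.asarray(position))
    out = np.zeros(flat.size)
    out[inside] = grad_vol.values.ravel()[flat[inside]]
    return out.reshape((KERNEL_SIZE,) * 3)


# ================================================================== optimizer
class RAdam:
    """Rectified Adam (variance-rectified adaptive moments)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = self.b1 ** self.t
        b2t = self.b2 ** self.t
        rho = self.rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            m_hat = m / (1.0 - b1t)
            if rho > 4.0:
                v_hat = np.sqrt(v / (1.0 - b2t))
                r = np.sqrt(((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                            / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho))
                p -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat


# ================================================================== training
class _SampleContext:
    """Precomputed per-sample projection pieces (patch submatrix etc.).

    The smooth-L1 loss and its gradient are evaluated only on the active LOR
    set (rows touched by the kernel patch or carrying counts); every other
    LOR contributes exactly zero to both, so this is a pure speedup.
    """

    def __init__(self, sample: TrainingSample, view: SystemMatrixView):
        self.sample = sample
        flat, inside = _patch_voxel_indices(view.template, sample.position)
        self.inside = inside
        a_patch = view.patch_matrix(flat[inside])
        patch_rows = np.flatnonzero(np.diff(a_patch.indptr) > 0)
        active = np.union1d(patch_rows, np.flatnonzero(sample.y_true))
        self.active = active
        self.a_patch = a_patch[active]
        self.y_true_hat = l1_normalize(sample.y_true)[active]
        # the kernel is placed at the voxel center (nearest-voxel placement),
        # so the network input is snapped to that center: otherwise the net
        # learns sub-voxel shifts that are wrong at prediction time, where it
        # is only ever evaluated at voxel centers
        self.input_position = view.template.voxel_to_world(
            np.asarray(view.template.voxel_index(sample.position), float))

    def loss_and_kernel_grad(self, kernel: np.ndarray):
        k = kernel.ravel()[self.inside]
        y_raw = self.a_patch @ k
        n = y_raw.sum()
        if n <= 0:
            return None, None  # kernel invisible to the projector
        y_hat = y_raw / n
        _, total = smooth_l1(y_hat, self.y_true_hat)
        d_raw = normalized_loss_grad_wrt_raw(y_raw, self.y_true_hat)
        gk = np.zeros(kernel.size)
        gk[self.inside] = self.a_patch.T @ d_raw
        return total, gk.reshape(kernel.shape)


def _run_epoch(net: ICSNet, contexts, order, config, optimizer=None):
    """One pass over `order`; returns mean per-sample loss.  With an
    optimizer, performs batched RAdam updates (mean gradient per batch)."""
    losses = []
    bs = config.batch_size
    for b0 in range(0, len(order), bs):
        batch = order[b0:b0 + bs]
        grad_acc = None
        n_used = 0
        for idx in batch:
            ctx = contexts[idx]
            kernel, cache = net.predict_kernel(ctx.input_position,
                                               with_cache=True)
            loss, gk = ctx.loss_and_kernel_grad(kernel)
            if loss is None:
                continue
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at sample {idx}, position "
                    f"{ctx.sample.position}")
            losses.append(loss)
            if optimizer is None:
                continue
            grads = net.backward(cache, gk)
            if grad_acc is None:
                grad_acc = grads
            else:
                for a, g in zip(grad_acc, grads):
                    a += g
            n_used += 1
        if optimizer is not None and grad_acc is not None:
            optimizer.step([g / n_used for g in grad_acc])
    return float(np.mean(losses)) if losses else np.nan


def train(network: ICSNet, samples: list[TrainingSample],
          view: SystemMatrixView, config: TrainConfig,
          cross_validate: bool = True):
    """Cross-validated training plus a final model fit on all samples.

    Returns ``(final_network, fold_curves)`` where ``fold_curves[f]`` is a
    list of per-epoch dicts with train/test loss.  Each fold trains a fresh
    copy of ``network`` on 80% of the samples (5 folds by default) and logs
    the held-out loss; the returned network is trained on every sample with
    the same protocol.
    """
    if len(samples) < config.folds:
        raise ValueError("not enough samples for the requested fold count")
    contexts = [_SampleContext(s, view) for s in samples]
    rng = np.random.default_rng(config.seed)
    n = len(samples)
    perm = rng.permutation(n)
    fold_curves: list[list[dict]] = []
    if cross_validate:
        folds = np.array_split(perm, config.folds)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            net = network.copy()
            opt = RAdam(list(net.parameters()), lr=config.learning_rate)
            curve = []
            for ep in range(config.epochs):
                order = rng.permutation(train_idx)
                tr = _run_epoch(net, contexts, order, config, opt)
                te = _run_epoch(net, contexts, test_idx, config, None)
                curve.append({"epoch": ep, "train_loss": tr, "test_loss": te})
            fold_curves.append(curve)
            log.info("fold %d: final train %.3e test %.3e", f, tr, te)
    final = network.copy()
    opt = RAdam(list(final.parameters()), lr=config.learning_rate)
    for ep in range(config.epochs):
        order = rng.permutation(n)
        tr = _run_epoch(final, contexts, order, config, opt)
        final.history.append({"epoch": ep, "train_loss": tr})
    return final, fold_curves


# =============================================== kernel-space reference fit
def optimize_kernel(y_true, view: SystemMatrixView, position,
                    iters: int = 500, lr: float = 0.05,
                    init: np.ndarray | None = None) -> np.ndarray:
    """Directly fit a normalized non-negative kernel to one LOR image by
    gradient descent in kernel space (rectify-and-normalize parameterization).

    This is the network-free optimum used as the reference in the
    kernel-recovery checks.
    """
    ctx = _SampleContext(
        TrainingSample(np.asarray(position, float), np.asarray(y_true, float),
                       int(np.asarray(y_true).sum() + 1), 0), view)
    u = (np.full((KERNEL_SIZE,) * 3, 1e-3) if init is None else init.copy())
    m = np.zeros_like(u)
    v = np.zeros_like(u)
    t = 0
    for _ in range(iters):
        w = np.maximum(u, 0.0)
        s = w.sum()
        k = w / s
        loss, gk = ctx.loss_and_kernel_grad(k)
        if gk is None:
            break
        gu = ((gk - (gk.ravel() @ k.ravel())) / s) * (u > 0)
        # plain Adam in kernel space
        t += 1
        m += 0.1 * (gu - m)
        v += 0.001 * (gu * gu - v)
        u -= lr * (m / (1 - 0.9 ** t)) / (np.sqrt(v / (1 - 0.999 ** t)) + 1e-12)
    w = np.maximum(u, 0.0)
    return w / w.sum()
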