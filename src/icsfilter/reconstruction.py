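"""OS-EM reconstruction with image-space position-dependent ICS filtering.

The trained network supplies one 11x11x11 kernel per voxel center
(precomputed into a ``KernelStore``; optionally only one spatial octant is
stored and the rest obtained by mirroring).  At every OS-EM subset update the
current image estimate is filtered -- each voxel's activity scattered over its
own kernel's footprint -- before the geometric forward projection, which
builds the ICS model into the reconstruction.  Kernels truncated by the
volume boundary are renormalized per voxel so filtering preserves the total
activity exactly.

The reference method reconstructs with a LOR-space ICS correction instead: a
spatially invariant endpoint-offset blur (estimated by high-sample Monte
Carlo) composed with the geometric projector, using the matched adjoint for
backprojection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import ImageVolume, LORHistogram, ScannerGeometry
from .icsnet import ICSNet
from .mc import LORBlur
from .phantoms import nrmse
from .projector import SystemMatrixView
from .skewnorm import KERNEL_SIZE

log = logging.getLogger(__name__)


# ================================================================ KernelStore
@dataclass
class OSEMConfig:
    n_subsets: int = 8
    n_iterations: int = 8
    filter_mode: str = "none"      # none | kernel-store | lor-space-reference
    filter_adjoint: bool = False   # also filter the backprojection (matched EM)
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ValueError("subsets and iterations must be >= 1")
        if self.filter_mode not in ("none", "kernel-store",
                                    "lor-space-reference"):
            raise ValueError(f"unknown filter mode {self.filter_mode!r}")


class KernelStore:
    """Per-voxel filter-kernel bank over an image-volume template.

    ``mode='dense'`` stores every voxel's kernel; ``mode='octant'`` stores the
    non-negative-coordinate octant and reconstructs the rest by mirroring
    (the scanner's blurring pattern is symmetric about the principal planes).
    """

    def __init__(self, template: ImageVolume, bank: np.ndarray,
                 row_of_voxel: np.ndarray, flips: np.ndarray, mode: str):
        self.template = template.copy_with(np.zeros(template.shape))
        self.bank = np.ascontiguousarray(bank, dtype=np.float32)
        self.row_of_voxel = np.ascontiguousarray(row_of_voxel, dtype=np.int64)
        self.flips = np.ascontiguousarray(flips, dtype=np.uint8)  # bits xyz
        self.mode = mode
        sums = self.bank.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-5) or np.any(self.bank < 0):
            raise ValueError("stored kernels must be non-negative, unit sum")
        self._edge_sums: np.ndarray | None = None

    @property
    def n_stored(self) -> int:
        return self.bank.shape[0]

    def kernel_at(self, voxel_flat_index: int) -> np.ndarray:
        """Read back one voxel's kernel (mirrored out of the octant bank)."""
        row = self.bank[self.row_of_voxel[voxel_flat_index]].astype(np.float64)
        k = row.reshape((KERNEL_SIZE,) * 3)
        f = int(self.flips[voxel_flat_index])
        axes = tuple(a for a in range(3) if f & (1 << a))
        return np.flip(k, axis=axes) if axes else k

    def nbytes(self) -> int:
        return self.bank.nbytes

    def edge_sums(self) -> np.ndarray:
        """Per-voxel in-volume kernel mass (for truncation renormalization)."""
        if self._edge_sums is None:
            self._edge_sums = _edge_sums_core(
                self.bank, self.row_of_voxel, self.flips,
                np.array(self.template.shape, dtype=np.int64))
        return self._edge_sums


def _octant_maps(shape):
    """Map every voxel to its octant representative and the mirror flips.

    The representative octant is the half with voxel centers at non-negative
    coordinates along each axis (index >= n//2 for even n, >= n//2 also for
    odd n whose center voxel is its own mate).
    """
    nx, ny, nz = shape
    idx = np.indices(shape)
    reps = []
    flips = np.zeros(shape, dtype=np.uint8)
    rep_idx = []
    for a, n in enumerate(shape):
        i = idx[a]
        mirrored = n - 1 - i
        neg = i < n // 2
        flips |= (neg.astype(np.uint8) << a)
        rep_idx.append(np.where(neg, mirrored, i))
    # octant sub-grid: indices >= n//2
    sub = [np.arange(n // 2, n) for n in shape]
    sub_shape = tuple(len(s) for s in sub)
    octant_flat = ((rep_idx[0] - nx // 2) * sub_shape[1]
                   + (rep_idx[1] - ny // 2)) * sub_shape[2] \
        + (rep_idx[2] - nz // 2)
    return octant_flat.ravel(), flips.ravel(), sub, sub_shape


def precompute_kernels(network: ICSNet, volume_template: ImageVolume,
                       mode: str = "octant", average_mates: bool = False,
                       max_bytes: int | None = None) -> KernelStore:
    """Evaluate the network at every (stored) voxel center.

    ``average_mates`` additionally averages each stored kernel with the
    mirrored predictions at the 7 symmetry-related positions, giving a more
    robust estimate when the network is not exactly symmetric.
    """
    if mode not in ("dense", "octant"):
        raise ValueError("mode must be 'dense' or 'octant'")
    nvox = int(np.prod(volume_template.shape))
    n_stored = nvox if mode == "dense" else None
    if mode == "octant":
        octant_flat, flips, sub, sub_shape = _octant_maps(volume_template.shape)
        n_stored = int(np.prod(sub_shape))
    est = n_stored * KERNEL_SIZE ** 3 * 4
    if max_bytes is not None and est > max_bytes:
        raise ValueError(
            f"kernel store would need {est/1e9:.2f} GB > cap; "
            "use mode='octant' or a coarser volume")
    if mode == "dense":
        bank = np.empty((nvox, KERNEL_SIZE ** 3), dtype=np.float32)
        centers = volume_template.voxel_centers()
        for v in range(nvox):
            bank[v] = network.predict_kernel(centers[v]).ravel()
        row_of_voxel = np.arange(nvox)
        flips = np.zeros(nvox, dtype=np.uint8)
    else:
        bank = np.empty((n_stored, KERNEL_SIZE ** 3), dtype=np.float32)
        ii, jj, kk = np.meshgrid(*sub, indexing="ij")
        coords = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        centers = volume_template.voxel_to_world(coords.astype(float))
        for r in range(n_stored):
            if average_mates:
                acc = np.zeros((KERNEL_SIZE,) * 3)
                for bits in range(8):
                    sgn = np.array([-1.0 if bits & (1 << a) else 1.0
                                    for a in range(3)])
                    k = network.predict_kernel(centers[r] * sgn)
                    axes = tuple(a for a in range(3) if bits & (1 << a))
                    acc += np.flip(k, axis=axes) if axes else k
                bank[r] = (acc / 8.0).ravel()
            else:
                bank[r] = network.predict_kernel(centers[r]).ravel()
        row_of_voxel = octant_flat
    store = KernelStore(volume_template, bank, row_of_voxel, flips, mode)
    store.edge_sums()  # warm the truncation-renormalization cache
    return store


def delta_kernel_store(volume_template: ImageVolume) -> KernelStore:
    """Store of centered delta kernels (filtering becomes the identity)."""
    bank = np.zeros((1, KERNEL_SIZE ** 3), dtype=np.float32)
    bank[0, KERNEL_SIZE ** 3 // 2] = 1.0
    nvox = int(np.prod(volume_template.shape))
    return KernelStore(volume_template, bank, np.zeros(nvox, dtype=np.int64),
                       np.zeros(nvox, dtype=np.uint8), "dense")


# ============================================================== apply_filter
@njit(cache=True)
def _edge_sums_core(bank, row_of_voxel, flips, shape):
    nx, ny, nz = shape[0], shape[1], shape[2]
    out = np.ones(nx * ny * nz)
    h = KERNEL_SIZE // 2
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if (ix >= h and ix < nx - h and iy >= h and iy < ny - h
                        and iz >= h and iz < nz - h):
                    continue  # interior voxels keep full kernel mass
                v = (ix * ny + iy) * nz + iz
                row = row_of_voxel[v]
                f = flips[v]
                s = 0.0
                for a in range(KERNEL_SIZE):
                    oa = a - h
                    if f & 1:
                        oa = -oa
                    ta = ix + a - h
                    if ta < 0 or ta >= nx:
                        continue
                    for b in range(KERNEL_SIZE):
                        tb = iy + b - h
                        if tb < 0 or tb >= ny:
                            continue
                        ob = b - h
                        if f & 2:
                            ob = -ob
                        for c in range(KERNEL_SIZE):
                            tc = iz + c - h
                            if tc < 0 or tc >= nz:
                                continue
                            oc = c - h
                            if f & 4:
                                oc = -oc
                            s += bank[row, ((oa + h) * KERNEL_SIZE
                                            + (ob + h)) * KERNEL_SIZE
                                      + (oc + h)]
                out[v] = s
    return out


@njit(cache=True)
def _apply_filter_adjoint_core(y, bank, row_of_voxel, flips, edge_sums, shape):
    """Adjoint of the scatter filter: gather each voxel's kernel over y."""
    nx, ny, nz = shape[0], shape[1], shape[2]
    out = np.zeros(nx * ny * nz)
    h = KERNEL_SIZE // 2
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                v = (ix * ny + iy) * nz + iz
                row = row_of_voxel[v]
                f = flips[v]
                acc = 0.0
                for a in range(KERNEL_SIZE):
                    ta = ix + a - h
                    if ta < 0 or ta >= nx:
                        continue
                    oa = a - h
                    if f & 1:
                        oa = -oa
                    for b in range(KERNEL_SIZE):
                        tb = iy + b - h
                        if tb < 0 or tb >= ny:
                            continue
                        ob = b - h
                        if f & 2:
                            ob = -ob
                        for c in range(KERNEL_SIZE):
                            tc = iz + c - h
                            if tc < 0 or tc >= nz:
                                continue
                            oc = c - h
                            if f & 4:
                                oc = -oc
                            acc += y[(ta * ny + tb) * nz + tc] * bank[
                                row, ((oa + h) * KERNEL_SIZE
                                      + (ob + h)) * KERNEL_SIZE + (oc + h)]
                out[v] = acc / edge_sums[v]
    return out


@njit(cache=True)
def _apply_filter_core(x, bank, row_of_voxel, flips, edge_sums, shape):
    nx, ny, nz = shape[0], shape[1], shape[2]
    out = np.zeros(nx * ny * nz)
    h = KERNEL_SIZE // 2
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                v = (ix * ny + iy) * nz + iz
                val = x[v]
                if val == 0.0:
                    continue
                row = row_of_voxel[v]
                f = flips[v]
                w = val / edge_sums[v]
                for a in range(KERNEL_SIZE):
                    ta = ix + a - h
                    if ta < 0 or ta >= nx:
                        continue
                    oa = a - h
                    if f & 1:
                        oa = -oa
                    for b in range(KERNEL_SIZE):
                        tb = iy + b - h
                        if tb < 0 or tb >= ny:
                            continue
                        ob = b - h
                        if f & 2:
                            ob = -ob
                        for c in range(KERNEL_SIZE):
                            tc = iz + c - h
                            if tc < 0 or tc >= nz:
                                continue
                            oc = c - h
                            if f & 4:
                                oc = -oc
                            out[(ta * ny + tb) * nz + tc] += w * bank[
                                row, ((oa + h) * KERNEL_SIZE
                                      + (ob + h)) * KERNEL_SIZE + (oc + h)]
    return out


def apply_filter(x: ImageVolume, store: KernelStore,
                 renormalize_truncated: bool = True,
                 adjoint: bool = False) -> ImageVolume:
    """Scatter every voxel's activity over its own kernel footprint.

    Kernels clipped by the volume boundary are renormalized per source voxel
    (default), so the total activity of the image is preserved exactly; with
    ``renormalize_truncated=False`` the clipped mass is simply lost.
    ``adjoint=True`` applies the exact transpose operator (a gather with each
    voxel's own kernel), used by the adjoint-matched OS-EM variant.
    """
    if not x.same_grid(store.template):
        raise ValueError("volume does not match the kernel store template")
    shape = np.array(x.shape, dtype=np.int64)
    edge = (store.edge_sums() if renormalize_truncated
            else np.ones(int(np.prod(x.shape))))
    core = _apply_filter_adjoint_core if adjoint else _apply_filter_core
    out = core(x.values.ravel(), store.bank,
               store.row_of_voxel, store.flips, edge, shape)
    return x.copy_with(out.reshape(x.shape))


# ==================================================================== OS-EM
def subset_indices(geometry: ScannerGeometry, n_subsets: int) -> list[np.ndarray]:
    """Partition LORs by transaxial angle index modulo n_subsets."""
    ia, ib = geometry.lor_crystal_pairs()
    ta = ia % geometry.n_crystals_transaxial
    tb = ib % geometry.n_crystals_transaxial
    angle = (ta + tb) % geometry.n_crystals_transaxial
    sets = [np.flatnonzero(angle % n_subsets == s) for s in range(n_subsets)]
    if any(s.size == 0 for s in sets):
        raise ValueError("empty LOR subset; reduce n_subsets")
    return sets


def osem_reconstruct(y: LORHistogram, view: SystemMatrixView,
                     config: OSEMConfig,
                     store: KernelStore | None = None) -> ImageVolume:
    """Ordered-subset EM with optional image-space ICS filtering.

    Per subset: the current image is filtered (if a kernel store is given),
    forward projected, and the usual multiplicative EM update is applied with
    the plain geometric sensitivity.  The filter sits only on the forward
    side, before each forward projection.
    """
    y.check_geometry(view.geometry)
    if config.filter_mode == "kernel-store" and store is None:
        raise ValueError("filter_mode 'kernel-store' needs a KernelStore")
    if y.counts.sum() == 0:
        log.warning("all-zero histogram: returning the zero image")
        return view.template.copy_with(np.zeros(view.template.shape))
    use_filter = store is not None and config.filter_mode == "kernel-store"
    matched = use_filter and config.filter_adjoint
    A = view.matrix
    subs = subset_indices(view.geometry, config.n_subsets)
    A_s = [A[s] for s in subs]
    sens = [np.asarray(a.sum(axis=0)).ravel() for a in A_s]
    if matched:  # sensitivity of the composed model (A F)^T 1 = F^T A^T 1
        sens = [apply_filter(view.template.copy_with(
            s0.reshape(view.template.shape)), store,
            adjoint=True).values.ravel() for s0 in sens]
    x = np.ones(A.shape[1])
    eps = config.eps

    def _vol(v):
        return view.template.copy_with(v.reshape(view.template.shape))

    for _ in range(config.n_iterations):
        for s, a in enumerate(A_s):
            if use_filter:
                xt = apply_filter(_vol(x), store).values.ravel()
            else:
                xt = x
            y_hat = a @ xt
            ratio = y.counts[subs[s]] / np.maximum(y_hat, eps)
            bp = a.T @ ratio
            if matched:
                bp = apply_filter(_vol(bp), store, adjoint=True).values.ravel()
            x = x * bp / np.maximum(sens[s], eps)
    return view.template.copy_with(x.reshape(view.template.shape))


# =================================================== LOR-space reference path
@njit(cache=True)
def _endpoint_wsum(ia, ib, move_b, n_t, n_rings, dts, dzs, ps):
    """Per-LOR retained offset mass when one endpoint is displaced (targets
    leaving the ring axially, or collapsing onto the other endpoint, drop)."""
    W = np.zeros(ia.size)
    for L in range(ia.size):
        mv = ib[L] if move_b else ia[L]
        other = ia[L] if move_b else ib[L]
        t0 = mv % n_t; r0 = mv // n_t
        s = 0.0
        for d in range(dts.size):
            r2 = r0 + dzs[d]
            if r2 < 0 or r2 >= n_rings:
                continue
            c2 = r2 * n_t + (t0 + dts[d]) % n_t
            if c2 == other:
                continue
            s += ps[d]
        W[L] = s
    return W


@njit(cache=True)
def _endpoint_blur(y, ia, ib, move_b, n_t, n_rings, dts, dzs, ps, W, adjoint):
    """Displace one endpoint of every LOR by the offset distribution.

    Forward mode scatters y[L] onto the displaced LORs; adjoint mode gathers
    from them.  Entry value for source L is p(offset) / W[L] so forward rows
    sum to exactly 1 (counts preserved).
    """
    n_c = n_t * n_rings
    out = np.zeros(y.size)
    for L in range(y.size):
        if W[L] <= 0.0:
            continue
        if (not adjoint) and y[L] == 0.0:
            continue
        mv = ib[L] if move_b else ia[L]
        other = ia[L] if move_b else ib[L]
        t0 = mv % n_t; r0 = mv // n_t
        inv = 1.0 / W[L]
        acc = 0.0
        for d in range(dts.size):
            r2 = r0 + dzs[d]
            if r2 < 0 or r2 >= n_rings:
                continue
            c2 = r2 * n_t + (t0 + dts[d]) % n_t
            if c2 == other:
                continue
            lo = c2 if c2 < other else other
            hi = other if c2 < other else c2
            L2 = lo * n_c - lo * (lo + 1) // 2 + (hi - lo - 1)
            if adjoint:
                acc += ps[d] * inv * y[L2]
            else:
                out[L2] += y[L] * ps[d] * inv
        if adjoint:
            out[L] = acc
    return out


@njit(cache=True, inline="always")
def _stage_targets(L, ia, ib, n_t, n_rings, axial, d, d1s, d2s):
    """Displaced crystal pair for offset entry d of one blur stage, in the
    LOR's canonical frame; returns (-1, -1) if the target leaves the ring."""
    a = ia[L]; b = ib[L]
    ta = a % n_t; ra = a // n_t
    tb = b % n_t; rb = b // n_t
    if axial:
        # ring-ordered frame: offset 1 belongs to the lower-ring endpoint
        if ra <= rb:
            r1 = ra + d1s[d]; r2 = rb + d2s[d]
            if r1 < 0 or r1 >= n_rings or r2 < 0 or r2 >= n_rings:
                return -1, -1
            return r1 * n_t + ta, r2 * n_t + tb
        r1 = rb + d1s[d]; r2 = ra + d2s[d]
        if r1 < 0 or r1 >= n_rings or r2 < 0 or r2 >= n_rings:
            return -1, -1
        return r1 * n_t + tb, r2 * n_t + ta
    # transaxial frame: endpoint A reaches B counterclockwise within n_t/2
    sraw = (tb - ta) % n_t
    if sraw <= n_t // 2:
        return (ra * n_t + (ta + d1s[d]) % n_t,
                rb * n_t + (tb + d2s[d]) % n_t)
    return (rb * n_t + (tb + d1s[d]) % n_t,
            ra * n_t + (ta + d2s[d]) % n_t)


@njit(cache=True)
def _joint_wsum(ia, ib, cls, n_t, n_rings, axial, d1s, d2s, ps, c0, cn):
    """Retained joint-offset mass per LOR for one (class-conditioned) stage."""
    W = np.zeros(ia.size)
    for L in range(ia.size):
        c = cls[L]
        s = 0.0
        for d in range(c0[c], c0[c] + cn[c]):
            c1, c2 = _stage_targets(L, ia, ib, n_t, n_rings, axial, d,
                                    d1s, d2s)
            if c1 < 0 or c1 == c2:
                continue
            s += ps[d]
        W[L] = s
    return W


@njit(cache=True)
def _joint_blur(y, ia, ib, cls, n_t, n_rings, axial, d1s, d2s, ps, c0, cn,
                W, adjoint):
    """One stage of the correlated endpoint blur (transaxial or axial)."""
    n_c = n_t * n_rings
    out = np.zeros(y.size)
    for L in range(y.size):
        if W[L] <= 0.0:
            continue
        if (not adjoint) and y[L] == 0.0:
            continue
        c = cls[L]
        inv = 1.0 / W[L]
        acc = 0.0
        for d in range(c0[c], c0[c] + cn[c]):
            c1, c2 = _stage_targets(L, ia, ib, n_t, n_rings, axial, d,
                                    d1s, d2s)
            if c1 < 0 or c1 == c2:
                continue
            lo = c1 if c1 < c2 else c2
            hi = c2 if c1 < c2 else c1
            L2 = lo * n_c - lo * (lo + 1) // 2 + (hi - lo - 1)
            if adjoint:
                acc += ps[d] * inv * y[L2]
            else:
                out[L2] += y[L] * ps[d] * inv
        if adjoint:
            out[L] = acc
    return out


class PairLORSpaceCorrection:
    """Correlated (pairwise) LOR-domain ICS blur around the projector.

    Two stages: a joint transaxial displacement of both endpoints, then a
    joint axial displacement, each conditioned on the LOR's transaxial
    separation class; each stage's rows are renormalized over the retained
    targets so counts are preserved exactly, and the exact adjoint (stages
    reversed, gathered) backs the EM update.
    """

    def __init__(self, view: SystemMatrixView, blur):
        g = view.geometry
        if blur.dz_offsets.size != 2 * g.n_rings - 1:
            raise ValueError("blur axial support does not match the geometry")
        if blur.joint_t.shape[0] != g.n_crystals_transaxial // 2 + 1:
            raise ValueError("blur class count does not match the geometry")
        self.view = view
        self.blur = blur
        ia, ib = g.lor_crystal_pairs()
        self.ia = ia.astype(np.int64)
        self.ib = ib.astype(np.int64)
        n_t = g.n_crystals_transaxial
        sep = np.abs((self.ia % n_t) - (self.ib % n_t))
        sep = np.minimum(sep, n_t - sep)
        cls_t = blur.class_map_t[sep].astype(np.int64)
        cls_z = blur.class_map_z[np.abs(self.ia // n_t
                                        - self.ib // n_t)].astype(np.int64)
        self.cls = {False: cls_t, True: cls_z}
        self.stages = []
        for axial, joint, offs in ((False, blur.joint_t, blur.dt_offsets),
                                   (True, blur.joint_z, blur.dz_offsets)):
            n_class = joint.shape[0]
            o1, o2 = np.meshgrid(offs, offs, indexing="ij")
            d1_all, d2_all, p_all = [], [], []
            c0 = np.zeros(n_class, dtype=np.int64)
            cn = np.zeros(n_class, dtype=np.int64)
            pos = 0
            for c in range(n_class):
                p = joint[c].copy()
                if p.sum() > 0:
                    p[p < 1e-3 * p.max()] = 0.0
                    p /= p.sum()
                nz = p.ravel() > 0
                d1_all.append(o1.ravel()[nz])
                d2_all.append(o2.ravel()[nz])
                p_all.append(p.ravel()[nz])
                c0[c] = pos
                cn[c] = int(nz.sum())
                pos += cn[c]
            d1 = np.concatenate(d1_all).astype(np.int64)
            d2 = np.concatenate(d2_all).astype(np.int64)
            ps = np.ascontiguousarray(np.concatenate(p_all))
            W = _joint_wsum(self.ia, self.ib, self.cls[axial], n_t,
                            g.n_rings, axial, d1, d2, ps, c0, cn)
            self.stages.append((axial, d1, d2, ps, c0, cn, W))

    def _one(self, y, stage, adjoint):
        axial, d1, d2, ps, c0, cn, W = stage
        g = self.view.geometry
        return _joint_blur(np.ascontiguousarray(y, dtype=np.float64),
                           self.ia, self.ib, self.cls[axial],
                           g.n_crystals_transaxial, g.n_rings,
                           axial, d1, d2, ps, c0, cn, W, adjoint)

    def apply(self, y: np.ndarray, adjoint: bool = False) -> np.ndarray:
        if adjoint:
            return self._one(self._one(y, self.stages[1], True),
                             self.stages[0], True)
        return self._one(self._one(y, self.stages[0], False),
                         self.stages[1], False)


class LORSpaceCorrection:
    """Spatially invariant LOR-domain ICS blur composed with the projector.

    The endpoint-offset distribution is applied to the two LOR endpoints in
    sequence (each displaced independently); the composite operator B and its
    exact adjoint are used around the geometric projector.
    """

    def __init__(self, view: SystemMatrixView, blur: LORBlur):
        if blur.dt_offsets.size > view.geometry.n_crystals_transaxial:
            raise ValueError("blur offset support exceeds the ring")
        if blur.dz_offsets.size != 2 * view.geometry.n_rings - 1:
            raise ValueError("blur axial support does not match the geometry")
        self.view = view
        self.blur = blur
        self.ia, self.ib = view.geometry.lor_crystal_pairs()
        self.ia = self.ia.astype(np.int64)
        self.ib = self.ib.astype(np.int64)
        # flatten nonzero offsets, trimming negligible mass for speed
        p = blur.probs.copy()
        p[p < 1e-5 * p.max()] = 0.0
        p /= p.sum()
        tt, zz = np.meshgrid(blur.dt_offsets, blur.dz_offsets, indexing="ij")
        nz = p.ravel() > 0
        self.dts = tt.ravel()[nz].astype(np.int64)
        self.dzs = zz.ravel()[nz].astype(np.int64)
        self.ps = np.ascontiguousarray(p.ravel()[nz])
        g = view.geometry
        args = (self.ia, self.ib, g.n_crystals_transaxial, g.n_rings,
                self.dts, self.dzs, self.ps)
        self._wa = _endpoint_wsum(args[0], args[1], False, *args[2:])
        self._wb = _endpoint_wsum(args[0], args[1], True, *args[2:])

    def _one(self, y, move_b, adjoint):
        g = self.view.geometry
        W = self._wb if move_b else self._wa
        return _endpoint_blur(np.ascontiguousarray(y, dtype=np.float64),
                              self.ia, self.ib, move_b,
                              g.n_crystals_transaxial, g.n_rings,
                              self.dts, self.dzs, self.ps, W, adjoint)

    def apply(self, y: np.ndarray, adjoint: bool = False) -> np.ndarray:
        if adjoint:  # (B_b B_a)^T = B_a^T B_b^T
            return self._one(self._one(y, True, True), False, True)
        return self._one(self._one(y, False, False), True, False)


def lor_space_corrected_reconstruct(y: LORHistogram, view: SystemMatrixView,
                                    config: OSEMConfig,
                                    blur) -> ImageVolume:
    """OS-EM with forward model B A (endpoint blur after geometric
    projection) and matched adjoint A^T B^T for the update.

    ``blur`` may be a marginal LORBlur (independent endpoints) or a
    PairLORBlur (correlated endpoints, the default reference estimate).
    """
    y.check_geometry(view.geometry)
    if hasattr(blur, "joint_t"):
        corr = PairLORSpaceCorrection(view, blur)
    else:
        corr = LORSpaceCorrection(view, blur)
    A = view.matrix
    subs = subset_indices(view.geometry, config.n_subsets)
    eps = config.eps
    # per-subset sensitivity A^T B^T 1_s
    sens = []
    for s in subs:
        ones = np.zeros(view.geometry.n_lors)
        ones[s] = 1.0
        sens.append(A.T @ corr.apply(ones, adjoint=True))
    x = np.ones(A.shape[1])
    for _ in range(config.n_iterations):
        for s_i, s in enumerate(subs):
            y_full = corr.apply(A @ x)
            ratio = np.zeros(view.geometry.n_lors)
            ratio[s] = y.counts[s] / np.maximum(y_full[s], eps)
            x = x * (A.T @ corr.apply(ratio, adjoint=True)) \
                / np.maximum(sens[s_i], eps)
    return view.template.copy_with(x.reshape(view.template.shape))


# ================================================================ evaluation
def evaluate_experiment(recons: dict[str, ImageVolume],
                        reference: ImageVolume) -> dict:
    """NRMSE (in %) of every labeled reconstruction against the reference."""
    if reference is None:
        raise ValueError("a reference reconstruction is required")
    report = {}
    for label, vol in recons.items():
        report[label] = 100.0 * nrmse(vol, reference)
    return report


def poisson_log_likelihood(y: LORHistogram, view: SystemMatrixView,
                           x: ImageVolume, eps: float = 1e-12) -> float:
    """Poisson data log-likelihood (up to the y! constant) of an image."""
    y_hat = np.maximum(view.forward_project(x).counts, eps)
    return float(np.sum(y.counts * np.log(y_hat) - y_hat))
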