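"""Matched geometric forward/backprojector between image and LOR space.

Rays run between the front-face centers of the two crystals of each LOR;
coefficients A[L, V] are exact ray-voxel intersection lengths (mm) from
incremental Siddon-style grid traversal, optionally averaged over a grid of
sub-rays between jittered points on each crystal face.  The operator pair is
realized by one sparse matrix and its transpose, so forward and backprojection
are an exactly matched adjoint pair -- the property the training-gradient
approximation relies on.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit

from .geometry import ImageVolume, LORHistogram, ScannerGeometry


@njit(cache=True)
def _siddon_fill(p0s, p1s, corner, voxel, shape, rows, cols, vals, weight):
    """Accumulate intersection lengths of every ray into COO triplets.

    Returns the number of triplets written.  ``rows`` gets the ray index,
    ``cols`` the flat voxel index.
    """
    nx, ny, nz = shape[0], shape[1], shape[2]
    n = 0
    for L in range(p0s.shape[0]):
        p0x, p0y, p0z = p0s[L, 0], p0s[L, 1], p0s[L, 2]
        dx = p1s[L, 0] - p0x
        dy = p1s[L, 1] - p0y
        dz = p1s[L, 2] - p0z
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        if length <= 0.0:
            continue
        dx /= length; dy /= length; dz /= length
        # entry/exit of the volume box
        t0, t1 = 0.0, length
        for a in range(3):
            d = (dx, dy, dz)[a]
            p = (p0x, p0y, p0z)[a]
            lo = corner[a]
            hi = corner[a] + shape[a] * voxel[a]
            if abs(d) < 1e-12:
                if p < lo or p > hi:
                    t0, t1 = 1.0, 0.0
                    break
            else:
                ta = (lo - p) / d
                tb = (hi - p) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
        if t1 <= t0:
            continue
        # walk the grid from t0 to t1
        t = t0 + 1e-9
        x = p0x + t * dx; y = p0y + t * dy; z = p0z + t * dz
        ix = int((x - corner[0]) / voxel[0])
        iy = int((y - corner[1]) / voxel[1])
        iz = int((z - corner[2]) / voxel[2])
        if ix < 0: ix = 0
        if iy < 0: iy = 0
        if iz < 0: iz = 0
        if ix >= nx: ix = nx - 1
        if iy >= ny: iy = ny - 1
        if iz >= nz: iz = nz - 1
        sx = 1 if dx > 0 else -1
        sy = 1 if dy > 0 else -1
        sz = 1 if dz > 0 else -1
        big = 1e30
        tdx = voxel[0] / abs(dx) if abs(dx) > 1e-12 else big
        tdy = voxel[1] / abs(dy) if abs(dy) > 1e-12 else big
        tdz = voxel[2] / abs(dz) if abs(dz) > 1e-12 else big
        if abs(dx) > 1e-12:
            nxt = corner[0] + (ix + (1 if sx > 0 else 0)) * voxel[0]
            tmx = (nxt - p0x) / dx
        else:
            tmx = big
        if abs(dy) > 1e-12:
            nxt = corner[1] + (iy + (1 if sy > 0 else 0)) * voxel[1]
            tmy = (nxt - p0y) / dy
        else:
            tmy = big
        if abs(dz) > 1e-12:
            nxt = corner[2] + (iz + (1 if sz > 0 else 0)) * voxel[2]
            tmz = (nxt - p0z) / dz
        else:
            tmz = big
        tcur = t0
        while tcur < t1 - 1e-12:
            if tmx <= tmy and tmx <= tmz:
                tnext = tmx
            elif tmy <= tmz:
                tnext = tmy
            else:
                tnext = tmz
            if tnext > t1:
                tnext = t1
            seg = tnext - tcur
            if seg > 0.0 and 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                rows[n] = L
                cols[n] = (ix * ny + iy) * nz + iz
                vals[n] = seg * weight
                n += 1
            if tmx <= tmy and tmx <= tmz:
                ix += sx; tmx += tdx
            elif tmy <= tmz:
                iy += sy; tmy += tdy
            else:
                iz += sz; tmz += tdz
            tcur = tnext
        if n > rows.size - (nx + ny + nz + 4):
            break  # safety; callers size the buffers generously
    return n


class SystemMatrixView:
    """Geometric system matrix for one (geometry, volume template) pair.

    The CSR matrix is built lazily on first use and cached; ``rays_per_lor``
    n > 1 averages an n x n grid of deterministically jittered sub-rays
    between the two crystal faces.
    """

    def __init__(self, geometry: ScannerGeometry, template: ImageVolume,
                 rays_per_lor: int = 1):
        self.geometry = geometry
        self.template = template.copy_with(np.zeros(template.shape))
        if rays_per_lor < 1:
            raise ValueError("rays_per_lor must be >= 1")
        self.rays_per_lor = int(rays_per_lor)
        self._matrix: sp.csr_matrix | None = None
        self._csc: sp.csc_matrix | None = None

    # ----------------------------------------------------------- construction
    def _sub_offsets(self) -> np.ndarray:
        n = self.rays_per_lor
        if n == 1:
            return np.array([[0.0, 0.0]])
        u = (np.arange(n) + 0.5) / n - 0.5
        uu, vv = np.meshgrid(u, u, indexing="ij")
        return np.column_stack([uu.ravel(), vv.ravel()])

    @property
    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            g = self.geometry
            ia, ib = g.lor_crystal_pairs()
            centers = g.crystal_front_centers()
            tmpl = self.template
            corner = tmpl.corner
            voxel = tmpl.voxel_size
            shape = np.array(tmpl.shape, dtype=np.int64)
            offs = self._sub_offsets()
            weight = 1.0 / len(offs)
            half_w = g.ring_radius * np.sin(np.pi / g.n_crystals_transaxial)
            nvox = int(np.prod(tmpl.shape))
            cap = g.n_lors * (int(shape.sum()) + 4) + 8
            rows = np.empty(cap, dtype=np.int64)
            cols = np.empty(cap, dtype=np.int64)
            vals = np.empty(cap)
            m = None
            for (du, dv) in offs:
                # tangential/axial jitter on each crystal face
                pa = self._face_point(centers[ia], ia, du * 2 * half_w,
                                      dv * g.crystal_pitch_axial)
                pb = self._face_point(centers[ib], ib, -du * 2 * half_w,
                                      -dv * g.crystal_pitch_axial)
                n = _siddon_fill(pa, pb, corner, voxel, shape,
                                 rows, cols, vals, weight)
                block = sp.coo_matrix(
                    (vals[:n].copy(),
                     (rows[:n].astype(np.int32), cols[:n].astype(np.int32))),
                    shape=(g.n_lors, nvox)).tocsr()
                m = block if m is None else m + block
            m.sum_duplicates()
            self._matrix = m
        return self._matrix

    def _face_point(self, base, cids, tang, axial) -> np.ndarray:
        g = self.geometry
        t = (cids % g.n_crystals_transaxial).astype(float)
        phi = 2.0 * np.pi * t / g.n_crystals_transaxial
        tangential = np.column_stack([-np.sin(phi), np.cos(phi),
                                      np.zeros_like(phi)])
        return base + tang * tangential + np.array([0.0, 0.0, 1.0]) * axial

    @property
    def matrix_csc(self) -> sp.csc_matrix:
        if self._csc is None:
            self._csc = self.matrix.tocsc()
        return self._csc

    # ------------------------------------------------------------- operators
    def forward_project(self, x: ImageVolume) -> LORHistogram:
        """y = A x: line integrals of the volume along every LOR."""
        if not x.same_grid(self.template):
            raise ValueError("volume does not match the projector template")
        y = self.matrix @ x.values.ravel()
        return LORHistogram(self.geometry.geometry_hash(), np.maximum(y, 0.0),
                            {"kind": "forward_projection"})

    def back_project(self, y: LORHistogram | np.ndarray) -> ImageVolume:
        """x = A^T y with the same coefficients as forward_project."""
        if isinstance(y, LORHistogram):
            y.check_geometry(self.geometry)
            vec = y.counts
        else:
            vec = np.asarray(y, dtype=float)
            if vec.size != self.geometry.n_lors:
                raise ValueError("LOR vector length does not match geometry")
        x = self.matrix.T @ vec
        return self.template.copy_with(x.reshape(self.template.shape))

    def patch_matrix(self, voxel_indices: np.ndarray) -> sp.csr_matrix:
        """Columns of A for a voxel subset (dense-indexed), as CSR."""
        return self.matrix_csc[:, voxel_indices].tocsr()
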