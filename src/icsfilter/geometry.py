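"""Scanner geometry, image volumes and LOR histograms.

Coordinate conventions used throughout the package:

* The world origin sits at the center of the tomograph; units are millimeters.
* The scanner is a single cylindrical ring stack: ``n_crystals_transaxial``
  crystals per ring, ``n_rings`` rings along z.  Crystal 0 of ring 0 is
  centered at azimuth 0 (the +x axis); crystal ids increase first with the
  transaxial index, then ring by ring (``cid = ring * n_t + t``).
* Image voxels: voxel ``(0, 0, 0)`` occupies the most-negative corner of the
  volume; voxel centers are at ``corner + (i + 0.5) * voxel_size``.
* LORs are unordered crystal pairs enumerated lexicographically.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

GEOMETRY_SCHEMA = "icsfilter/geometry-v1"


@dataclass(frozen=True)
class ScannerGeometry:
    """Cylindrical PET ring with radially-oriented rectangular crystals."""

    ring_radius: float = 40.0
    n_crystals_transaxial: int = 64
    n_rings: int = 8
    crystal_pitch_transaxial: float = 3.9
    crystal_pitch_axial: float = 4.0
    crystal_depth: float = 10.0
    axial_fov: float = 32.0
    material: str = "lyso_like"

    def __post_init__(self) -> None:
        if self.n_crystals_transaxial < 8:
            raise ValueError("n_crystals_transaxial must be >= 8")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        for name in ("ring_radius", "crystal_pitch_transaxial",
                     "crystal_pitch_axial", "crystal_depth", "axial_fov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # ------------------------------------------------------------------ ids
    @property
    def n_crystals(self) -> int:
        return self.n_crystals_transaxial * self.n_rings

    @property
    def n_lors(self) -> int:
        c = self.n_crystals
        return c * (c - 1) // 2

    @property
    def axial_extent(self) -> float:
        """Axial length of the crystal stack (mm)."""
        return self.n_rings * self.crystal_pitch_axial

    def crystal_index(self, transaxial: int, ring: int) -> int:
        return ring * self.n_crystals_transaxial + transaxial

    def transaxial_ring(self, crystal_id: int) -> tuple[int, int]:
        self._check_crystal(crystal_id)
        return (crystal_id % self.n_crystals_transaxial,
                crystal_id // self.n_crystals_transaxial)

    def _check_crystal(self, cid: int) -> None:
        if not (0 <= int(cid) < self.n_crystals):
            raise ValueError(f"crystal id {cid} out of range [0, {self.n_crystals})")

    # ------------------------------------------------------------------ LORs
    def lor_index(self, crystal_a: int, crystal_b: int) -> int:
        """Canonical index of the unordered pair (a, b).

        Lexicographic enumeration over pairs ``i < j``; symmetric in its
        arguments and bijective onto ``[0, C*(C-1)/2)``.
        """
        self._check_crystal(crystal_a)
        self._check_crystal(crystal_b)
        if crystal_a == crystal_b:
            raise ValueError("self-pair: a LOR requires two distinct crystals")
        i, j = (crystal_a, crystal_b) if crystal_a < crystal_b else (crystal_b, crystal_a)
        c = self.n_crystals
        return i * c - i * (i + 1) // 2 + (j - i - 1)

    def lor_crystal_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (a, b) with a < b for every LOR index, in index order."""
        c = self.n_crystals
        i, j = np.triu_indices(c, k=1)
        return i.astype(np.int32), j.astype(np.int32)

    # -------------------------------------------------------------- crystals
    def crystal_azimuth(self, crystal_id: int) -> float:
        t, _ = self.transaxial_ring(crystal_id)
        return 2.0 * np.pi * t / self.n_crystals_transaxial

    def crystal_axial_center(self, crystal_id: int) -> float:
        _, r = self.transaxial_ring(crystal_id)
        return (r + 0.5) * self.crystal_pitch_axial - 0.5 * self.axial_extent

    def crystal_world_box(self, crystal_id: int):
        """Oriented box of a crystal: (center, axes, half_extents), all mm.

        ``axes`` rows are the radial, tangential and axial unit vectors; the
        tangential half-width is the inscribed chord so neighbouring boxes on
        the ring never overlap.
        """
        self._check_crystal(crystal_id)
        phi = self.crystal_azimuth(crystal_id)
        zc = self.crystal_axial_center(crystal_id)
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        tangential = np.array([-np.sin(phi), np.cos(phi), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        center = radial * (self.ring_radius + 0.5 * self.crystal_depth)
        center = center + np.array([0.0, 0.0, zc])
        half_width = self.ring_radius * np.sin(np.pi / self.n_crystals_transaxial)
        half = np.array([0.5 * self.crystal_depth,
                         min(half_width, 0.5 * self.crystal_pitch_transaxial),
                         0.5 * self.crystal_pitch_axial])
        return center, np.vstack([radial, tangential, axial]), half

    def crystal_front_centers(self) -> np.ndarray:
        """(C, 3) front-face (inner-surface) centers — projector ray endpoints."""
        t = np.arange(self.n_crystals) % self.n_crystals_transaxial
        r = np.arange(self.n_crystals) // self.n_crystals_transaxial
        phi = 2.0 * np.pi * t / self.n_crystals_transaxial
        z = (r + 0.5) * self.crystal_pitch_axial - 0.5 * self.axial_extent
        return np.column_stack([self.ring_radius * np.cos(phi),
                                self.ring_radius * np.sin(phi), z])

    # ------------------------------------------------------------------ misc
    def geometry_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "schema": GEOMETRY_SCHEMA,
            "ring_radius": self.ring_radius,
            "n_crystals_transaxial": self.n_crystals_transaxial,
            "n_rings": self.n_rings,
            "crystal_pitch_transaxial": self.crystal_pitch_transaxial,
            "crystal_pitch_axial": self.crystal_pitch_axial,
            "crystal_depth": self.crystal_depth,
            "axial_fov": self.axial_fov,
            "material": self.material,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerGeometry":
        d = dict(d)
        schema = d.pop("schema", GEOMETRY_SCHEMA)
        if schema != GEOMETRY_SCHEMA:
            raise ValueError(f"unsupported geometry schema {schema!r}")
        return cls(**d)

    def save(self, path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "ScannerGeometry":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))


# --------------------------------------------------------------------------
@dataclass
class ImageVolume:
    """3D voxelized activity map with a world-coordinate mapping.

    ``origin`` is the world position of the geometric center of the volume
    (the tomograph center by default).
    """

    shape: tuple[int, int, int]
    voxel_size: np.ndarray
    origin: np.ndarray = None
    values: np.ndarray = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        self.origin = (np.zeros(3) if self.origin is None
                       else np.asarray(self.origin, dtype=float).copy())
        if self.values is None:
            self.values = np.zeros(self.shape, dtype=np.float64)
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.shape != self.shape:
                raise ValueError("values shape does not match volume shape")

    # ------------------------------------------------------------- mapping
    @property
    def corner(self) -> np.ndarray:
        """World coordinate of the most-negative voxel corner."""
        return self.origin - 0.5 * np.asarray(self.shape) * self.voxel_size

    @property
    def half_extents(self) -> np.ndarray:
        return 0.5 * np.asarray(self.shape) * self.voxel_size

    def world_to_voxel(self, p) -> np.ndarray:
        """Continuous voxel coordinate of world point(s); center of voxel i
        maps to coordinate i exactly."""
        p = np.asarray(p, dtype=float)
        return (p - self.corner) / self.voxel_size - 0.5

    def voxel_to_world(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.corner + (c + 0.5) * self.voxel_size

    def voxel_index(self, p) -> tuple[int, int, int]:
        """Integer voxel containing world point p (half-open convention:
        voxel i owns [corner + i*v, corner + (i+1)*v))."""
        idx = np.floor((np.asarray(p, float) - self.corner) / self.voxel_size)
        return tuple(int(v) for v in idx)

    def contains(self, p) -> bool:
        idx = self.voxel_index(p)
        return all(0 <= i < s for i, s in zip(idx, self.shape))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of every voxel center, C-order."""
        grids = [np.arange(s) for s in self.shape]
        ii, jj, kk = np.meshgrid(*grids, indexing="ij")
        c = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
        return self.voxel_to_world(c)

    def copy_with(self, values: np.ndarray | None = None) -> "ImageVolume":
        return ImageVolume(self.shape, self.voxel_size, self.origin,
                           self.values.copy() if values is None else values)

    def same_grid(self, other: "ImageVolume") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size)
                and np.allclose(self.origin, other.origin))

    # ------------------------------------------------------------------- IO
    def save_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.voxel_size)
        affine[:3, 3] = self.corner + 0.5 * self.voxel_size
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def load_nifti(cls, path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        voxel = np.diag(affine)[:3].copy()
        shape = img.shape[:3]
        corner = affine[:3, 3] - 0.5 * voxel
        origin = corner + 0.5 * np.asarray(shape) * voxel
        return cls(tuple(shape), voxel, origin,
                   np.asarray(img.dataobj, dtype=np.float64))

    def save_raw(self, path) -> None:
        """Raw little-endian float32 + JSON sidecar (<path>.json)."""
        path = pathlib.Path(path)
        self.values.astype("<f4").tofile(path)
        sidecar = {"shape": list(self.shape),
                   "voxel_size": self.voxel_size.tolist(),
                   "origin": self.origin.tolist(),
                   "dtype": "<f4", "order": "C"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load_raw(cls, path) -> "ImageVolume":
        path = pathlib.Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
        return cls(tuple(meta["shape"]), np.asarray(meta["voxel_size"]),
                   np.asarray(meta["origin"]), data.astype(np.float64))


# --------------------------------------------------------------------------
@dataclass
class LORHistogram:
    """Dense per-unordered-crystal-pair event counts."""

    geometry_id: str
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a flat per-LOR vector")
        if np.any(self.counts < 0):
            raise ValueError("LOR counts must be non-negative")

    @classmethod
    def zeros(cls, geometry: ScannerGeometry, **meta) -> "LORHistogram":
        return cls(geometry.geometry_hash(), np.zeros(geometry.n_lors), meta)

    def check_geometry(self, geometry: ScannerGeometry) -> None:
        if self.geometry_id != geometry.geometry_hash():
            raise ValueError("LOR histogram belongs to a different geometry")
        if self.counts.size != geometry.n_lors:
            raise ValueError("LOR histogram length does not match geometry")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts, compression="gzip")
            f.attrs["geometry_id"] = self.geometry_id
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "LORHistogram":
        with h5py.File(path, "r") as f:
            return cls(str(f.attrs["geometry_id"]), f["counts"][...],
                       json.loads(f.attrs.get("meta", "{}")))
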