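"""Test objects (Derenzo, point source, cylinder) and the image-quality metric.

The Derenzo phantom is the classic resolution target: angular sectors of
parallel rods with graded diameters, held between two solid plates.  Within a
sector the rods sit on a triangular lattice with center spacing equal to twice
the rod diameter.  Voxelization uses 3x3x3 subvoxel occupancy sampling to
reduce rasterization bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ImageVolume

SUBSAMPLE = 3  # subvoxel occupancy sampling per axis


@dataclass
class DerenzoSpec:
    """One rod diameter per sector; rods between two plates along z."""

    sector_rod_diameters: tuple = (1.2, 1.6, 2.0, 2.4, 3.2, 4.0)
    rod_length: float = 12.0
    plate_thickness: float = 3.0
    plate_radius: float = 20.0
    activity: float = 1.0
    inner_margin: float = 4.0   # rod-free radius around the center
    edge_margin: float = 1.0    # clearance from plate rim and sector borders

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.sector_rod_diameters):
            raise ValueError("rod diameters must be positive")
        for name in ("rod_length", "plate_thickness", "plate_radius", "activity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_sectors(self) -> int:
        return len(self.sector_rod_diameters)

    @property
    def axial_half_extent(self) -> float:
        return 0.5 * self.rod_length + self.plate_thickness


def derenzo_rod_centers(spec: DerenzoSpec) -> list[tuple[float, float, float]]:
    """(x, y, diameter) of every rod center, all sectors.

    Row ``j`` of a sector holds ``j + 1`` rods at radius
    ``inner_margin + j * sqrt(3) * d`` (triangular lattice, spacing ``2 d``),
    centered on the sector bisector; rods that would leave the sector wedge or
    the plate rim (with ``edge_margin`` clearance) are culled.
    """
    rods = []
    wedge = 2.0 * np.pi / spec.n_sectors
    for s, d in enumerate(spec.sector_rod_diameters):
        pitch = 2.0 * d
        bisector = (s + 0.5) * wedge
        j = 0
        while True:
            r_row = spec.inner_margin + j * pitch * np.sqrt(3.0) / 2.0
            if r_row + 0.5 * d > spec.plate_radius - spec.edge_margin:
                break
            # j+1 rods spread tangentially, spacing `pitch`, centered on bisector
            offsets = (np.arange(j + 1) - 0.5 * j) * pitch
            for u in offsets:
                x = r_row * np.cos(bisector) - u * np.sin(bisector)
                y = r_row * np.sin(bisector) + u * np.cos(bisector)
                rr = np.hypot(x, y)
                if rr + 0.5 * d > spec.plate_radius - spec.edge_margin:
                    continue
                ang = np.arctan2(y, x) % (2.0 * np.pi)
                rel = (ang - s * wedge) % (2.0 * np.pi)
                # keep the rod fully inside its sector wedge
                if rel > wedge:
                    continue
                clearance = rr * np.sin(min(rel, wedge - rel))
                if clearance < 0.5 * d + spec.edge_margin and rr > 0:
                    continue
                rods.append((x, y, d))
            j += 1
    return rods


def _occupancy(template: ImageVolume, inside_fn, bbox_lo, bbox_hi) -> np.ndarray:
    """Fractional voxel occupancy of an implicit solid over a bounding box."""
    lo = np.maximum(np.floor(template.world_to_voxel(bbox_lo) + 0.5), 0).astype(int)
    hi = np.minimum(np.ceil(template.world_to_voxel(bbox_hi) + 0.5),
                    np.asarray(template.shape)).astype(int)
    frac = np.zeros(template.shape)
    if np.any(hi <= lo):
        return frac
    n = SUBSAMPLE
    offs = (np.arange(n) + 0.5) / n - 0.5  # subvoxel offsets in voxel units
    gi = [np.arange(lo[a], hi[a]) for a in range(3)]
    ii, jj, kk = np.meshgrid(*gi, indexing="ij")
    centers = template.voxel_to_world(
        np.stack([ii, jj, kk], axis=-1).astype(float))
    acc = np.zeros(ii.shape)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                p = centers + np.array([ox, oy, oz]) * template.voxel_size
                acc += inside_fn(p)
    frac[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = acc / n**3
    return frac


def make_derenzo(spec: DerenzoSpec, volume_template: ImageVolume) -> ImageVolume:
    """Rasterize a Derenzo phantom into a copy of the template volume."""
    he = volume_template.half_extents
    if (spec.plate_radius > min(he[0], he[1]) or
            spec.axial_half_extent > he[2]):
        raise ValueError("Derenzo spec does not fit inside the volume template")

    vals = np.zeros(volume_template.shape)
    z_hi = spec.axial_half_extent
    z_lo = 0.5 * spec.rod_length

    def plate(p):
        r2 = p[..., 0] ** 2 + p[..., 1] ** 2
        az = np.abs(p[..., 2])
        return (r2 <= spec.plate_radius ** 2) & (az >= z_lo) & (az <= z_hi)

    vals += _occupancy(volume_template, plate,
                       [-spec.plate_radius, -spec.plate_radius, -z_hi],
                       [spec.plate_radius, spec.plate_radius, z_hi])

    for (cx, cy, d) in derenzo_rod_centers(spec):
        rad = 0.5 * d

        def rod(p, cx=cx, cy=cy, rad=rad):
            r2 = (p[..., 0] - cx) ** 2 + (p[..., 1] - cy) ** 2
            return (r2 <= rad ** 2) & (np.abs(p[..., 2]) <= z_lo)

        vals += _occupancy(volume_template, rod,
                           [cx - rad, cy - rad, -z_lo],
                           [cx + rad, cy + rad, z_lo])

    out = volume_template.copy_with(np.clip(vals, 0.0, 1.0) * spec.activity)
    return out


def derenzo_analytic_volume(spec: DerenzoSpec) -> float:
    """Closed-form material volume (mm^3) of plates + rods."""
    plates = 2.0 * np.pi * spec.plate_radius ** 2 * spec.plate_thickness
    rods = sum(np.pi * (0.5 * d) ** 2 * spec.rod_length
               for (_, _, d) in derenzo_rod_centers(spec))
    return plates + rods


def make_point_source(position, volume_template: ImageVolume) -> ImageVolume:
    """Unit point source assigned to the voxel containing ``position``."""
    if not volume_template.contains(position):
        raise ValueError(f"point source position {position} outside the volume")
    out = volume_template.copy_with(np.zeros(volume_template.shape))
    out.values[volume_template.voxel_index(position)] = 1.0
    return out


def make_cylinder(radius: float, length: float, activity: float,
                  volume_template: ImageVolume) -> ImageVolume:
    """Uniform activity cylinder centered at the origin, axis along z."""
    he = volume_template.half_extents
    if radius > min(he[0], he[1]) or 0.5 * length > he[2]:
        raise ValueError("cylinder does not fit inside the volume template")

    def inside(p):
        return ((p[..., 0] ** 2 + p[..., 1] ** 2 <= radius ** 2)
                & (np.abs(p[..., 2]) <= 0.5 * length))

    frac = _occupancy(volume_template, inside,
                      [-radius, -radius, -0.5 * length],
                      [radius, radius, 0.5 * length])
    return volume_template.copy_with(frac * activity)


def nrmse(pred: ImageVolume, gt: ImageVolume) -> float:
    """Normalized root-mean-square error (a fraction; multiply by 100 for %).

    RMS of the voxelwise difference over all voxels, divided by the mean
    voxel intensity of the ground-truth array.
    """
    p = pred.values if isinstance(pred, ImageVolume) else np.asarray(pred)
    g = gt.values if isinstance(gt, ImageVolume) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError("NRMSE requires identical shapes")
    mean_gt = float(g.mean())
    if mean_gt <= 0:
        raise ValueError("NRMSE undefined for non-positive ground-truth mean")
    return float(np.sqrt(np.mean((p - g) ** 2)) / mean_gt)
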