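"""Monte Carlo photon transport through the detector ring.

Photon pairs are launched back-to-back from a source point with an isotropic
direction, traced through the scintillator with Beer-Lambert free paths and
photoelectric / Compton (Klein-Nishina) / Rayleigh (Thomson) interactions,
and each photon is registered to the crystal in which it deposited the most
energy.  Coincidences between two distinct registered crystals fill a LOR
histogram.  Scattering between crystals before absorption is what displaces
LOR endpoints -- the inter-crystal scattering (ICS) effect this package
compensates.

Transport geometry: the crystal stack is treated as a solid cylindrical
annulus (inner radius = ring radius, radial thickness = crystal depth, axial
extent = n_rings * axial pitch); the crystal id of an interaction point is its
azimuthal sector x ring slab.  This is exact for a gapless ring tiling up to
the chord-vs-arc difference of the rectangular crystal cross-section.  The
simulation models neither the measured object (no attenuation or scatter in
the FOV) nor positron range / acollinearity.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import LORHistogram, ScannerGeometry, ImageVolume

E_INITIAL = 511.0   # keV, annihilation photon energy
E_CUT = 10.0        # keV, photons below this deposit locally and terminate
ELECTRON_REST = 511.0  # keV (m_e c^2)

_TABLE_E_MIN = 10    # keV, fine lookup grid start (1 keV steps)
_TABLE_E_MAX = 650


# ===================================================================== table
@dataclass
class AttenuationTable:
    """Partial linear attenuation coefficients (1/mm) on an energy grid."""

    energies: np.ndarray
    photoelectric: np.ndarray
    compton: np.ndarray
    rayleigh: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > 50.0 or e[-1] < 600.0:
            raise ValueError("energy grid must cover at least [50, 600] keV")
        self.energies = e
        for name in ("photoelectric", "compton", "rayleigh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != e.shape or np.any(arr < 0):
                raise ValueError(f"{name} coefficients invalid")
            setattr(self, name, arr)

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.compton + self.rayleigh

    # The shipped table is generated by this analytic LYSO-like model (no
    # measured data): Compton from the integrated Klein-Nishina cross-section
    # times the electron density of a 7.1 g/cm^3 scintillator, photoelectric
    # ~ E^-3 anchored to a 33% photoelectric fraction at 511 keV, Rayleigh a
    # small E^-2 component.  It is a synthetic stand-in, not vendor data.
    @classmethod
    def lyso_like(cls) -> "AttenuationTable":
        e = np.arange(10.0, 651.0, 10.0)
        n_e = 1.80e24  # electrons / cm^3
        mu_c = n_e * _kn_total_cross_section(e / ELECTRON_REST) / 10.0  # 1/mm
        mu_pe = 0.030 * (511.0 / e) ** 3        # 1/mm, anchored at 511 keV
        mu_r = 0.005 * (511.0 / e) ** 2
        return cls(e, mu_pe, mu_c, mu_r)

    @classmethod
    def photoelectric_only(cls) -> "AttenuationTable":
        """Absorption-only variant: every registered photon stops where it
        first interacts (no ICS possible) -- used as a null model in tests."""
        t = cls.lyso_like()
        return cls(t.energies, t.total, np.zeros_like(t.energies),
                   np.zeros_like(t.energies))

    def fine_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-keV lookup arrays over [10, 650] keV (log-log interpolated)."""
        ef = np.arange(_TABLE_E_MIN, _TABLE_E_MAX + 1, dtype=float)
        loge = np.log(self.energies)
        out = []
        for arr in (self.photoelectric, self.compton, self.rayleigh):
            if arr.max() <= 0:
                out.append(np.zeros_like(ef))
                continue
            la = np.log(np.maximum(arr, 1e-300))
            fine = np.exp(np.interp(np.log(ef), loge, la))
            fine[fine < 1e-290] = 0.0
            out.append(np.ascontiguousarray(fine))
        return tuple(out)

    def to_csv(self, path) -> None:
        header = "energy_keV,mu_photo_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm"
        np.savetxt(path, np.column_stack(
            [self.energies, self.photoelectric, self.compton, self.rayleigh]),
            delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "AttenuationTable":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], data[:, 2], data[:, 3])

    @classmethod
    def from_material(cls, material: str) -> "AttenuationTable":
        if material == "lyso_like":
            ref = importlib.resources.files("icsfilter") / "data" / "lyso_like_attenuation.csv"
            with importlib.resources.as_file(ref) as p:
                return cls.from_csv(p)
        raise ValueError(f"unknown attenuation material {material!r}")


def _kn_total_cross_section(eps) -> np.ndarray:
    """Integrated Klein-Nishina cross-section (cm^2/electron); eps = E/mc^2."""
    eps = np.asarray(eps, dtype=float)
    r_e2 = 7.9407e-26  # classical electron radius squared, cm^2
    term1 = (1 + eps) / eps ** 2 * (2 * (1 + eps) / (1 + 2 * eps)
                                    - np.log(1 + 2 * eps) / eps)
    term2 = np.log(1 + 2 * eps) / (2 * eps)
    term3 = (1 + 3 * eps) / (1 + 2 * eps) ** 2
    return 2 * np.pi * r_e2 * (term1 + term2 - term3)


# ================================================================ primitives
@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    energy: float = E_INITIAL
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector")
        if self.alive and not (0.0 < self.energy <= E_INITIAL):
            raise ValueError("live photon energy must be in (0, 511] keV")


@dataclass(frozen=True)
class DepositRecord:
    crystal_id: int
    deposited_energy: float
    interaction_order: int

    def __post_init__(self) -> None:
        if self.deposited_energy <= 0:
            raise ValueError("deposited energy must be positive")


def sample_direction(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere (z ~ U(-1,1), azimuth uniform)."""
    z = 1.0 - 2.0 * rng.random()
    phi = 2.0 * np.pi * rng.random()
    s = np.sqrt(max(0.0, 1.0 - z * z))
    return np.array([s * np.cos(phi), s * np.sin(phi), z])


def sample_free_path(mu_total: float, rng: np.random.Generator) -> float:
    """Beer-Lambert free path; mu_total = 0 means the photon escapes."""
    if mu_total < 0:
        raise ValueError("attenuation coefficient must be non-negative")
    if mu_total == 0.0:
        return np.inf
    return -np.log(1.0 - rng.random()) / mu_total


def sample_compton(energy: float, rng: np.random.Generator) -> tuple[float, float]:
    """Scattering angle (rad) and outgoing energy from Klein-Nishina."""
    if energy <= 0:
        raise ValueError("photon energy must be positive")
    cos_t = _kahn_sample(energy / ELECTRON_REST, rng)
    e_out = energy / (1.0 + (energy / ELECTRON_REST) * (1.0 - cos_t))
    return float(np.arccos(cos_t)), float(e_out)


def sample_rayleigh(rng: np.random.Generator) -> float:
    """Thomson scattering angle (rad), density ~ (1 + cos^2) sin(theta)."""
    return float(np.arccos(_thomson_cos(rng.random())))


@njit(cache=True, inline="always")
def _kahn_sample(a, rng):
    """Kahn's rejection method for the Klein-Nishina energy ratio.

    ``a`` is E/mc^2; returns cos(theta).
    """
    while True:
        r1 = rng.random(); r2 = rng.random(); r3 = rng.random()
        if r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return 1.0 - (x - 1.0) / a
        else:
            x = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            c = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (c * c + 1.0 / x):
                return c


@njit(cache=True, inline="always")
def _thomson_cos(uu):
    # invert CDF of (3/8)(1 + c^2) on [-1, 1]: c^3 + 3c = 8u - 4 (Cardano)
    q = 4.0 * uu - 2.0
    s = np.sqrt(q * q + 1.0)
    return np.cbrt(q + s) + np.cbrt(q - s)


# ============================================================ transport core
@njit(cache=True, inline="always")
def _annulus_interval(px, py, pz, dx, dy, dz, r0, r1, zh):
    """First [t_in, t_out] (t_out > 0) where the ray is inside the annular
    solid {r0 <= r <= r1, |z| <= zh}; returns (-1, -1) if none."""
    EPS = 1e-9
    # z slab
    if abs(dz) > 1e-14:
        ta = (-zh - pz) / dz
        tb = (zh - pz) / dz
        z0, z1 = (ta, tb) if ta < tb else (tb, ta)
    else:
        if abs(pz) > zh:
            return -1.0, -1.0
        z0, z1 = -1e30, 1e30
    a = dx * dx + dy * dy
    b = px * dx + py * dy
    c1 = px * px + py * py - r1 * r1
    if a < 1e-14:
        if c1 > 0.0:
            return -1.0, -1.0
        o0, o1 = -1e30, 1e30
        hole = px * px + py * py < r0 * r0
        if hole:
            return -1.0, -1.0  # vertical ray inside the bore never enters
    else:
        disc = b * b - a * c1
        if disc <= 0.0:
            return -1.0, -1.0
        sq = np.sqrt(disc)
        o0 = (-b - sq) / a
        o1 = (-b + sq) / a
    lo = z0 if z0 > o0 else o0
    hi = z1 if z1 < o1 else o1
    if hi <= lo or hi <= EPS:
        return -1.0, -1.0
    # subtract the inner bore
    i_has = False
    i0 = 0.0; i1 = 0.0
    if a >= 1e-14:
        c0 = px * px + py * py - r0 * r0
        disc0 = b * b - a * c0
        if disc0 > 0.0:
            sq0 = np.sqrt(disc0)
            i0 = (-b - sq0) / a
            i1 = (-b + sq0) / a
            i_has = True
    if not i_has or i1 <= lo or i0 >= hi:
        t0 = lo if lo > 0.0 else 0.0
        return t0, hi
    # candidate before the bore
    if i0 > lo and i0 > EPS:
        t0 = lo if lo > 0.0 else 0.0
        if i0 > t0:
            return t0, i0
    # candidate after the bore
    if i1 < hi:
        t0 = i1 if i1 > lo else lo
        if t0 < 0.0:
            t0 = 0.0
        if hi > t0 and hi > EPS:
            return t0, hi
    return -1.0, -1.0


@njit(cache=True, inline="always")
def _crystal_of(x, y, z, n_t, n_rings, pitch_ax, zh):
    dphi = 2.0 * np.pi / n_t
    t = int(np.round(np.arctan2(y, x) / dphi)) % n_t
    r = int((z + zh) / pitch_ax)
    if r < 0:
        r = 0
    if r >= n_rings:
        r = n_rings - 1
    return r * n_t + t


@njit(cache=True, inline="always")
def _rotate_direction(dx, dy, dz, cos_t, phi):
    """New unit vector at polar angle theta from (dx,dy,dz), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # orthonormal basis (u, v) perpendicular to d
    if abs(dz) < 0.999:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    n = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= n; uy /= n; uz /= n
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp = np.cos(phi); sp = np.sin(phi)
    nx = cos_t * dx + sin_t * (cp * ux + sp * vx)
    ny = cos_t * dy + sin_t * (cp * uy + sp * vy)
    nz = cos_t * dz + sin_t * (cp * uz + sp * vz)
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


_MAX_DEPOSITS = 64


@njit(cache=True)
def _trace_core(px, py, pz, dx, dy, dz, e0,
                r0, r1, zh, n_t, n_rings, pitch_ax,
                mu_pe, mu_c, mu_r, rng,
                dep_crystal, dep_energy):
    """Trace one photon; fills deposit arrays, returns (n_deposits, escaped_E)."""
    e = e0
    n_dep = 0
    for _ in range(1000):
        t_in, t_out = _annulus_interval(px, py, pz, dx, dy, dz, r0, r1, zh)
        if t_in < 0.0:
            return n_dep, e  # escaped with remaining energy
        px += t_in * dx; py += t_in * dy; pz += t_in * dz
        chord = t_out - t_in
        ei = int(e) - _TABLE_E_MIN
        if ei < 0:
            ei = 0
        if ei >= mu_pe.size:
            ei = mu_pe.size - 1
        mp = mu_pe[ei]; mc = mu_c[ei]; mr = mu_r[ei]
        mt = mp + mc + mr
        if mt <= 0.0:
            s = 1e30
        else:
            s = -np.log(1.0 - rng.random()) / mt
        if s >= chord:
            adv = chord + 1e-6
            px += adv * dx; py += adv * dy; pz += adv * dz
            continue  # traversed this interval; may re-enter across the bore
        px += s * dx; py += s * dy; pz += s * dz
        cid = _crystal_of(px, py, pz, n_t, n_rings, pitch_ax, zh)
        u = rng.random() * mt
        if u < mp:
            # photoelectric: deposit everything, terminate
            if n_dep < _MAX_DEPOSITS:
                dep_crystal[n_dep] = cid
                dep_energy[n_dep] = e
                n_dep += 1
            return n_dep, 0.0
        elif u < mp + mc:
            cos_t = _kahn_sample(e / ELECTRON_REST, rng)
            e_new = e / (1.0 + (e / ELECTRON_REST) * (1.0 - cos_t))
            if e_new < E_CUT:
                # remaining energy absorbed locally
                if n_dep < _MAX_DEPOSITS:
                    dep_crystal[n_dep] = cid
                    dep_energy[n_dep] = e
                    n_dep += 1
                return n_dep, 0.0
            if n_dep < _MAX_DEPOSITS:
                dep_crystal[n_dep] = cid
                dep_energy[n_dep] = e - e_new
                n_dep += 1
            e = e_new
            dx, dy, dz = _rotate_direction(dx, dy, dz, cos_t,
                                           2.0 * np.pi * rng.random())
        else:
            cos_t = _thomson_cos(rng.random())
            dx, dy, dz = _rotate_direction(dx, dy, dz, cos_t,
                                           2.0 * np.pi * rng.random())
    return n_dep, e


@njit(cache=True, inline="always")
def _register_core(dep_crystal, dep_energy, n_dep):
    """Crystal with maximum summed deposit; ties -> earliest interaction."""
    if n_dep == 0:
        return -1
    best = -1
    best_e = 0.0
    for i in range(n_dep):
        c = dep_crystal[i]
        seen = False
        for j in range(i):
            if dep_crystal[j] == c:
                seen = True
                break
        if seen:
            continue
        tot = 0.0
        for j in range(i, n_dep):
            if dep_crystal[j] == c:
                tot += dep_energy[j]
        if tot > best_e + 1e-12:
            best_e = tot
            best = c
    return best


@njit(cache=True)
def _simulate_pairs(src_x, src_y, src_z, src_w, n_pairs,
                    r0, r1, zh, n_t, n_rings, pitch_ax,
                    mu_pe, mu_c, mu_r, rng):
    """Pair loop; sources given as weighted points (CDF in src_w)."""
    n_c = n_t * n_rings
    hist = np.zeros(n_c * (n_c - 1) // 2)
    dep_c = np.empty(_MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(_MAX_DEPOSITS)
    n_coinc = 0
    for _ in range(n_pairs):
        if src_w.size > 1:
            k = np.searchsorted(src_w, rng.random())
        else:
            k = 0
        x = src_x[k]; y = src_y[k]; z = src_z[k]
        zz = 1.0 - 2.0 * rng.random()
        ph = 2.0 * np.pi * rng.random()
        st = np.sqrt(max(0.0, 1.0 - zz * zz))
        dx = st * np.cos(ph); dy = st * np.sin(ph); dz = zz
        nd, _esc = _trace_core(x, y, z, dx, dy, dz, E_INITIAL,
                               r0, r1, zh, n_t, n_rings, pitch_ax,
                               mu_pe, mu_c, mu_r, rng, dep_c, dep_e)
        c_a = _register_core(dep_c, dep_e, nd)
        nd, _esc = _trace_core(x, y, z, -dx, -dy, -dz, E_INITIAL,
                               r0, r1, zh, n_t, n_rings, pitch_ax,
                               mu_pe, mu_c, mu_r, rng, dep_c, dep_e)
        c_b = _register_core(dep_c, dep_e, nd)
        if c_a >= 0 and c_b >= 0 and c_a != c_b:
            i, j = (c_a, c_b) if c_a < c_b else (c_b, c_a)
            hist[i * n_c - i * (i + 1) // 2 + (j - i - 1)] += 1.0
            n_coinc += 1
    return hist, n_coinc


@njit(cache=True)
def _pair_blur_offsets(n_pairs, r0, r1, zh, n_t, n_rings, pitch_ax,
                       mu_pe, mu_c, mu_r, rng, max_dt, src_r, src_zh):
    """Joint endpoint offsets for coincidence pairs from a volumetric source.

    Offsets (registered minus geometric entry crystal) are recorded in
    canonical per-LOR frames so the coherent parallax displacement of the
    two endpoints keeps its orientation:

    * transaxial -- endpoint A is the one from which endpoint B is reached
      counterclockwise within half a turn; the class is the separation
      ``(tB - tA) mod n_t`` in [0, n_t/2].  This frame fixes the sign of the
      LOR's impact parameter, so drift directions are geometrically
      meaningful.  The reflection symmetry (swap A/B, negate offsets) is
      folded in for statistics.
    * axial -- endpoints ordered by ring (low, high); class is the ring
      difference.  The z-mirror symmetry (swap low/high, negate) is folded.
    """
    n_dz = 2 * n_rings - 1
    counts_t = np.zeros((n_t // 2 + 1, 2 * max_dt + 1, 2 * max_dt + 1))
    counts_z = np.zeros((n_rings, n_dz, n_dz))
    dep_c = np.empty(_MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(_MAX_DEPOSITS)
    n_reg = 0
    for _ in range(n_pairs):
        while True:
            x = src_r * (2.0 * rng.random() - 1.0)
            y = src_r * (2.0 * rng.random() - 1.0)
            if x * x + y * y <= src_r * src_r:
                break
        z = src_zh * (2.0 * rng.random() - 1.0)
        cz = 1.0 - 2.0 * rng.random()
        cphi = 2.0 * np.pi * rng.random()
        st = np.sqrt(max(0.0, 1.0 - cz * cz))
        dx = st * np.cos(cphi); dy = st * np.sin(cphi); dz = cz
        ok = True
        dt_pair = np.zeros(2, dtype=np.int64)
        dz_pair = np.zeros(2, dtype=np.int64)
        entry_t = np.zeros(2, dtype=np.int64)
        entry_r = np.zeros(2, dtype=np.int64)
        for side in range(2):
            sx, sy, sz = (dx, dy, dz) if side == 0 else (-dx, -dy, -dz)
            t_in, t_out = _annulus_interval(x, y, z, sx, sy, sz, r0, r1, zh)
            if t_in < 0.0:
                ok = False
                break
            ex = x + t_in * sx; ey = y + t_in * sy; ez = z + t_in * sz
            entry = _crystal_of(ex + 1e-3 * sx, ey + 1e-3 * sy,
                                ez + 1e-3 * sz, n_t, n_rings, pitch_ax, zh)
            nd, _esc = _trace_core(x, y, z, sx, sy, sz, E_INITIAL,
                                   r0, r1, zh, n_t, n_rings, pitch_ax,
                                   mu_pe, mu_c, mu_r, rng, dep_c, dep_e)
            cid = _register_core(dep_c, dep_e, nd)
            if cid < 0:
                ok = False
                break
            dt = (cid % n_t) - (entry % n_t)
            if dt > n_t // 2:
                dt -= n_t
            if dt < -(n_t // 2):
                dt += n_t
            if dt < -max_dt or dt > max_dt:
                ok = False
                break
            dt_pair[side] = dt
            dz_pair[side] = (cid // n_t) - (entry // n_t)
            entry_t[side] = entry % n_t
            entry_r[side] = entry // n_t
        if not ok:
            continue
        n_reg += 1
        # transaxial canonical frame
        sraw = (entry_t[1] - entry_t[0]) % n_t
        if sraw <= n_t // 2:
            sep = sraw
            dtA = dt_pair[0]; dtB = dt_pair[1]
        else:
            sep = n_t - sraw
            dtA = dt_pair[1]; dtB = dt_pair[0]
        counts_t[sep, dtA + max_dt, dtB + max_dt] += 0.5
        counts_t[sep, -dtB + max_dt, -dtA + max_dt] += 0.5
        # axial canonical frame (ring-ordered)
        if entry_r[0] <= entry_r[1]:
            dr = entry_r[1] - entry_r[0]
            dzL = dz_pair[0]; dzH = dz_pair[1]
        else:
            dr = entry_r[0] - entry_r[1]
            dzL = dz_pair[1]; dzH = dz_pair[0]
        counts_z[dr, dzL + n_rings - 1, dzH + n_rings - 1] += 0.5
        counts_z[dr, -dzH + n_rings - 1, -dzL + n_rings - 1] += 0.5
    return counts_t, counts_z, n_reg


@njit(cache=True)
def _blur_offsets(n_photons, r0, r1, zh, n_t, n_rings, pitch_ax,
                  mu_pe, mu_c, mu_r, rng, max_dt, src_r, src_zh):
    """Offsets (registered - geometric entry crystal).

    With ``src_r > 0`` photons start at uniformly random positions inside a
    source cylinder (radius src_r, half-length src_zh) with isotropic
    directions -- the realistic incidence mix of an acquisition, so oblique
    penetration (parallax) contributes.  With ``src_r == 0`` photons hit the
    inner surface radially (perpendicular incidence).
    """
    n_dz = 2 * n_rings - 1
    counts = np.zeros((2 * max_dt + 1, n_dz))
    dep_c = np.empty(_MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(_MAX_DEPOSITS)
    n_reg = 0
    for _ in range(n_photons):
        if src_r > 0.0:
            while True:
                x = src_r * (2.0 * rng.random() - 1.0)
                y = src_r * (2.0 * rng.random() - 1.0)
                if x * x + y * y <= src_r * src_r:
                    break
            z = src_zh * (2.0 * rng.random() - 1.0)
            cz = 1.0 - 2.0 * rng.random()
            cphi = 2.0 * np.pi * rng.random()
            st = np.sqrt(max(0.0, 1.0 - cz * cz))
            dx = st * np.cos(cphi); dy = st * np.sin(cphi); dz = cz
            t_in, t_out = _annulus_interval(x, y, z, dx, dy, dz, r0, r1, zh)
            if t_in < 0.0:
                continue
            ex = x + t_in * dx; ey = y + t_in * dy; ez = z + t_in * dz
        else:
            phi = 2.0 * np.pi * rng.random()
            z = zh * (2.0 * rng.random() - 1.0)
            x = (r0 - 1e-6) * np.cos(phi)
            y = (r0 - 1e-6) * np.sin(phi)
            dx = np.cos(phi); dy = np.sin(phi); dz = 0.0
            ex = x; ey = y; ez = z
        entry = _crystal_of(ex + 1e-3 * dx, ey + 1e-3 * dy, ez + 1e-3 * dz,
                            n_t, n_rings, pitch_ax, zh)
        t0 = entry % n_t
        ring0 = entry // n_t
        nd, _esc = _trace_core(x, y, z, dx, dy, dz, E_INITIAL,
                               r0, r1, zh, n_t, n_rings, pitch_ax,
                               mu_pe, mu_c, mu_r, rng, dep_c, dep_e)
        cid = _register_core(dep_c, dep_e, nd)
        if cid < 0:
            continue
        n_reg += 1
        dt = (cid % n_t) - t0
        if dt > n_t // 2:
            dt -= n_t
        if dt < -(n_t // 2):
            dt += n_t
        dr = (cid // n_t) - ring0
        if -max_dt <= dt <= max_dt:
            counts[dt + max_dt, dr + n_rings - 1] += 1.0
    return counts, n_reg


# ================================================================ public API
def trace_photon(state: PhotonState, geometry: ScannerGeometry,
                 table: AttenuationTable,
                 rng: np.random.Generator) -> list[DepositRecord]:
    """Trace a single photon; returns its deposit records (may be empty)."""
    mu_pe, mu_c, mu_r = table.fine_grids()
    dep_c = np.empty(_MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(_MAX_DEPOSITS)
    nd, _esc = _trace_core(
        *state.position, *state.direction, state.energy,
        geometry.ring_radius, geometry.ring_radius + geometry.crystal_depth,
        0.5 * geometry.axial_extent, geometry.n_crystals_transaxial,
        geometry.n_rings, geometry.crystal_pitch_axial,
        mu_pe, mu_c, mu_r, rng, dep_c, dep_e)
    return [DepositRecord(int(dep_c[i]), float(dep_e[i]), i) for i in range(nd)]


def trace_photon_energy_check(state, geometry, table, rng):
    """As trace_photon but also returns the escaped energy (bookkeeping)."""
    mu_pe, mu_c, mu_r = table.fine_grids()
    dep_c = np.empty(_MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(_MAX_DEPOSITS)
    nd, esc = _trace_core(
        *state.position, *state.direction, state.energy,
        geometry.ring_radius, geometry.ring_radius + geometry.crystal_depth,
        0.5 * geometry.axial_extent, geometry.n_crystals_transaxial,
        geometry.n_rings, geometry.crystal_pitch_axial,
        mu_pe, mu_c, mu_r, rng, dep_c, dep_e)
    deposits = [DepositRecord(int(dep_c[i]), float(dep_e[i]), i)
                for i in range(nd)]
    return deposits, float(esc)


def register_hit(deposits: list[DepositRecord]) -> int | None:
    """Crystal with the maximum summed deposited energy (None if no hits).

    Equal maxima break toward the earlier interaction order.
    """
    if not deposits:
        return None
    order = sorted(deposits, key=lambda d: d.interaction_order)
    cid = _register_core(
        np.array([d.crystal_id for d in order], dtype=np.int64),
        np.array([d.deposited_energy for d in order]), len(order))
    return int(cid)


def _geom_args(geometry: ScannerGeometry):
    return (geometry.ring_radius,
            geometry.ring_radius + geometry.crystal_depth,
            0.5 * geometry.axial_extent,
            geometry.n_crystals_transaxial, geometry.n_rings,
            geometry.crystal_pitch_axial)


def simulate_point_source(position, n_pairs: int, geometry: ScannerGeometry,
                          table: AttenuationTable, seed: int) -> LORHistogram:
    """LOR histogram of an ICS-affected point-source acquisition."""
    position = np.asarray(position, dtype=float)
    r = np.hypot(position[0], position[1])
    if r >= geometry.ring_radius or abs(position[2]) > 0.5 * geometry.axial_extent:
        raise ValueError("point source must lie inside the detector bore")
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    mu_pe, mu_c, mu_r = table.fine_grids()
    hist, n_coinc = _simulate_pairs(
        np.array([position[0]]), np.array([position[1]]),
        np.array([position[2]]), np.array([1.0]), int(n_pairs),
        *_geom_args(geometry), mu_pe, mu_c, mu_r,
        np.random.default_rng(int(seed) & 0x7FFFFFFF))
    return LORHistogram(geometry.geometry_hash(), hist,
                        {"kind": "point_source", "position": position.tolist(),
                         "n_pairs": int(n_pairs), "seed": int(seed),
                         "n_coincidences": int(n_coinc)})


def simulate_volume_source(volume: ImageVolume, n_pairs: int,
                           geometry: ScannerGeometry, table: AttenuationTable,
                           seed: int) -> LORHistogram:
    """Acquisition of an arbitrary activity volume: emission points sampled
    proportionally to voxel activity, uniformly within each voxel."""
    vals = volume.values.ravel()
    total = vals.sum()
    if total <= 0:
        raise ValueError("volume has no activity")
    nz = np.flatnonzero(vals)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    w = vals[nz] / total
    cdf = np.cumsum(w)
    cdf[-1] = 1.0
    idx = np.array(np.unravel_index(nz, volume.shape)).T.astype(float)
    centers = volume.voxel_to_world(idx)
    # jitter emission positions uniformly within their voxel
    jitter_seed = int(rng.integers(0, 2**31 - 1))
    jr = np.random.default_rng(jitter_seed)
    # positions are resampled per pair inside the numba loop by drawing the
    # voxel; sub-voxel jitter is folded in by pre-jittering 8 replicas
    reps = []
    for _ in range(8):
        reps.append(centers + (jr.random(centers.shape) - 0.5) * volume.voxel_size)
    src = np.concatenate(reps, axis=0)
    src_w = np.tile(w / 8.0, 8)
    cdf = np.cumsum(src_w)
    cdf[-1] = 1.0
    mu_pe, mu_c, mu_r = table.fine_grids()
    hist, n_coinc = _simulate_pairs(
        np.ascontiguousarray(src[:, 0]), np.ascontiguousarray(src[:, 1]),
        np.ascontiguousarray(src[:, 2]), cdf, int(n_pairs),
        *_geom_args(geometry), mu_pe, mu_c, mu_r,
        np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
    return LORHistogram(geometry.geometry_hash(), hist,
                        {"kind": "volume_source", "n_pairs": int(n_pairs),
                         "seed": int(seed), "n_coincidences": int(n_coinc)})


@dataclass
class LORBlur:
    """Endpoint mislocation distribution: P(transaxial, axial crystal offset).

    Estimated from perpendicular-incidence photons; drives the LOR-space
    reference correction as a spatially invariant endpoint blur.
    """

    dt_offsets: np.ndarray   # transaxial index offsets
    dz_offsets: np.ndarray   # ring index offsets
    probs: np.ndarray        # (n_dt, n_dz), sums to 1

    def __post_init__(self) -> None:
        s = self.probs.sum()
        if s <= 0:
            raise ValueError("degenerate (zero-count) blur estimate")
        self.probs = self.probs / s

    @property
    def is_delta(self) -> bool:
        i = int(np.argmax(self.dt_offsets == 0))
        j = int(np.argmax(self.dz_offsets == 0))
        return bool(self.probs[i, j] > 1.0 - 1e-12)


@dataclass
class PairLORBlur:
    """Joint endpoint mislocation of coincidence pairs, per LOR class.

    ``joint_t[c, i, j]`` is the probability of transaxial offsets
    ``(dt_offsets[i]`` for endpoint A, ``dt_offsets[j]`` for endpoint B) of
    a LOR in separation class ``c`` (circular transaxial distance of the
    entry crystals, endpoint A chosen so B lies counterclockwise within half
    a turn); ``joint_z`` likewise for ring offsets in the ring-ordered
    (low, high) frame, classed by ring difference.  The class conditioning
    keeps the blur invariant under ring rotation while letting it depend on
    the LOR's own obliquity, which drives crystal-penetration parallax; the
    canonical frames preserve the orientation of the coherent endpoint
    displacements.  Classes with no counts fall back to the nearest
    populated class.
    """

    dt_offsets: np.ndarray
    dz_offsets: np.ndarray
    joint_t: np.ndarray    # (n_t // 2 + 1 separation classes, n_dt, n_dt)
    joint_z: np.ndarray    # (n_rings ring-difference classes, n_dz, n_dz)

    def __post_init__(self) -> None:
        if self.joint_t.sum() <= 0 or self.joint_z.sum() <= 0:
            raise ValueError("degenerate (zero-count) blur estimate")
        for arr_name, map_name in (("joint_t", "class_map_t"),
                                   ("joint_z", "class_map_z")):
            arr = getattr(self, arr_name).copy()
            populated = np.flatnonzero(arr.sum(axis=(1, 2)) > 0)
            cmap = np.empty(arr.shape[0], dtype=np.int64)
            for c in range(arr.shape[0]):
                cmap[c] = populated[np.argmin(np.abs(populated - c))]
            for c in populated:
                arr[c] = arr[c] / arr[c].sum()
            setattr(self, arr_name, arr)
            setattr(self, map_name, cmap)


def estimate_pair_lor_blur(geometry: ScannerGeometry, table: AttenuationTable,
                           n_pairs: int, seed: int, max_dt: int = 6,
                           source_radius: float | None = None,
                           source_half_length: float | None = None
                           ) -> PairLORBlur:
    """Joint endpoint-offset blur from coincidence pairs (volumetric source).

    This is the estimate behind the LOR-space reference correction: it keeps
    the correlation between the two endpoints' displacements, which a
    per-endpoint (independent) blur destroys.
    """
    max_dt = min(max_dt, geometry.n_crystals_transaxial // 2 - 1)
    src_r = (0.5 * geometry.ring_radius if source_radius is None
             else float(source_radius))
    src_zh = (0.4 * geometry.axial_extent if source_half_length is None
              else float(source_half_length))
    mu_pe, mu_c, mu_r = table.fine_grids()
    ct, cz, n_reg = _pair_blur_offsets(
        int(n_pairs), *_geom_args(geometry), mu_pe, mu_c, mu_r,
        np.random.default_rng(int(seed) & 0x7FFFFFFF), max_dt, src_r, src_zh)
    if n_reg == 0:
        raise ValueError("no pairs registered; cannot estimate LOR blur")
    if n_reg < 10 * (ct.size + cz.size):
        warnings.warn("pair LOR blur estimate is noisy: fewer than 10 "
                      "expected counts per joint bin", stacklevel=2)
    dt = np.arange(-max_dt, max_dt + 1)
    dz = np.arange(-(geometry.n_rings - 1), geometry.n_rings)
    return PairLORBlur(dt, dz, ct, cz)


def estimate_lor_blur(geometry: ScannerGeometry, table: AttenuationTable,
                      n_pairs: int, seed: int, max_dt: int = 6,
                      incidence: str = "volumetric",
                      source_radius: float | None = None,
                      source_half_length: float | None = None) -> LORBlur:
    """Estimate the crystal-offset endpoint mislocation kernel.

    ``incidence='volumetric'`` (default) launches photons from a source
    cylinder in the FOV with isotropic directions and records the offset of
    the registered crystal from the geometric entry crystal, so both ICS and
    oblique crystal penetration contribute -- the blur a real acquisition
    sees.  ``incidence='perpendicular'`` fires photons radially at the inner
    surface, isolating pure ICS.
    """
    max_dt = min(max_dt, geometry.n_crystals_transaxial // 2 - 1)
    if incidence == "volumetric":
        src_r = (0.5 * geometry.ring_radius if source_radius is None
                 else float(source_radius))
        src_zh = (0.4 * geometry.axial_extent if source_half_length is None
                  else float(source_half_length))
    elif incidence == "perpendicular":
        src_r, src_zh = 0.0, 0.0
    else:
        raise ValueError("incidence must be 'volumetric' or 'perpendicular'")
    mu_pe, mu_c, mu_r = table.fine_grids()
    counts, n_reg = _blur_offsets(int(n_pairs), *_geom_args(geometry),
                                  mu_pe, mu_c, mu_r,
                                  np.random.default_rng(int(seed) & 0x7FFFFFFF),
                                  max_dt, src_r, src_zh)
    if n_reg == 0:
        raise ValueError("no photons registered; cannot estimate LOR blur")
    n_bins = counts.size
    if n_reg < 10 * n_bins:
        warnings.warn("LOR blur estimate is noisy: fewer than 10 expected "
                      "counts per offset bin", stacklevel=2)
    dt = np.arange(-max_dt, max_dt + 1)
    dz = np.arange(-(geometry.n_rings - 1), geometry.n_rings)
    return LORBlur(dt, dz, counts)
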