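"""Rotated 3D skew-normal distributions discretized into 11x11x11 kernels.

The univariate skew normal generalizes the Gaussian with a shape parameter:

    SN(x; mu, sigma, alpha) = (2 / sigma) * phi(t) * Phi(alpha * t),
    t = (x - mu) / sigma,

with ``phi``/``Phi`` the standard normal PDF/CDF (``Phi`` through the standard
error function).  The 3D form is the product of independent axis factors,
evaluated at grid points rotated in the xy plane by a learned angle theta:

    x' = R(theta) x,   R = [[c, s, 0], [-s, c, 0], [0, 0, 1]].

Kernels are the distribution sampled on the integer lattice [-5, 5]^3 and
normalized to unit sum so filtering preserves total activity.  All gradients
with respect to the 10 parameters (mu, sigma, alpha, theta) are analytic --
they back the skew-normal prediction head during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

KERNEL_SIZE = 11
KERNEL_HALF = KERNEL_SIZE // 2

# printed clamping ranges for the 10 learned parameters
MU_RANGE = (-5.0, 5.0)
SIGMA_RANGE = (0.01, 10.0)
ALPHA_RANGE = (-5.0, 5.0)
THETA_RANGE = (0.0, 360.0)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def kernel_grid() -> np.ndarray:
    """(1331, 3) integer offsets of the kernel lattice, C-order over axes."""
    r = np.arange(-KERNEL_HALF, KERNEL_HALF + 1, dtype=float)
    ii, jj, kk = np.meshgrid(r, r, r, indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])


_GRID = kernel_grid()


@dataclass(frozen=True)
class SkewNormParams:
    """Location, scale, skewness per axis plus an xy-plane rotation (deg)."""

    mu: tuple
    sigma: tuple
    alpha: tuple
    theta: float

    def __post_init__(self) -> None:
        if len(self.mu) != 3 or len(self.sigma) != 3 or len(self.alpha) != 3:
            raise ValueError("mu, sigma, alpha must each have 3 components")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma components must be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([*self.mu, *self.sigma, *self.alpha, self.theta])

    @classmethod
    def from_vector(cls, v) -> "SkewNormParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (10,):
            raise ValueError("parameter vector must have 10 entries")
        return cls(tuple(v[0:3]), tuple(v[3:6]), tuple(v[6:9]), float(v[9]))


def clamp_params(raw) -> SkewNormParams:
    """Clamp a raw 10-vector to the valid parameter box (hard clamp)."""
    v = np.asarray(raw, dtype=float).copy()
    if v.shape != (10,):
        raise ValueError("expected a 10-vector (mu, sigma, alpha, theta)")
    v[0:3] = np.clip(v[0:3], *MU_RANGE)
    v[3:6] = np.clip(v[3:6], *SIGMA_RANGE)
    v[6:9] = np.clip(v[6:9], *ALPHA_RANGE)
    v[9] = np.clip(v[9], *THETA_RANGE)
    return SkewNormParams.from_vector(v)


def clamp_mask(raw) -> np.ndarray:
    """1 where the raw parameter lies strictly inside its range, else 0.

    This is the hard-clamp gradient used to chain training updates through
    ``clamp_params`` (a straight-through variant simply ignores this mask).
    """
    v = np.asarray(raw, dtype=float)
    lo = np.array([*([MU_RANGE[0]] * 3), *([SIGMA_RANGE[0]] * 3),
                   *([ALPHA_RANGE[0]] * 3), THETA_RANGE[0]])
    hi = np.array([*([MU_RANGE[1]] * 3), *([SIGMA_RANGE[1]] * 3),
                   *([ALPHA_RANGE[1]] * 3), THETA_RANGE[1]])
    return ((v > lo) & (v < hi)).astype(float)


def sn_pdf(x, mu: float, sigma: float, alpha: float):
    """Univariate skew-normal density."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = (np.asarray(x, dtype=float) - mu) / sigma
    return (2.0 / sigma) * _phi(t) * ndtr(alpha * t)


def _phi(t):
    return np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)


def rotation_matrix(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def sn3d(x, params: SkewNormParams):
    """Rotated 3D skew-normal density at point(s) x (shape (..., 3))."""
    x = np.asarray(x, dtype=float)
    xr = x @ rotation_matrix(params.theta).T
    out = np.ones(xr.shape[:-1])
    for d in range(3):
        out = out * sn_pdf(xr[..., d], params.mu[d], params.sigma[d],
                           params.alpha[d])
    return out


def evaluate_kernel(params: SkewNormParams, with_grad: bool = False):
    """Discretize the distribution on the 11^3 lattice, normalized to sum 1.

    With ``with_grad=True`` also returns the (1331, 10) Jacobian of the
    flattened kernel with respect to (mu, sigma, alpha, theta); matches
    central finite differences to ~1e-6 relative.  Densities are evaluated in
    log space (log_ndtr for the CDF factor) so extreme parameter corners of
    the clamp box cannot underflow the normalizer.
    """
    mu = np.asarray(params.mu)
    sigma = np.asarray(params.sigma)
    alpha = np.asarray(params.alpha)
    theta = params.theta
    R = rotation_matrix(theta)
    xr = _GRID @ R.T                              # (1331, 3)
    t = (xr - mu) / sigma                         # (1331, 3)
    u = alpha * t
    logphi = -0.5 * t * t - _LOG_SQRT_2PI
    logPhi = log_ndtr(u)
    logf = np.sum(np.log(2.0 / sigma) + logphi + logPhi, axis=1)
    shift = logf.max()
    if not np.isfinite(shift):
        raise ValueError("skew-normal kernel underflow; widen sigma")
    f = np.exp(logf - shift)
    S = f.sum()
    k = (f / S).reshape((KERNEL_SIZE,) * 3)
    if not with_grad:
        return k

    # hazard ratio phi(u)/Phi(u), computed in log space (stable for u -> -inf)
    r = np.exp(-0.5 * u * u - _LOG_SQRT_2PI - logPhi)
    dlogf_dmu = (t - alpha * r) / sigma                       # (1331, 3)
    dlogf_dsigma = (t * t - 1.0 - u * r) / sigma
    dlogf_dalpha = r * t
    # theta enters through the rotated xy coordinates
    dlogf_dx = (alpha * r - t) / sigma                        # d logf / d x'_d
    dR = np.deg2rad(1.0) * np.array(
        [[-np.sin(np.deg2rad(theta)), np.cos(np.deg2rad(theta)), 0.0],
         [-np.cos(np.deg2rad(theta)), -np.sin(np.deg2rad(theta)), 0.0],
         [0.0, 0.0, 0.0]])
    dxr = _GRID @ dR.T                                        # (1331, 3)
    dlogf_dtheta = np.sum(dlogf_dx * dxr, axis=1, keepdims=True)
    dlogf = np.concatenate([dlogf_dmu, dlogf_dsigma, dlogf_dalpha,
                            dlogf_dtheta], axis=1)            # (1331, 10)
    df = f[:, None] * dlogf
    kflat = k.ravel()
    jac = (df - kflat[:, None] * df.sum(axis=0)[None, :]) / S
    return k, jac


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Isotropic Gaussian discretized on the kernel lattice, unit sum."""
    g = np.exp(-0.5 * np.sum(_GRID ** 2, axis=1) / sigma ** 2)
    return (g / g.sum()).reshape((KERNEL_SIZE,) * 3)


def mirror_kernel(kernel: np.ndarray, flips) -> np.ndarray:
    """Reverse the kernel along the flipped axes (sum is preserved exactly)."""
    kernel = np.asarray(kernel)
    if kernel.shape != (KERNEL_SIZE,) * 3:
        raise ValueError("kernel must be 11x11x11")
    axes = tuple(a for a, f in enumerate(flips) if f)
    return np.flip(kernel, axis=axes) if axes else kernel.copy()
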