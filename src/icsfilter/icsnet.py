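"""Filter-prediction networks: a multilayer perceptron with two heads.

Both networks map a 3D world position (mm) to a normalized, non-negative
11x11x11 image-space filter kernel.  They share a fully connected trunk of
hidden widths 64 / 128 / 256 / 512 with Mish activations and differ only in
the output layer:

* **direct head** -- 1331 outputs, rectified and normalized to unit sum;
  initialized so the very first prediction is the isotropic Gaussian kernel
  with sigma = 7/6.
* **skew-normal head** -- 10 outputs (no activation) interpreted as the
  location / scale / skewness / rotation parameters of the rotated 3D
  skew-normal kernel, clamped to their valid ranges before evaluation;
  initialized at mu = (1,1,1), sigma = (1,1,1), alpha = (1,1,1), theta = 180.

Inputs are standardized by the FOV half-extent before the first layer (the
public API takes raw millimeters).  Everything is NumPy; gradients are exact
analytic backpropagation, verified against finite differences in the tests.
"""

from __future__ import annotations

import json
import warnings

import numpy as np

from . import skewnorm
from .skewnorm import (KERNEL_SIZE, clamp_mask, clamp_params, evaluate_kernel,
                       gaussian_kernel)

HIDDEN_WIDTHS = (64, 128, 256, 512)
DIRECT_OUT = KERNEL_SIZE ** 3
SKEWNORM_OUT = 10
GAUSS_INIT_SIGMA = 7.0 / 6.0
SKEWNORM_INIT = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 180.0])


def mish(x):
    """x * tanh(softplus(x)), overflow-safe for large |x|."""
    return x * np.tanh(np.logaddexp(0.0, x))


def mish_grad(x):
    sp = np.logaddexp(0.0, x)
    t = np.tanh(sp)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    return t + x * (1.0 - t * t) * sig


class ICSNet:
    """MLP predicting an image-space ICS correction kernel at a position."""

    def __init__(self, head: str = "direct", fov_half_extents=(30.0, 30.0, 16.0),
                 seed: int = 0, straight_through_clamp: bool = False):
        if head not in ("direct", "skewnorm"):
            raise ValueError("head must be 'direct' or 'skewnorm'")
        self.head = head
        self.fov_half_extents = np.asarray(fov_half_extents, dtype=float)
        self.seed = int(seed)
        self.straight_through_clamp = bool(straight_through_clamp)
        out_dim = DIRECT_OUT if head == "direct" else SKEWNORM_OUT
        dims = (3, *HIDDEN_WIDTHS, out_dim)
        rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            self.weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                           size=(dims[i + 1], dims[i])))
            self.biases.append(np.zeros(dims[i + 1]))
        # output layer: zero weights + bias set so the first prediction is the
        # documented starting kernel, independent of the trunk init
        self.weights[-1][:] = 0.0
        if head == "direct":
            self.biases[-1] = gaussian_kernel(GAUSS_INIT_SIGMA).ravel().copy()
        else:
            self.biases[-1] = SKEWNORM_INIT.copy()
        self.history: list[dict] = []

    # ------------------------------------------------------------- plumbing
    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def count_parameters(self) -> int:
        return int(sum(w.size + b.size
                       for w, b in zip(self.weights, self.biases)))

    def parameters(self):
        for w, b in zip(self.weights, self.biases):
            yield w
            yield b

    # -------------------------------------------------------------- forward
    def _trunk_forward(self, position):
        """Returns (output vector, cache for backward)."""
        x = np.asarray(position, dtype=float) / self.fov_half_extents
        pre = []      # pre-activation per layer
        acts = [x]    # inputs per layer
        h = x
        for i in range(self.n_layers - 1):
            z = self.weights[i] @ h + self.biases[i]
            pre.append(z)
            h = mish(z)
            acts.append(h)
        out = self.weights[-1] @ h + self.biases[-1]
        return out, (pre, acts)

    def predict_kernel(self, position, with_cache: bool = False):
        """Normalized non-negative 11^3 kernel at a world position (mm)."""
        out, cache = self._trunk_forward(position)
        if self.head == "direct":
            u = np.maximum(out, 0.0)
            s = u.sum()
            if s <= 0.0:
                warnings.warn("direct head produced an all-zero kernel; "
                              "falling back to the centered delta",
                              stacklevel=2)
                k = np.zeros(DIRECT_OUT)
                k[DIRECT_OUT // 2] = 1.0
                head_cache = (out, None, 0.0)
            else:
                k = u / s
                head_cache = (out, u, s)
        else:
            params = clamp_params(out)
            k3, jac = evaluate_kernel(params, with_grad=True)
            k = k3.ravel()
            head_cache = (out, params, jac)
        kernel = k.reshape((KERNEL_SIZE,) * 3)
        if with_cache:
            return kernel, (cache, head_cache)
        return kernel

    # ------------------------------------------------------------- backward
    def backward(self, cache, grad_kernel) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter.

        ``grad_kernel`` is dLoss/dkernel (11^3); returns a flat list matching
        ``parameters()`` order.
        """
        (pre, acts), (out, aux1, aux2) = cache
        gk = np.asarray(grad_kernel, dtype=float).ravel()
        if self.head == "direct":
            u, s = aux1, aux2
            if u is None:  # delta fallback: no useful gradient
                d_out = np.zeros_like(out)
            else:
                k = u / s
                d_u = (gk - gk @ k) / s
                d_out = d_u * (out > 0.0)
        else:
            params, jac = aux1, aux2
            d_clamped = jac.T @ gk
            if self.straight_through_clamp:
                d_out = d_clamped
            else:
                d_out = d_clamped * clamp_mask(out)
        grads: list[np.ndarray] = []
        delta = d_out
        for i in range(self.n_layers - 1, -1, -1):
            gw = np.outer(delta, acts[i])
            gb = delta.copy()
            grads.insert(0, gb)
            grads.insert(0, gw)
            if i > 0:
                delta = (self.weights[i].T @ delta) * mish_grad(pre[i - 1])
        return grads

    # ------------------------------------------------------------------- IO
    def copy(self) -> "ICSNet":
        net = ICSNet(self.head, self.fov_half_extents, self.seed,
                     self.straight_through_clamp)
        net.weights = [w.copy() for w in self.weights]
        net.biases = [b.copy() for b in self.biases]
        net.history = list(self.history)
        return net

    def save(self, path) -> None:
        meta = {"head": self.head, "seed": self.seed,
                "fov_half_extents": self.fov_half_extents.tolist(),
                "straight_through_clamp": self.straight_through_clamp,
                "history": self.history}
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ICSNet":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            net = cls(meta["head"], meta["fov_half_extents"], meta["seed"],
                      meta.get("straight_through_clamp", False))
            net.weights = [f[f"w{i}"] for i in range(net.n_layers)]
            net.biases = [f[f"b{i}"] for i in range(net.n_layers)]
            net.history = meta.get("history", [])
        return net


def count_parameters(head: str) -> int:
    """Closed-form trainable parameter count for a head's architecture."""
    dims = (3, *HIDDEN_WIDTHS,
            DIRECT_OUT if head == "direct" else SKEWNORM_OUT)
    return sum(dims[i] * dims[i + 1] + dims[i + 1]
               for i in range(len(dims) - 1))
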