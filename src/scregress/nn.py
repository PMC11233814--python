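"""Minimal feed-forward network primitives with manual backpropagation.

The three network heads used by the framework (encoder, projection head,
regression head) are plain fully connected stacks with ReLU activations, so
forward/backward passes reduce to a handful of matrix products. Parameters
are kept as flat lists of ``[W, b]`` arrays in float32; gradients mirror that
layout. Layers are initialized uniformly on +-1/sqrt(fan_in) (the de-facto
default for affine layers in the major deep-learning frameworks; the small
scale matters — wide high-dimensional stacks with larger variance-preserving
initializations memorize i.i.d. tabular inputs before they generalize).
Seeding through a numpy Generator keeps runs reproducible end to end.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

# A parameter list is [W1, b1, W2, b2, ...]; layer i maps via x @ Wi + bi.


def init_mlp(dims: list[int], rng: np.random.Generator) -> list[np.ndarray]:
    """Parameters for a stack of ``len(dims) - 1`` affine layers.

    Weights and biases drawn uniformly from +-1/sqrt(fan_in).
    """
    params: list[np.ndarray] = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        lim = 1.0 / np.sqrt(fan_in)
        params.append(rng.uniform(-lim, lim, (fan_in, fan_out)).astype(DTYPE))
        params.append(rng.uniform(-lim, lim, fan_out).astype(DTYPE))
    return params


def n_layers(params: list[np.ndarray]) -> int:
    return len(params) // 2


def mlp_forward(
    params: list[np.ndarray],
    x: np.ndarray,
    relu_last: bool,
    want_cache: bool = False,
):
    """Forward pass with ReLU after every layer except (optionally) the last.

    Returns the output, or ``(output, cache)`` when ``want_cache`` — the cache
    holds each layer's input and whether ReLU clipped, for the backward pass.
    """
    x = np.ascontiguousarray(x, dtype=DTYPE)
    cache = [] if want_cache else None
    k = n_layers(params)
    for i in range(k):
        w, b = params[2 * i], params[2 * i + 1]
        pre = x @ w + b
        act = relu_last or i < k - 1
        out = np.maximum(pre, 0.0) if act else pre
        if want_cache:
            cache.append((x, out if act else None))
        x = out
    return (x, cache) if want_cache else x


def mlp_backward(
    params: list[np.ndarray],
    cache: list,
    grad_out: np.ndarray,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Backward pass matching :func:`mlp_forward`; returns (grads, grad_input)."""
    grads: list[np.ndarray | None] = [None] * len(params)
    g = np.ascontiguousarray(grad_out, dtype=DTYPE)
    for i in reversed(range(n_layers(params))):
        x_in, activated = cache[i]
        if activated is not None:  # ReLU layer: zero gradient where clipped
            g = g * (activated > 0)
        w = params[2 * i]
        grads[2 * i] = x_in.T @ g
        grads[2 * i + 1] = g.sum(axis=0)
        g = g @ w.T
    return grads, g


def normalize_forward(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise L2 normalization; returns (z, norms) for the backward pass."""
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms = np.maximum(norms, np.finfo(u.dtype).tiny)
    return u / norms, norms


def normalize_backward(z: np.ndarray, norms: np.ndarray, grad_z: np.ndarray) -> np.ndarray:
    """Gradient through z = u / ||u||: project out the radial component."""
    inner = (z * grad_z).sum(axis=1, keepdims=True)
    return (grad_z - z * inner) / norms


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updates in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def clone_params(params: list[np.ndarray]) -> list[np.ndarray]:
    return [p.copy() for p in params]
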