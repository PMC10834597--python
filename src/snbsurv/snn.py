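"""Self-normalizing network primitives.

SELU activation, alpha-dropout, and a small fully-connected network with
LeCun-normal initialization and explicit reverse-mode gradients. The SELU
constants are the canonical fixed-point values: with LeCun-scaled weights
(variance 1/fan-in) and standardized inputs, activations are driven toward
zero mean and unit variance layer after layer, which is what lets deep
feed-forward survival networks train without batch normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "selu",
    "selu_grad",
    "alpha_dropout",
    "LayerSpec",
    "MLP",
    "mlp_forward",
    "Adam",
]

# Fixed-point constants of the self-normalizing map, to full double precision.
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772
# Negative saturation value lim_{x -> -inf} selu(x) = -lambda * alpha.
SELU_SATURATION = -SELU_LAMBDA * SELU_ALPHA


def selu(x):
    """Scaled exponential linear unit.

    ``selu(x) = lambda*x`` for x > 0 and ``lambda*alpha*(exp(x)-1)`` otherwise.
    """
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, SELU_LAMBDA * x,
                    SELU_LAMBDA * SELU_ALPHA * np.expm1(np.minimum(x, 0.0)))


def selu_grad(x):
    """Derivative of :func:`selu` (left derivative at 0)."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, SELU_LAMBDA,
                    SELU_LAMBDA * SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def _alpha_dropout_affine(rate: float) -> tuple[float, float]:
    """Affine correction (a, b) restoring zero mean / unit variance."""
    q = 1.0 - rate
    ap = SELU_SATURATION
    a = (q + ap * ap * q * (1.0 - q)) ** -0.5
    b = -a * (1.0 - q) * ap
    return a, b


def alpha_dropout(x, rate: float, training: bool = True,
                  rng: np.random.Generator | None = None):
    """Dropout for SELU activations.

    In training mode, units are set to the SELU negative saturation value with
    probability ``rate``; an affine correction then restores zero mean and
    unit variance in expectation. In evaluation mode (or at rate 0) this is
    the identity.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    x = np.asarray(x, dtype=float)
    if not training or rate == 0.0:
        return x
    if rng is None:
        rng = np.random.default_rng()
    keep = rng.random(x.shape) >= rate
    a, b = _alpha_dropout_affine(rate)
    return a * np.where(keep, x, SELU_SATURATION) + b


@dataclass(frozen=True)
class LayerSpec:
    """One fully-connected layer: output width, activation, dropout rate."""

    width: int
    activation: str = "selu"  # "selu" or "linear"
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("layer width must be >= 1")
        if self.activation not in ("selu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class MLP:
    """Fully-connected network with SELU/alpha-dropout layers.

    Weights follow the LeCun-normal contract (std = 1/sqrt(fan_in), zero
    biases), the initialization under which SELU self-normalization holds.
    ``forward`` returns a cache for ``backward``, which computes parameter
    gradients and the gradient with respect to the input.
    """

    def __init__(self, in_dim: int, specs: list[LayerSpec],
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng()
        self.in_dim = in_dim
        self.specs = list(specs)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        fan_in = in_dim
        for spec in self.specs:
            self.weights.append(rng.normal(0.0, fan_in ** -0.5,
                                           size=(fan_in, spec.width)))
            self.biases.append(np.zeros(spec.width))
            fan_in = spec.width

    @property
    def out_dim(self) -> int:
        return self.specs[-1].width

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Run the network; returns ``(output, cache)``.

        Deterministic in evaluation mode. Raises on input-width mismatch,
        naming the offending layer.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = X
        cache = {"inputs": [], "pre": [], "keeps": [], "training": training}
        for i, spec in enumerate(self.specs):
            if out.shape[1] != self.weights[i].shape[0]:
                raise ValueError(
                    f"layer {i}: input width {out.shape[1]} does not match "
                    f"weight shape {self.weights[i].shape}")
            cache["inputs"].append(out)
            z = out @ self.weights[i] + self.biases[i]
            cache["pre"].append(z)
            h = selu(z) if spec.activation == "selu" else z
            if training and spec.dropout_rate > 0.0:
                if rng is None:
                    rng = np.random.default_rng()
                keep = rng.random(h.shape) >= spec.dropout_rate
                a, b = _alpha_dropout_affine(spec.dropout_rate)
                h = a * np.where(keep, h, SELU_SATURATION) + b
                cache["keeps"].append((keep, a))
            else:
                cache["keeps"].append(None)
            out = h
        return out, cache

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)[0]

    def backward(self, cache, grad_out: np.ndarray):
        """Backpropagate ``grad_out`` (dL/d output) through the cached pass.

        Returns ``(param_grads, grad_input)`` where ``param_grads`` is a list
        of ``(dW, db)`` per layer.
        """
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.specs)
        g = np.atleast_2d(np.asarray(grad_out, dtype=float))
        for i in range(len(self.specs) - 1, -1, -1):
            keep = cache["keeps"][i]
            if keep is not None:
                mask, a = keep
                g = g * (a * mask)
            if self.specs[i].activation == "selu":
                g = g * selu_grad(cache["pre"][i])
            grads[i] = (cache["inputs"][i].T @ g, g.sum(axis=0))
            g = g @ self.weights[i].T
        return grads, g

    # --- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            p[...] = s


def mlp_forward(specs: list[LayerSpec], weights: list[tuple[np.ndarray, np.ndarray]],
                x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Functional forward pass: affine -> selu -> alpha-dropout per layer.

    ``weights`` is a list of ``(W, b)`` pairs conforming to ``specs``.
    """
    net = MLP.__new__(MLP)
    net.in_dim = np.atleast_2d(x).shape[1]
    net.specs = list(specs)
    net.weights = [np.asarray(W, dtype=float) for W, _ in weights]
    net.biases = [np.asarray(b, dtype=float) for _, b in weights]
    return net.forward(x, training=training, rng=rng)[0]


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
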