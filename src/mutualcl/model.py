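"""A small fully-connected softmax classifier with hand-derived gradients.

The backbone is deliberately tiny — flattened pixels, one or two hidden
ReLU layers, a linear classifier head — so the whole incremental protocol
runs in seconds on one CPU.  The head can be widened in place when new
classes arrive: existing columns (and therefore existing class logits)
are preserved bit for bit, new columns are freshly initialized.

Gradients are analytic (manual backprop); the optimizer is ADADELTA in
its original formulation (per-parameter accumulators of squared
gradients and squared updates, rho=0.95, eps=1e-6), matching the
training protocol the objective was published with.  Both the model and
the optimizer are plain numpy, fully deterministic given a seed.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = ["SoftmaxMLP", "Adadelta"]


class SoftmaxMLP:
    """Flatten -> [Linear+ReLU]* -> Linear head producing class logits."""

    def __init__(
        self,
        input_dim: int,
        n_classes: int,
        hidden_dims: Sequence[int] = (64,),
        seed: int = 0,
    ) -> None:
        if input_dim < 1 or n_classes < 1:
            raise ValidationError("input_dim and n_classes must be >= 1")
        self.input_dim = int(input_dim)
        self.hidden_dims = tuple(int(h) for h in hidden_dims)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        dims = [self.input_dim, *self.hidden_dims, int(n_classes)]
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            # He initialization for the ReLU stack; the head reuses it.
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._head_rng = rng
        self.trained = False

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (logits, cache of layer inputs) for a batch of flat inputs."""
        a = np.atleast_2d(np.asarray(x, dtype=float))
        if a.shape[1] != self.input_dim:
            raise ValidationError(
                f"input dim {a.shape[1]} != model input dim {self.input_dim}"
            )
        cache = [a]
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if i < n_layers - 1:
                a = np.maximum(a, 0.0)
            cache.append(a)
        return a, cache

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Top-1 class indices (argmax of logits; temperature-invariant)."""
        return np.argmax(self.logits(x), axis=1)

    def backward(self, cache: list[np.ndarray], d_logits: np.ndarray) -> list[np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(logits), in parameter order."""
        grads_w: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        delta = np.asarray(d_logits, dtype=float)
        for i in range(len(self.weights) - 1, -1, -1):
            a_in = cache[i]
            grads_w[i] = a_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                delta = delta * (cache[i] > 0)  # ReLU mask
        out: list[np.ndarray] = []
        for gw, gb in zip(grads_w, grads_b):
            out.extend((gw, gb))
        return out

    def widen_head(self, n_new: int) -> None:
        """Append freshly initialized columns for ``n_new`` classes.

        Pre-existing logit columns are untouched, so predictions for old
        classes are bitwise identical before any further training.
        """
        if n_new < 0:
            raise ValidationError("n_new must be >= 0")
        if n_new == 0:
            return
        fan_in = self.weights[-1].shape[0]
        extra = self._head_rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, n_new))
        self.weights[-1] = np.concatenate([self.weights[-1], extra], axis=1)
        self.biases[-1] = np.concatenate([self.biases[-1], np.zeros(n_new)])

    def copy(self) -> "SoftmaxMLP":
        return copy.deepcopy(self)


class Adadelta:
    """ADADELTA: adaptive per-parameter steps without a hand-set learning rate.

    update:  E[g^2] <- rho E[g^2] + (1-rho) g^2
             dx = - sqrt(E[dx^2]+eps) / sqrt(E[g^2]+eps) * g
             E[dx^2] <- rho E[dx^2] + (1-rho) dx^2
    """

    def __init__(self, params: Sequence[np.ndarray], rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        self.rho = float(rho)
        self.eps = float(eps)
        self.lr = float(lr)
        self._acc_g = [np.zeros_like(p) for p in params]
        self._acc_dx = [np.zeros_like(p) for p in params]

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        for p, g, ag, ad in zip(params, grads, self._acc_g, self._acc_dx):
            ag *= self.rho
            ag += (1.0 - self.rho) * g * g
            dx = -np.sqrt(ad + self.eps) / np.sqrt(ag + self.eps) * g
            ad *= self.rho
            ad += (1.0 - self.rho) * dx * dx
            p += self.lr * dx
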