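"""Small dense feed-forward networks with hand-written differentiation.

Supports exactly what the potential needs:

* batched forward evaluation,
* exact gradients of the scalar output(s) with respect to the inputs
  (for forces),
* gradients of the loss with respect to the weights, including the
  double-backprop term required when the loss contains input-gradients
  (force-matching), implemented via a forward tangent pass followed by a
  reverse pass over the combined computation,
* Adam updates.

Activation is tanh (smooth, bounded derivatives of all orders).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected net: dims[0] -> hidden ... -> dims[-1], tanh hidden."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.dims = tuple(int(d) for d in dims)
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for d_in, d_out in zip(self.dims[:-1], self.dims[1:]):
            scale = np.sqrt(2.0 / (d_in + d_out))
            self.weights.append(scale * rng.standard_normal((d_out, d_in)))
            self.biases.append(np.zeros(d_out))

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    @property
    def n_out(self) -> int:
        return self.dims[-1]

    def parameters(self) -> List[np.ndarray]:
        return self.weights + self.biases

    def copy(self) -> "MLP":
        clone = MLP.__new__(MLP)
        clone.dims = self.dims
        clone.weights = [w.copy() for w in self.weights]
        clone.biases = [b.copy() for b in self.biases]
        return clone

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray):
        """Return (output (B, n_out), activations cache)."""
        a = np.asarray(x, dtype=float)
        acts = [a]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w.T + b)
            acts.append(a)
        out = a @ self.weights[-1].T + self.biases[-1]
        return out, acts

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    # -- input gradients --------------------------------------------------

    def input_grad(self, acts: List[np.ndarray], out_index: int = 0) -> np.ndarray:
        """d out[:, out_index] / d input, shape (B, dims[0])."""
        u = np.broadcast_to(
            self.weights[-1][out_index], (acts[0].shape[0], self.dims[-2])
        ).copy()
        for layer in range(self.n_hidden - 1, -1, -1):
            a = acts[layer + 1]
            u = ((1.0 - a * a) * u) @ self.weights[layer]
        return u

    # -- tangent (JVP) pass ----------------------------------------------

    def tangent(self, acts: List[np.ndarray], c: np.ndarray):
        """Directional derivative of the outputs along input direction ``c``.

        Returns (S (B, n_out), tangent cache).  ``t_inputs[l]`` is the
        tangent entering layer ``l`` (``t_inputs[0]`` is ``c`` itself).
        """
        t = np.asarray(c, dtype=float)
        t_inputs = [t]
        s_list = []
        for layer in range(self.n_hidden):
            s = t @ self.weights[layer].T
            a = acts[layer + 1]
            t = (1.0 - a * a) * s
            s_list.append(s)
            t_inputs.append(t)
        s_out = t @ self.weights[-1].T
        return s_out, (s_list, t_inputs)

    # -- reverse pass over forward (+ optional tangent) graph -------------

    def backward(
        self,
        acts: List[np.ndarray],
        d_out: np.ndarray,
        tangent_cache=None,
        d_s_out: Optional[np.ndarray] = None,
    ) -> Tuple[List[np.ndarray], List[np.ndarray]]:
        """Weight/bias gradients of  sum(d_out * out) + sum(d_s_out * S).

        ``tangent_cache`` / ``d_s_out`` supply the double-backprop
        (force-loss) contribution; pass None for energy-only training.
        """
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        with_tangent = tangent_cache is not None
        s_list, t_inputs = tangent_cache if with_tangent else (None, None)

        d_a = d_out @ self.weights[-1]
        grads_w[-1] = d_out.T @ acts[-1]
        grads_b[-1] = d_out.sum(axis=0)
        d_t = None
        if with_tangent:
            d_t = d_s_out @ self.weights[-1]
            grads_w[-1] += d_s_out.T @ t_inputs[-1]
        for layer in range(self.n_hidden - 1, -1, -1):
            a = acts[layer + 1]
            sigp = 1.0 - a * a
            if with_tangent:
                d_s = sigp * d_t
                # sigma''(z) = -2 a sigma'(z), expressed via the activation
                d_z = (-2.0 * a * sigp) * s_list[layer] * d_t + sigp * d_a
                grads_w[layer] += d_z.T @ acts[layer] + d_s.T @ t_inputs[layer]
                d_t = d_s @ self.weights[layer]
            else:
                d_z = sigp * d_a
                grads_w[layer] += d_z.T @ acts[layer]
            grads_b[layer] += d_z.sum(axis=0)
            d_a = d_z @ self.weights[layer]
        return grads_w, grads_b


class Adam:
    """Plain Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, params: List[np.ndarray], lr: float = 5e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
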