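"""Dense neural layers on the numpy autodiff engine.

A small MLP maps medium descriptors (uptake bounds or binary compositions)
to an initial flux vector for the mechanistic layer. Weights use He
initialization; dropout uses inverted scaling and is disabled at inference.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["DenseNet"]


class DenseNet:
    """MLP with rectified hidden layers and a configurable output activation.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths, input first, output last.
    dropout : float
        Dropout fraction applied after each hidden activation during
        training.
    output_activation : {"relu", "linear"}
        A rectified output keeps predicted fluxes nonnegative.
    """

    def __init__(self, sizes, dropout=0.0, output_activation="relu", seed=0):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.dropout = float(dropout)
        self.output_activation = output_activation
        rng = np.random.default_rng(seed)
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(Tensor(W, requires_grad=True))
            self.biases.append(Tensor(np.zeros((1, fan_out)),
                                      requires_grad=True))
        self.frozen = False

    @property
    def params(self):
        return [] if self.frozen else self.weights + self.biases

    def freeze(self):
        for p in self.weights + self.biases:
            p.requires_grad = False
        self.frozen = True

    def checksum(self) -> float:
        """Order-sensitive digest of all parameters (immutability checks)."""
        return float(sum(np.sum(p.data * (i + 1))
                         for i, p in enumerate(self.weights + self.biases)))

    def forward(self, X: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                h = h.relu()
                if training and self.dropout > 0:
                    if rng is None:
                        raise ValueError("dropout needs an rng when training")
                    keep = 1.0 - self.dropout
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * Tensor(mask)
            elif self.output_activation == "relu":
                h = h.relu()
        return h

    def state(self) -> dict:
        return {f"W{i}": w.data.copy() for i, w in enumerate(self.weights)} | \
               {f"b{i}": b.data.copy() for i, b in enumerate(self.biases)}

    def load_state(self, state: dict) -> None:
        for i, w in enumerate(self.weights):
            w.data = np.asarray(state[f"W{i}"], dtype=float).copy()
        for i, b in enumerate(self.biases):
            b.data = np.asarray(state[f"b{i}"], dtype=float).copy()
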