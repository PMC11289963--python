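"""Minimal 1 x k self-organizing map for embedding quantization.

Prototypes live on a 1D grid; training is the classic online rule with a
Gaussian neighborhood whose width and learning rate decay linearly over a
fixed number of iterations.  Deterministic per seed.
"""

from __future__ import annotations

import numpy as np


class SOM1D:
    """Self-organizing map with a 1 x k prototype grid.

    Parameters
    ----------
    k : number of prototypes (domains).
    n_iter : online updates (default 10,000).
    learning_rate : initial learning rate, decaying linearly to ~0.
    sigma : initial Gaussian neighborhood width on the prototype grid;
        defaults to k / 2, decaying linearly to a floor of 0.01.
    seed : RNG seed (prototype initialization from data rows + sample order).
    """

    def __init__(
        self,
        k: int,
        n_iter: int = 10_000,
        learning_rate: float = 0.5,
        sigma: float | None = None,
        seed: int = 0,
    ):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.sigma = k / 2.0 if sigma is None else sigma
        self.seed = seed
        self.prototypes: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "SOM1D":
        x = np.asarray(x, dtype=float)
        if len(x) < self.k:
            raise ValueError("need at least k samples to fit a 1 x k map")
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), self.k]))
        init_idx = rng.choice(len(x), size=self.k, replace=False)
        proto = x[init_idx].copy()
        grid = np.arange(self.k, dtype=float)
        order = rng.integers(0, len(x), size=self.n_iter)
        for t, i in enumerate(order):
            frac = 1.0 - t / self.n_iter
            lr = self.learning_rate * frac
            sig = max(self.sigma * frac, 0.01)
            xi = x[i]
            bmu = int(np.argmin(((proto - xi) ** 2).sum(axis=1)))
            h = np.exp(-((grid - bmu) ** 2) / (2.0 * sig**2))
            proto += lr * h[:, None] * (xi - proto)
        self.prototypes = proto
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Index of the best-matching prototype per row."""
        x = np.asarray(x, dtype=float)
        d2 = ((x[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def quantization_error(self, x: np.ndarray) -> float:
        """Mean Euclidean distance of samples to their best-matching prototype."""
        x = np.asarray(x, dtype=float)
        d2 = ((x[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min(axis=1)).mean())
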