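"""A single fuzzy ART module: complement coding, choice-by-difference
activation, vigilance-gated search, fast-commit/slow-recode learning.

The module clusters feature vectors in [0, 1]^M unsupervised.  Inputs are
complement coded to 2M components with constant L1 norm M.  Committed
coding cells compete through the choice-by-difference (CBD) function; the
vigilance threshold rho decides whether the best-matching cell recodes
toward the input (slow, beta = 0.1) or a fresh cell is committed (fast,
beta = 1, so the new weight column equals the input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FuzzyARTParams",
    "FuzzyARTModule",
    "CapacityError",
    "complement_code",
    "match",
]


class CapacityError(RuntimeError):
    """Raised when a new commit would exceed the module's cell budget."""


@dataclass(frozen=True)
class FuzzyARTParams:
    alpha: float = 0.01  # CBD prior on existing representations
    rho: float = 0.65  # vigilance
    beta_commit: float = 1.0  # learning rate on first commit
    beta_recode: float = 0.1  # learning rate on subsequent updates
    c_max: int = 512  # maximum committable coding cells

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("vigilance rho must be in [0, 1]")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")


def complement_code(m: np.ndarray) -> np.ndarray:
    """x = (m, 1 - m); doubles the length, fixes ||x||_1 = M exactly."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 1:
        raise ValueError("expected a 1-D feature vector")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("features must lie in [0, 1]")
    return np.concatenate([m, 1.0 - m])


def match(x: np.ndarray, w: np.ndarray) -> float:
    """Match score Gamma = ||x ^ w||_1 / ||x||_1 (fuzzy AND = min)."""
    x = np.asarray(x, dtype=float)
    norm = np.abs(x).sum()
    if norm == 0:
        raise ValueError("zero-norm input")
    return float(np.minimum(x, w).sum() / norm)


class FuzzyARTModule:
    """One fuzzy ART network over M input features.

    The weight matrix is held at its full 2M x c_max extent with
    uncommitted columns at 1, matching the textbook initialization; only
    the first ``C`` columns are committed.
    """

    def __init__(self, M: int, params: FuzzyARTParams):
        if M < 1:
            raise ValueError("M must be >= 1")
        self.M = M
        self.params = params
        self.W = np.ones((2 * M, params.c_max))
        self.C = 0

    @property
    def weights(self) -> np.ndarray:
        """Committed weight columns, shape (2M, C)."""
        return self.W[:, : self.C]

    def choice_activation(self, x: np.ndarray) -> np.ndarray:
        """CBD activation T_j = ||x ^ w_j||_1 + (1 - alpha)(M - ||w_j||_1).

        Empty (length-0) when no cells are committed yet.
        """
        w = self.weights
        minsum = np.minimum(x[:, None], w).sum(axis=0)
        return minsum + (1.0 - self.params.alpha) * (self.M - w.sum(axis=0))

    def _search(self, x: np.ndarray):
        """ART search: (winner index, is_new_commit). Does not learn."""
        if self.C > 0:
            w = self.weights
            minsum = np.minimum(x[:, None], w).sum(axis=0)
            t = minsum + (1.0 - self.params.alpha) * (self.M - w.sum(axis=0))
            gamma = minsum / self.M  # ||x||_1 = M after complement coding
            # descending T, ties broken toward the earliest-committed cell
            for j in np.argsort(-t, kind="stable"):
                if gamma[j] >= self.params.rho:
                    return int(j), False
        if self.C >= self.params.c_max:
            raise CapacityError(
                f"all {self.params.c_max} coding cells committed and none match"
            )
        return self.C, True

    def train_step(self, x: np.ndarray) -> tuple[int, bool]:
        """Present one complement-coded sample; learn; return (winner, new)."""
        j, new = self._search(x)
        beta = self.params.beta_commit if new else self.params.beta_recode
        self.W[:, j] = beta * np.minimum(x, self.W[:, j]) + (1 - beta) * self.W[:, j]
        if new:
            self.C += 1
        return j, new

    def batch_activation(self, X: np.ndarray) -> np.ndarray:
        """CBD activations for a batch, shape (n_samples, C)."""
        if self.C == 0:
            raise RuntimeError("module has no committed cells")
        w = self.weights
        bias = (1.0 - self.params.alpha) * (self.M - w.sum(axis=0))
        # chunk the (samples x 2M x C) broadcast to bound peak memory
        step = max(1, int(2e7 // max(w.size, 1)))
        out = np.empty((len(X), self.C))
        for i in range(0, len(X), step):
            out[i : i + step] = np.minimum(
                X[i : i + step, :, None], w[None, :, :]
            ).sum(axis=1)
        return out + bias

    def output(self, x: np.ndarray, mode: str = "softmax") -> np.ndarray:
        """Prediction output: softmax(T) (hidden layers) or raw T (output layer)."""
        if self.C == 0:
            raise RuntimeError("module has no committed cells")
        t = self.choice_activation(x)
        return _apply_mode(t, mode)


def _apply_mode(t: np.ndarray, mode: str) -> np.ndarray:
    if mode == "identity":
        return t
    if mode == "softmax":
        z = t - t.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown output mode {mode!r}")
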