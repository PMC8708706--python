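"""Hebbian (Sanger's rule) baseline with the same hierarchical structure.

Each module runs the generalized Hebbian algorithm, whose weight rows
converge to the leading principal components of its input.  A baseline
network is built to match a trained fuzzy ART network: same MT feature
partition and grid, with every module in a layer given C_mean neurons, the
rounded mean committed-cell count of the corresponding fuzzy ART layer.
Unlike fuzzy ART's one-pass learning, each Sanger module iterates epochs
until its weight matrix stops changing (Frobenius norm < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SangerModule",
    "sanger_epoch",
    "train_to_convergence",
    "HebbianNetwork",
    "build_matched_network",
    "logistic",
]


def logistic(x):
    """f(x) = 1 / (1 + exp(-x)); keeps prediction-time outputs in (0, 1)."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SangerModule:
    """One Sanger's-rule module: weights (n_units x n_features)."""

    weights: np.ndarray
    learning_rate: float = 0.01
    tol: float = 0.01  # Frobenius-norm convergence threshold
    max_epochs: int = 200
    n_epochs_run: int = 0
    converged: bool = False

    @classmethod
    def init(cls, n_units: int, n_features: int, rng: np.random.Generator, **kw):
        w = rng.uniform(-0.01, 0.01, size=(n_units, n_features))
        return cls(weights=w, **kw)

    def output(self, X: np.ndarray) -> np.ndarray:
        """Raw linear outputs y = W x, shape (n_samples, n_units)."""
        return np.atleast_2d(X) @ self.weights.T


def sanger_epoch(samples: np.ndarray, module: SangerModule) -> SangerModule:
    """One pass of the generalized Hebbian update over the samples.

    Per sample: y = W x; dW = eta * (y x^T - LT(y y^T) W), LT = lower
    triangular (including the diagonal).
    """
    W = module.weights
    eta = module.learning_rate
    for x in np.atleast_2d(samples):
        y = W @ x
        W += eta * (np.outer(y, x) - np.tril(np.outer(y, y)) @ W)
    module.n_epochs_run += 1
    return module


def train_to_convergence(samples: np.ndarray, module: SangerModule) -> SangerModule:
    """Repeat epochs until successive weight matrices differ by < tol."""
    import warnings

    for _ in range(module.max_epochs):
        prev = module.weights.copy()
        sanger_epoch(samples, module)
        if np.linalg.norm(module.weights - prev) < module.tol:
            module.converged = True
            return module
    warnings.warn(
        f"Sanger module did not converge within {module.max_epochs} epochs",
        RuntimeWarning,
    )
    return module


class HebbianNetwork:
    """Hierarchical Sanger network matched to a trained ARTFLOW network."""

    def __init__(self, artflow_net, seed: int = 0):
        from .network import ARTFLOWNetwork  # noqa: F401  (type reference)

        artflow_net._check_trained()
        self.partition = artflow_net.partition
        self.configs = artflow_net.configs
        self.fan_ins = artflow_net.fan_ins
        self.c_mean = [
            max(1, int(round(np.mean(list(artflow_net.committed_counts(l).values())))))
            for l in range(len(artflow_net.configs))
        ]
        self.seed = seed
        self.layers: list[dict] = []
        self.trained = False

    def _layer_inputs(self, layer: int, features: np.ndarray, outputs: list):
        if layer == 0:
            return {k: features[:, idx] for k, idx in self.partition.indices.items()}
        blocks = self.fan_ins[layer - 1]
        prev = outputs[layer - 1]
        return {
            key: np.concatenate([prev[src] for src in blocks[key]], axis=1)
            for key in sorted(blocks)
        }

    def fit(self, responses: np.ndarray):
        """Train each layer's modules to convergence, layer by layer.

        Each module's Sanger update runs on its raw linear outputs, but the
        signal passed to the next layer is logistic-transformed in training
        as at prediction: the generalized Hebbian update is only stable for
        learning rates below 1/lambda_max of the input covariance, and raw
        linear inter-layer signals have unbounded variance, which makes the
        fixed 0.01 learning rate diverge in the second layer.
        """
        responses = np.asarray(responses, dtype=float)
        rng = np.random.default_rng(self.seed)
        self.layers = []
        outputs: list[dict] = []
        for l in range(len(self.configs)):
            inputs = self._layer_inputs(l, responses, outputs)
            modules = {}
            outs = {}
            for key in sorted(inputs):
                X = inputs[key]
                n_units = min(self.c_mean[l], X.shape[1])
                mod = SangerModule.init(n_units, X.shape[1], rng)
                train_to_convergence(X, mod)
                modules[key] = mod
                outs[key] = logistic(mod.output(X))
            self.layers.append(modules)
            outputs.append(outs)
        self.trained = True
        return self

    def predict(self, responses: np.ndarray) -> np.ndarray:
        """Top-layer activations; every layer output passes the logistic."""
        if not self.trained:
            raise RuntimeError("network has not been trained")
        responses = np.atleast_2d(np.asarray(responses, dtype=float))
        outputs: list[dict] = []
        for l in range(len(self.configs)):
            inputs = self._layer_inputs(l, responses, outputs)
            outputs.append(
                {k: logistic(self.layers[l][k].output(inputs[k])) for k in sorted(inputs)}
            )
        top = outputs[-1]
        return np.concatenate([top[key] for key in sorted(top)], axis=1)


def build_matched_network(artflow_net, seed: int = 0) -> HebbianNetwork:
    """Untrained Hebbian network with the grid/partition/C_mean of the source."""
    return HebbianNetwork(artflow_net, seed=seed)
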