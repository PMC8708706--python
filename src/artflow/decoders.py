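"""Linear and MLP decoders of self-motion parameters from MSTd activations.

Both decoders are small regression networks trained with Adam on
mean-squared error over standardized features and labels, with early
stopping (patience 5) on a held-out 20% validation split.  The linear
decoder has no hidden layer; the nonlinear decoder is a single-hidden-layer
MLP (250 ReLU units).  Reported errors are mean absolute errors in the
original units: degrees for heading, deg/s for rotation rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

__all__ = [
    "DecoderSpec",
    "Standardizer",
    "TrainedDecoder",
    "EvalReport",
    "fit_decoder",
    "evaluate",
    "HEADING_COLS",
    "ROTATION_COLS",
]

HEADING_COLS = ("azimuth_deg", "elevation_deg")
ROTATION_COLS = ("pitch_dps", "yaw_dps", "roll_dps")


@dataclass(frozen=True)
class DecoderSpec:
    kind: str = "linear"  # {"linear", "mlp"}
    hidden_units: int = 250
    patience: int = 5
    max_epochs: int = 500
    val_fraction: float = 0.2
    batch_size: int = 32  # MLP only
    learning_rate: float = 1e-3
    # The linear decoder is full-batch (one gradient step per epoch versus
    # the MLP's n/32), so it gets a larger step size and epoch budget to
    # reach the least-squares solution before early stopping.
    linear_learning_rate: float = 1e-2
    linear_max_epochs: int = 2000


class Standardizer:
    """Z-score transform fitted on the training split; epsilon-guarded so
    zero-variance columns pass through unscaled."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd < 1e-12, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd_ + self.mean_


def _adam_linear(X, Y, Xv, Yv, spec: DecoderSpec):
    """Full-batch Adam on MSE for an affine map; early stops on val loss."""
    n, d = X.shape
    k = Y.shape[1]
    W = np.zeros((d, k))
    b = np.zeros(k)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = spec.linear_learning_rate
    best = (np.inf, W.copy(), b.copy())
    bad = 0
    for t in range(1, spec.linear_max_epochs + 1):
        r = X @ W + b - Y
        gW = 2.0 * X.T @ r / n
        gb = 2.0 * r.mean(axis=0)
        mW = b1 * mW + (1 - b1) * gW; vW = b2 * vW + (1 - b2) * gW**2
        mb = b1 * mb + (1 - b1) * gb; vb = b2 * vb + (1 - b2) * gb**2
        c1, c2 = 1 - b1**t, 1 - b2**t
        W -= lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
        b -= lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
        val = float(np.mean((Xv @ W + b - Yv) ** 2))
        if val < best[0] - 1e-12:
            best = (val, W.copy(), b.copy())
            bad = 0
        else:
            bad += 1
            if bad >= spec.patience:
                break
    return best[1], best[2]


@dataclass
class TrainedDecoder:
    spec: DecoderSpec
    x_std: Standardizer
    y_std: Standardizer
    _predict_std: object = field(repr=False)  # standardized-space predictor

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.x_std.transform(np.atleast_2d(X))
        return self.y_std.inverse(self._predict_std(Z))


def fit_decoder(
    features: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    seed: int = 0,
) -> TrainedDecoder:
    """Fit a decoder on (n_samples x n_features) activations and labels.

    Labels are (az, el) for heading or (az, el, pitch, yaw, roll) for
    heading + rotation; both features and labels are standardized
    internally and predictions are returned in original units.
    """
    spec = spec or DecoderSpec()
    X = np.asarray(features, dtype=float)
    Y = np.atleast_2d(np.asarray(labels, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    x_std = Standardizer().fit(X)
    y_std = Standardizer().fit(Y)
    Xs, Ys = x_std.transform(X), y_std.transform(Y)
    if spec.kind == "linear":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(Xs))
        n_val = max(1, int(round(spec.val_fraction * len(Xs))))
        vi, ti = idx[:n_val], idx[n_val:]
        if len(ti) == 0:
            ti = vi
        W, b = _adam_linear(Xs[ti], Ys[ti], Xs[vi], Ys[vi], spec)
        predict = lambda Z: Z @ W + b
    elif spec.kind == "mlp":
        mlp = MLPRegressor(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="relu",
            solver="adam",
            batch_size=spec.batch_size,
            learning_rate_init=spec.learning_rate,
            max_iter=spec.max_epochs,
            early_stopping=True,
            validation_fraction=spec.val_fraction,
            n_iter_no_change=spec.patience,
            random_state=int(seed) % (2**32),
        )
        mlp.fit(Xs, Ys if Ys.shape[1] > 1 else Ys.ravel())
        predict = lambda Z: np.atleast_2d(mlp.predict(Z).T).T
    else:
        raise ValueError(f"unknown decoder kind {spec.kind!r}")
    return TrainedDecoder(spec=spec, x_std=x_std, y_std=y_std, _predict_std=predict)


@dataclass
class EvalReport:
    """Heading MAE pools absolute errors over azimuth and elevation."""

    heading_mae: float
    rotation_mae: dict
    per_sample_errors: np.ndarray  # (n_samples, n_outputs) absolute errors

    def as_dict(self) -> dict:
        d = {"heading_mae_deg": self.heading_mae}
        d.update({f"{k}_mae_dps": v for k, v in self.rotation_mae.items()})
        return d


def evaluate(decoder: TrainedDecoder, features: np.ndarray, labels: np.ndarray) -> EvalReport:
    """MAE of decoder predictions in original units (deg, deg/s)."""
    Y = np.atleast_2d(np.asarray(labels, dtype=float))
    pred = decoder.predict(features)
    err = np.abs(pred - Y)
    heading_mae = float(err[:, :2].mean())
    rotation = {}
    if Y.shape[1] >= 5:
        for i, name in enumerate(("pitch", "yaw", "roll")):
            rotation[name] = float(err[:, 2 + i].mean())
    return EvalReport(heading_mae=heading_mae, rotation_mae=rotation,
                      per_sample_errors=err)
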