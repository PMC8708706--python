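"""Generative pass: reconstruct optic flow from template activations.

Template activations are propagated backward through the network: each
layer's weight columns are inverted out of complement coding by taking the
midpoint of their fuzzy box ("defuzz"), activation-weighted sums produce
estimates of the layer below, and the reconstructed MT activation pattern
is finally turned into a sparse flow field by population-vector decoding
(circular mean of preferred directions; activation-weighted geometric mean
of preferred speeds, matching the log-normal speed tuning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowFrame, FlowSequence
from .mt import MTPopulation

__all__ = [
    "Reconstruction",
    "defuzz",
    "backproject",
    "decode_flow",
    "reconstruction_error",
    "fit_foe",
]


def defuzz(w: np.ndarray, M: int) -> np.ndarray:
    """Midpoint of the fuzzy box coded by a 2M weight column.

    For a freshly committed column w = (m, 1-m) this returns m exactly.
    """
    w = np.asarray(w, dtype=float)
    if w.shape[-1] != 2 * M:
        raise ValueError("weight column length must be 2M")
    return 0.5 * (w[..., :M] + (1.0 - w[..., M:]))


def backproject(a: np.ndarray, net) -> np.ndarray:
    """MT-level activation estimate from top-layer (MSTd) activations.

    ``a`` is normalized to sum 1; the layer-1 activation estimate is the
    activation-weighted sum of defuzzed template columns; within each
    layer-1 module the (renormalized) cell activations weight the defuzzed
    layer-1 columns to produce the MT estimate.  Supports the two-layer
    network shape.
    """
    net._check_trained()
    a = np.asarray(a, dtype=float).ravel()
    top = net.top_module
    if len(a) != top.C:
        raise ValueError(f"expected {top.C} template activations, got {len(a)}")
    total = a.sum()
    if total <= 0:
        raise ValueError("zero total template activation")
    a = a / total
    # layer-1 activation estimate over the concatenated module outputs
    templ = defuzz(top.weights.T, top.M)  # (C_top, M_top)
    layer1_est = a @ templ
    _, spans = net.get_templates()
    mt_est = np.zeros(net.population.n)
    for (key, start, stop) in spans:
        mod = net.layers[0][key]
        ahat = layer1_est[start:stop]
        s = ahat.sum()
        if s <= 0:
            continue
        ahat = ahat / s
        feats = defuzz(mod.weights.T, mod.M)  # (C_k, M_k)
        mt_est[net.partition.indices[key]] = ahat @ feats
    return mt_est


@dataclass
class Reconstruction:
    """Sparse decoded flow field on a spatial bin grid (y-up image px)."""

    x: np.ndarray  # bin-center positions, px
    y: np.ndarray
    direction: np.ndarray  # rad
    speed: np.ndarray  # deg/s
    grid: tuple[int, int]

    def __len__(self) -> int:
        return len(self.x)


def decode_flow(
    mt_estimate: np.ndarray,
    pop: MTPopulation,
    bins: tuple[int, int] = (16, 16),
    min_resultant: float = 0.1,
) -> Reconstruction:
    """Population-vector decode of an MT activation pattern onto a bin grid.

    Per bin: direction = atan2(sum m sin theta_pref, sum m cos theta_pref)
    over neurons whose RF center falls in the bin; speed = exp of the
    activation-weighted mean log preferred speed.  Bins with no neurons,
    zero activation mass, or a circular resultant below ``min_resultant``
    produce no vector (direction-balanced activation carries no signal).
    """
    rows, cols = bins
    cam = pop.camera
    m = np.asarray(mt_estimate, dtype=float)
    bw, bh = cam.width / cols, cam.height / rows
    cx = np.clip(((pop.x + cam.width / 2) // bw).astype(int), 0, cols - 1)
    ry = np.clip(((cam.height / 2 - pop.y) // bh).astype(int), 0, rows - 1)
    flat = ry * cols + cx
    n_bins = rows * cols
    mass = np.bincount(flat, weights=m, minlength=n_bins)
    sin_sum = np.bincount(flat, weights=m * np.sin(pop.theta_pref), minlength=n_bins)
    cos_sum = np.bincount(flat, weights=m * np.cos(pop.theta_pref), minlength=n_bins)
    log_nu = np.bincount(flat, weights=m * np.log(pop.nu_pref), minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        resultant = np.hypot(sin_sum, cos_sum) / mass
    keep = (mass > 0) & (resultant >= min_resultant)
    idx = np.flatnonzero(keep)
    r, c = idx // cols, idx % cols
    x = (c + 0.5) * bw - cam.width / 2
    y = cam.height / 2 - (r + 0.5) * bh
    direction = np.arctan2(sin_sum[idx], cos_sum[idx])
    speed = np.exp(log_nu[idx] / mass[idx])
    return Reconstruction(x=x, y=y, direction=direction, speed=speed, grid=bins)


def _wrap_angle(d):
    """Wrap angular differences to [-pi, pi]."""
    return (np.asarray(d) + np.pi) % (2 * np.pi) - np.pi


def reconstruction_error(pred: Reconstruction, truth) -> dict:
    """Angular and relative-speed error of a reconstruction against truth.

    ``truth`` may be a FlowSequence (first frame used) or a FlowFrame.
    Each predicted bin vector is compared with its nearest ground-truth
    flow vector.  Returns mean absolute angular difference (rad) and mean
    relative speed error.
    """
    if isinstance(truth, FlowSequence):
        truth = truth.frames[0]
    if len(pred) == 0 or len(truth) == 0:
        raise ValueError("empty reconstruction or truth field")
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([truth.x, truth.y]))
    _, nearest = tree.query(np.column_stack([pred.x, pred.y]))
    ang = np.abs(_wrap_angle(pred.direction - truth.direction[nearest]))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(pred.speed - truth.speed[nearest]) / truth.speed[nearest]
    return {
        "mean_angular_error_rad": float(ang.mean()),
        "mean_relative_speed_error": float(np.nanmean(rel)),
        "n_bins": len(pred),
    }


def fit_foe(recon: Reconstruction) -> tuple[float, float]:
    """Least-squares focus of expansion of a (near-)radial decoded field.

    Each flow vector constrains the FoE to its line: the perpendicular
    distance from (x0, y0) to the line through (x, y) with direction d is
    minimized over all vectors.
    """
    if len(recon) < 2:
        raise ValueError("need at least 2 vectors to fit a FoE")
    nx = -np.sin(recon.direction)
    ny = np.cos(recon.direction)
    A = np.column_stack([nx, ny])
    b = nx * recon.x + ny * recon.y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])
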