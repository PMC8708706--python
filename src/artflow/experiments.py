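"""End-to-end simulation protocol: dataset -> MT -> train -> decode -> report.

``run_pipeline`` reproduces the default experiment on one dot-defined
environment: generate the train/test flow datasets, encode them with a
shared MT population, train the fuzzy ART hierarchy for one epoch, fit the
linear and MLP decoders on the training-set MSTd activations, and report
test-set MAE.  ``stability_study`` tracks template drift over extra
training epochs; ``vigilance_sweep`` maps decoding accuracy and template
count over a (rho1, rho2) grid.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import decoders as dec
from .flow import CameraModel, DatasetSpec, generate_dataset, label_matrix
from .hebbian import build_matched_network
from .model import ARTFLOWModel
from .mt import encode_sequences
from .network import default_layer_configs, sample_partitioned_population

__all__ = [
    "ExperimentConfig",
    "PipelineData",
    "prepare_data",
    "run_pipeline",
    "stability_study",
    "vigilance_sweep",
    "DEFAULT_VIGILANCE_GRID",
]

DEFAULT_VIGILANCE_GRID = (0.0, 0.3, 0.5, 0.65, 0.75, 0.85, 0.95)


@dataclass(frozen=True)
class ExperimentConfig:
    environment: str = "cloud_T"
    n_train: int | None = None
    n_test: int | None = None
    seed: int = 0
    n_mt: int = 5000
    rho1: float = 0.65
    rho2: float = 0.85
    epochs: int = 1
    decoders: tuple[str, ...] = ("linear", "mlp")
    learners: tuple[str, ...] = ("artflow",)  # optionally + "hebbian"

    @property
    def targets(self) -> str:
        return "heading+rotation" if self.environment.endswith("TR") else "heading"

    def dataset_spec(self) -> DatasetSpec:
        return DatasetSpec(
            environment=self.environment, n_train=self.n_train,
            n_test=self.n_test, seed=self.seed,
        )


@dataclass
class PipelineData:
    """Encoded dataset shared across training runs (e.g. a vigilance sweep)."""

    config: ExperimentConfig
    population: object
    train_responses: np.ndarray
    test_responses: np.ndarray
    train_labels: np.ndarray
    test_labels: np.ndarray
    timings: dict = field(default_factory=dict)


def prepare_data(config: ExperimentConfig, progress: bool = False) -> PipelineData:
    """Generate flow datasets and encode both splits with one MT population."""
    camera = CameraModel()
    t0 = time.perf_counter()
    train, test = generate_dataset(config.dataset_spec(), camera)
    t1 = time.perf_counter()
    pop, _ = sample_partitioned_population(
        config.n_mt, camera, (8, 8), seed=config.seed + 1
    )
    train_r = encode_sequences(train, pop, progress=progress)
    test_r = encode_sequences(test, pop, progress=progress)
    t2 = time.perf_counter()
    return PipelineData(
        config=config, population=pop,
        train_responses=train_r, test_responses=test_r,
        train_labels=label_matrix(train, config.targets),
        test_labels=label_matrix(test, config.targets),
        timings={"generate_s": t1 - t0, "encode_s": t2 - t1},
    )


def _decode_report(features_tr, features_te, data: PipelineData, seed: int) -> dict:
    out = {}
    for kind in data.config.decoders:
        decoder = dec.fit_decoder(
            features_tr, data.train_labels, dec.DecoderSpec(kind=kind), seed=seed
        )
        out[kind] = dec.evaluate(decoder, features_te, data.test_labels).as_dict()
    return out


def run_pipeline(
    config: ExperimentConfig, data: PipelineData | None = None, progress: bool = False
) -> dict:
    """Full default run; returns a JSON-serializable report.

    The report has one entry per (learner, decoder) cell with heading MAE
    (and per-axis rotation MAE on the T+R environment), plus template
    counts and stage timings.
    """
    data = data or prepare_data(config, progress=progress)
    report = {"config": {k: getattr(config, k) for k in (
        "environment", "n_train", "n_test", "seed", "n_mt", "rho1", "rho2", "epochs")},
        "timings": dict(data.timings), "learners": {}}
    model = ARTFLOWModel(
        data.train_responses, data.population, labels=data.train_labels,
        layer_configs=default_layer_configs(config.rho1, config.rho2),
    )
    t0 = time.perf_counter()
    res = model.fit(epochs=config.epochs)
    t1 = time.perf_counter()
    feats_te = res.predict(data.test_responses)
    report["learners"]["artflow"] = {
        "n_templates": res.n_templates,
        "layer1_cells_mean": float(np.mean(list(res.network.committed_counts(0).values()))),
        "train_s": t1 - t0,
        "decoders": _decode_report(res.train_activations, feats_te, data, config.seed),
    }
    if "hebbian" in config.learners:
        t0 = time.perf_counter()
        heb = build_matched_network(res.network, seed=config.seed).fit(
            data.train_responses
        )
        t1 = time.perf_counter()
        report["learners"]["hebbian"] = {
            "c_mean": heb.c_mean,
            "train_s": t1 - t0,
            "decoders": _decode_report(
                heb.predict(data.train_responses),
                heb.predict(data.test_responses), data, config.seed,
            ),
        }
    report["results"] = res
    return report


def best_heading_mae(report: dict, learner: str = "artflow") -> float:
    """Lower test heading MAE across the fitted decoders."""
    decs = report["learners"][learner]["decoders"]
    return min(v["heading_mae_deg"] for v in decs.values())


def aligned_template_drift(net_a, net_b) -> float:
    """Mean absolute difference between two networks' learned templates.

    Templates are compared in defuzzed (uncoded) feature space.  Because
    extra layer-1 training epochs can commit additional layer-1 cells, the
    top module's feature vector may differ in length between runs; features
    are aligned per layer-1 module on the shared commit-order prefix, and
    templates on the shared top-layer prefix.
    """
    from .generative import defuzz

    wa, spans_a = net_a.get_templates()
    wb, spans_b = net_b.get_templates()
    fa = defuzz(wa.T, wa.shape[0] // 2)  # (C_top, M_top)
    fb = defuzz(wb.T, wb.shape[0] // 2)
    span_b = {key: (s, e) for key, s, e in spans_b}
    blocks_a, blocks_b = [], []
    for key, sa, ea in spans_a:
        sb, eb = span_b[key]
        c = min(ea - sa, eb - sb)
        if c:
            blocks_a.append(fa[:, sa : sa + c])
            blocks_b.append(fb[:, sb : sb + c])
    a = np.hstack(blocks_a)
    b = np.hstack(blocks_b)
    c_top = min(len(a), len(b))
    return float(np.mean(np.abs(a[:c_top] - b[:c_top])))


def template_contrast(net) -> float:
    """Mean absolute difference between distinct templates of one network.

    Serves as the scale against which cross-epoch drift is judged: stable
    learning means a template stays far closer to its counterpart in a
    longer run than any two distinct templates are to each other.
    """
    from .generative import defuzz

    w, _ = net.get_templates()
    f = defuzz(w.T, w.shape[0] // 2)
    c = len(f)
    if c < 2:
        return np.nan
    diffs = [
        np.mean(np.abs(f[i] - f[j])) for i in range(c) for j in range(i + 1, c)
    ]
    return float(np.mean(diffs))


def stability_study(
    config: ExperimentConfig, epochs: tuple[int, ...] = (1, 10, 100),
    data: PipelineData | None = None,
) -> dict:
    """Template snapshots and drift as the training epoch budget grows.

    Each epoch budget is an independent run from the same data and order
    (as when the training set is simply presented again).  Reports, per
    consecutive budget pair, the aligned mean absolute template change, the
    top-layer template counts, and the layer-1 committed-cell totals (which
    are non-decreasing in the budget, since a longer run extends the
    shorter one's deterministic trajectory on fixed inputs).
    """
    data = data or prepare_data(config)
    model = ARTFLOWModel(
        data.train_responses, data.population, labels=data.train_labels,
        layer_configs=default_layer_configs(config.rho1, config.rho2),
    )
    runs = {}
    for ep in sorted(epochs):
        runs[ep] = model.fit(epochs=ep)
    eps = sorted(epochs)
    drift = {
        f"{a}->{b}": aligned_template_drift(runs[a].network, runs[b].network)
        for a, b in zip(eps[:-1], eps[1:])
    }
    return {
        "epochs": eps,
        "template_counts": {e: runs[e].n_templates for e in eps},
        "layer1_cells": {
            e: sum(runs[e].network.committed_counts(0).values()) for e in eps
        },
        "drift": drift,
        "snapshots": {e: runs[e].templates for e in eps},
    }


def vigilance_sweep(
    config: ExperimentConfig,
    rho1_values: tuple[float, ...] = DEFAULT_VIGILANCE_GRID,
    rho2_values: tuple[float, ...] = DEFAULT_VIGILANCE_GRID,
    decoder: str = "mlp",
    data: PipelineData | None = None,
) -> dict:
    """Heading-MAE and template-count grids over (rho1, rho2) combinations."""
    data = data or prepare_data(config)
    mae = np.full((len(rho1_values), len(rho2_values)), np.nan)
    n_templates = np.zeros_like(mae, dtype=int)
    for i, r1 in enumerate(rho1_values):
        for j, r2 in enumerate(rho2_values):
            model = ARTFLOWModel(
                data.train_responses, data.population, labels=data.train_labels,
                layer_configs=default_layer_configs(r1, r2),
            )
            res = model.fit(epochs=config.epochs)
            n_templates[i, j] = res.n_templates
            decoder_fit = dec.fit_decoder(
                res.train_activations, data.train_labels,
                dec.DecoderSpec(kind=decoder), seed=config.seed,
            )
            mae[i, j] = dec.evaluate(
                decoder_fit, res.predict(data.test_responses), data.test_labels
            ).heading_mae
    return {
        "rho1_values": list(rho1_values), "rho2_values": list(rho2_values),
        "heading_mae": mae, "n_templates": n_templates,
        "default_cell": (0.65, 0.85),
    }
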