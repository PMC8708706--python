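"""Hierarchical grid-of-modules network: MT -> 8x8 fuzzy ART -> 1x1 MSTd.

Each fuzzy ART layer is a spatial lattice of independent modules.  A
layer-1 module receives the MT neurons whose RF centers fall in its image
sector; modules in deeper layers receive the concatenated outputs of the
block of modules that fans in to them.  Layers are trained sequentially
(train, freeze, train the next), and the weight columns of the single
top-layer (MSTd) module are the learned optic-flow templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import CameraModel
from .fuzzy_art import FuzzyARTModule, FuzzyARTParams, _apply_mode, complement_code
from .mt import MTPopulation, sample_population

__all__ = [
    "LayerConfig",
    "FeaturePartition",
    "ARTFLOWNetwork",
    "default_layer_configs",
    "partition_features",
    "sample_partitioned_population",
    "EmptySectorError",
]


@dataclass(frozen=True)
class LayerConfig:
    grid: tuple[int, int]
    rho: float
    output_mode: str = "softmax"  # "identity" for the output layer


def default_layer_configs(rho1: float = 0.65, rho2: float = 0.85) -> list[LayerConfig]:
    """The two-layer default: 8x8 grid at rho1, single MSTd module at rho2."""
    return [
        LayerConfig(grid=(8, 8), rho=rho1, output_mode="softmax"),
        LayerConfig(grid=(1, 1), rho=rho2, output_mode="identity"),
    ]


class EmptySectorError(RuntimeError):
    """A grid sector received no MT RF centers (module would have M = 0)."""


@dataclass
class FeaturePartition:
    """Assignment of MT neurons to layer-1 grid sectors.

    ``indices[(row, col)]`` lists the neuron indices whose RF center lies
    in that sector; rows count from the top of the image so that e.g. a
    pixel-grid center (10, 500) in a 512x512 image lands in the bottom-left
    module of an 8x8 grid.
    """

    grid: tuple[int, int]
    indices: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.indices.items()}


def partition_features(pop: MTPopulation, grid: tuple[int, int]) -> FeaturePartition:
    rows, cols = grid
    cam = pop.camera
    if cam.width % cols or cam.height % rows:
        raise ValueError("grid must divide the image evenly")
    sw, sh = cam.width // cols, cam.height // rows
    # image-centered y-up -> pixel-grid top-left origin
    px = pop.x + cam.width / 2
    py = cam.height / 2 - pop.y
    c = np.clip((px // sw).astype(int), 0, cols - 1)
    r = np.clip((py // sh).astype(int), 0, rows - 1)
    part = FeaturePartition(grid=grid)
    for rr in range(rows):
        for cc in range(cols):
            idx = np.flatnonzero((r == rr) & (c == cc))
            if len(idx) == 0:
                raise EmptySectorError(f"sector ({rr}, {cc}) has no MT neurons")
            part.indices[(rr, cc)] = idx
    return part


def sample_partitioned_population(
    n: int, camera: CameraModel, grid: tuple[int, int], seed: int
) -> tuple[MTPopulation, FeaturePartition]:
    """Sample an MT population, redrawing with the next seed on an empty sector."""
    for s in range(seed, seed + 64):
        pop = sample_population(n, camera, np.random.default_rng(s), seed=s)
        try:
            return pop, partition_features(pop, grid)
        except EmptySectorError:
            continue
    raise EmptySectorError(f"no non-empty partition within 64 seed redraws from {seed}")


def _fan_in(src_grid, dst_grid):
    """Map each destination module to its row-major block of source modules."""
    sr, sc = src_grid
    dr, dc = dst_grid
    if sr % dr or sc % dc:
        raise ValueError(f"grid {src_grid} does not fan in evenly to {dst_grid}")
    fr, fc = sr // dr, sc // dc
    blocks = {}
    for r in range(dr):
        for c in range(dc):
            blocks[(r, c)] = [
                (r * fr + i, c * fc + j) for i in range(fr) for j in range(fc)
            ]
    return blocks


class ARTFLOWNetwork:
    """Stack of fuzzy ART layers over an MT population.

    Parameters
    ----------
    population
        MT population providing the input features.
    layer_configs
        Grid, vigilance and output mode per layer (defaults to the
        two-layer 8x8 -> 1x1 network).
    art_params
        alpha / learning rates / cell budget shared by every module; the
        per-layer vigilance from ``layer_configs`` overrides ``rho``.
    """

    def __init__(
        self,
        population: MTPopulation,
        layer_configs: list[LayerConfig] | None = None,
        art_params: FuzzyARTParams | None = None,
    ):
        self.population = population
        self.configs = list(layer_configs or default_layer_configs())
        base = art_params or FuzzyARTParams()
        self.params = [
            FuzzyARTParams(
                alpha=base.alpha, rho=cfg.rho, beta_commit=base.beta_commit,
                beta_recode=base.beta_recode, c_max=base.c_max,
            )
            for cfg in self.configs
        ]
        self.partition = partition_features(population, self.configs[0].grid)
        self.fan_ins = [
            _fan_in(self.configs[i].grid, self.configs[i + 1].grid)
            for i in range(len(self.configs) - 1)
        ]
        # layers[l][(r, c)] -> FuzzyARTModule, populated by fit()
        self.layers: list[dict] = []
        self.trained = False

    # -- training -----------------------------------------------------------

    def _layer_inputs(self, layer: int, features: np.ndarray, outputs: list[dict]):
        """Per-module raw input matrices for ``layer`` given MT features and
        the softmax outputs of already-trained layers."""
        cfg = self.configs[layer]
        if layer == 0:
            return {
                key: features[:, idx] for key, idx in self.partition.indices.items()
            }
        blocks = self.fan_ins[layer - 1]
        prev = outputs[layer - 1]
        return {
            key: np.concatenate([prev[src] for src in blocks[key]], axis=1)
            for key in sorted(blocks)
        }

    def _module_outputs(self, layer: int, inputs: dict) -> dict:
        cfg = self.configs[layer]
        return {
            key: _apply_mode(
                self.layers[layer][key].batch_activation(
                    np.array([complement_code(x) for x in inputs[key]])
                ),
                cfg.output_mode,
            )
            for key in sorted(inputs)
        }

    def fit(self, responses: np.ndarray, epochs: int | list[int] = 1):
        """Train layers sequentially on MT response rows (one pass each by
        default); freezes each layer before training the next."""
        responses = np.asarray(responses, dtype=float)
        if responses.ndim != 2 or responses.shape[1] != self.population.n:
            raise ValueError("responses must be (n_samples, n_mt_neurons)")
        if len(responses) == 0:
            raise ValueError("empty training set")
        if np.isscalar(epochs):
            epochs = [int(epochs)] * len(self.configs)
        self.layers = []
        outputs: list[dict] = []
        for l, cfg in enumerate(self.configs):
            inputs = self._layer_inputs(l, responses, outputs)
            modules = {}
            for key in sorted(inputs):
                mod = FuzzyARTModule(M=inputs[key].shape[1], params=self.params[l])
                for _ in range(epochs[l]):
                    for x in inputs[key]:
                        mod.train_step(complement_code(x))
                modules[key] = mod
            self.layers.append(modules)
            outputs.append(self._module_outputs(l, inputs))
        self.trained = True
        return self

    # -- prediction ---------------------------------------------------------

    def _check_trained(self):
        if not self.trained:
            raise RuntimeError("network has not been trained")

    def layer1_forward(self, responses: np.ndarray) -> np.ndarray:
        """Concatenated layer-1 softmax outputs, row-major over (row, col)."""
        self._check_trained()
        responses = np.atleast_2d(np.asarray(responses, dtype=float))
        inputs = self._layer_inputs(0, responses, [])
        out = self._module_outputs(0, inputs)
        return np.concatenate([out[key] for key in sorted(out)], axis=1)

    def forward(self, responses: np.ndarray) -> np.ndarray:
        """Raw top-layer (MSTd) activations T_j, shape (n_samples, C_top)."""
        self._check_trained()
        responses = np.atleast_2d(np.asarray(responses, dtype=float))
        outputs: list[dict] = []
        for l in range(len(self.configs)):
            inputs = self._layer_inputs(l, responses, outputs)
            outputs.append(self._module_outputs(l, inputs))
        top = outputs[-1]
        return np.concatenate([top[key] for key in sorted(top)], axis=1)

    predict = forward

    # -- introspection ------------------------------------------------------

    @property
    def top_module(self) -> FuzzyARTModule:
        self._check_trained()
        return next(iter(self.layers[-1].values()))

    @property
    def n_templates(self) -> int:
        """Committed cells in the output (MSTd) module."""
        return self.top_module.C

    def committed_counts(self, layer: int) -> dict:
        self._check_trained()
        return {key: mod.C for key, mod in self.layers[layer].items()}

    def get_templates(self) -> tuple[np.ndarray, list]:
        """Top-layer weight columns plus bookkeeping slices.

        Returns ``(W, spans)`` where ``W`` is (2*M_top, C_top) and
        ``spans`` lists ``((row, col), start, stop)`` giving, for each
        layer-1 module, its sub-range within the top module's (uncoded)
        feature vector.
        """
        self._check_trained()
        spans = []
        start = 0
        for key in sorted(self.layers[0]):
            c = self.layers[0][key].C
            spans.append((key, start, start + c))
            start += c
        return self.top_module.weights.copy(), spans
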