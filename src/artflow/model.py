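"""Model/Results front end for ARTFLOW.

``ARTFLOWModel`` holds the data (MT population responses + self-motion
labels) and configuration; ``fit()`` trains the hierarchical fuzzy ART
network and returns an ``ARTFLOWResults`` object carrying the learned
templates, committed-cell diagnostics, decoder fitting/evaluation, the
generative reconstruction pass, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoders as dec
from . import generative
from .flow import CameraModel, FlowSequence, label_matrix
from .fuzzy_art import FuzzyARTParams
from .mt import MTPopulation, encode_sequences
from .network import ARTFLOWNetwork, LayerConfig, default_layer_configs

__all__ = ["ARTFLOWModel", "ARTFLOWResults"]


class ARTFLOWModel:
    """Unsupervised optic-flow template model over MT population responses.

    Parameters
    ----------
    responses
        (n_samples, n_mt_neurons) MT activation matrix in [0, 1).
    labels
        Optional (n_samples, k) self-motion labels — (az, el) or
        (az, el, pitch, yaw, roll) — used only by the decoders.
    population
        The MT population the responses were encoded with.
    layer_configs, art_params
        Network architecture and fuzzy ART hyperparameters.
    """

    def __init__(
        self,
        responses: np.ndarray,
        population: MTPopulation,
        labels: np.ndarray | None = None,
        layer_configs: list[LayerConfig] | None = None,
        art_params: FuzzyARTParams | None = None,
    ):
        self.responses = np.asarray(responses, dtype=float)
        self.labels = None if labels is None else np.asarray(labels, dtype=float)
        self.population = population
        self.layer_configs = layer_configs or default_layer_configs()
        self.art_params = art_params or FuzzyARTParams()

    @classmethod
    def from_sequences(
        cls,
        sequences: list[FlowSequence],
        population: MTPopulation,
        targets: str = "heading",
        **kwargs,
    ) -> "ARTFLOWModel":
        """Build the model from raw flow sequences (runs the MT encoding)."""
        responses = encode_sequences(sequences, population)
        labels = label_matrix(sequences, targets)
        return cls(responses, population, labels=labels, **kwargs)

    def fit(self, epochs: int | list[int] = 1) -> "ARTFLOWResults":
        """Train the network (one pass per layer by default)."""
        net = ARTFLOWNetwork(
            self.population, self.layer_configs, self.art_params
        ).fit(self.responses, epochs=epochs)
        return ARTFLOWResults(model=self, network=net)


@dataclass
class ARTFLOWResults:
    model: ARTFLOWModel
    network: ARTFLOWNetwork
    _train_activations: np.ndarray | None = field(default=None, repr=False)

    # -- estimates ----------------------------------------------------------

    @property
    def n_templates(self) -> int:
        return self.network.n_templates

    @property
    def templates(self) -> np.ndarray:
        """Learned template weight columns of the MSTd module, (2M, C_top)."""
        return self.network.get_templates()[0]

    @property
    def train_activations(self) -> np.ndarray:
        """MSTd activations of the training samples (frozen weights)."""
        if self._train_activations is None:
            self._train_activations = self.network.predict(self.model.responses)
        return self._train_activations

    def predict(self, responses: np.ndarray) -> np.ndarray:
        """MSTd activations for new MT responses; no learning occurs."""
        return self.network.predict(responses)

    # -- decoding -----------------------------------------------------------

    def fit_decoder(
        self, kind: str = "linear", labels: np.ndarray | None = None, seed: int = 0,
        spec: dec.DecoderSpec | None = None,
    ) -> dec.TrainedDecoder:
        """Fit a self-motion decoder on the training activations."""
        if labels is None:
            labels = self.model.labels
        if labels is None:
            raise ValueError("no labels available to fit a decoder")
        spec = spec or dec.DecoderSpec(kind=kind)
        return dec.fit_decoder(self.train_activations, labels, spec, seed=seed)

    # -- generative pass ----------------------------------------------------

    def reconstruct(
        self,
        activations: np.ndarray,
        bins: tuple[int, int] = (16, 16),
        sharpen: bool = True,
    ) -> generative.Reconstruction:
        """Flow field implied by a set of template activations.

        Raw MSTd activations are choice-by-difference values with a large
        common baseline; ``sharpen`` converts them to template weights with
        a softmax (mirroring the forward normalization of non-output
        layers) so the best-matching templates dominate the blend.  Pass
        ``sharpen=False`` to use the activations as convex weights as-is.
        """
        a = np.asarray(activations, dtype=float).ravel()
        if sharpen:
            a = np.exp(a - a.max())
        mt_est = generative.backproject(a, self.network)
        return generative.decode_flow(mt_est, self.model.population, bins=bins)

    def plot_templates(self, **kwargs):
        """Quiver-plot grid of the learned templates (see plotting module)."""
        from .plotting import plot_templates

        return plot_templates(self, **kwargs)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        counts1 = list(self.network.committed_counts(0).values())
        lines = [
            "ARTFLOW Results",
            "=" * 46,
            f"{'MT neurons':<32}{self.model.population.n:>14}",
            f"{'Training samples':<32}{len(self.model.responses):>14}",
        ]
        for i, cfg in enumerate(self.network.configs):
            lines.append(
                f"{'Layer %d grid / vigilance' % (i + 1):<32}"
                f"{'%dx%d / %.2f' % (*cfg.grid, cfg.rho):>14}"
            )
        lines += [
            f"{'Layer-1 committed cells (total)':<32}{sum(counts1):>14}",
            f"{'Layer-1 cells per module (mean)':<32}{np.mean(counts1):>14.1f}",
            f"{'Learned templates (MSTd)':<32}{self.n_templates:>14}",
            "=" * 46,
        ]
        return "\n".join(lines)
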