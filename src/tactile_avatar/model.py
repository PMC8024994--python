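"""Model/Results interface for fitting a personalized tactile avatar.

:class:`TactileAvatarModel` pairs a corpus of preprocessed recordings
(touch windows + sliding spectra, labelled by material) with one human
participant's per-material decision histograms, and `fit()` trains the
dual-branch network, returning an :class:`AvatarResults` carrying the
trained network, loss history, held-out evaluation split, decision
metrics (tolerance accuracy / decision error), per-material output mean
and kurtosis diagnostics, and a `summary()` table.

Typical use::

    library = build_material_library(42, seed=1)
    config = SimulationConfig(seed=2)
    participant = sample_participant("S", 42, seed=3)
    matrix = simulate_decision_matrix(participant, n_trials=20)
    model = TactileAvatarModel.from_corpus(library, config, matrix)
    res = model.fit(epochs=40, seed=4)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import decision as _decision
from .features import features_for_corpus
from .network import AvatarNetwork, NetworkSpec
from .psychophysics import (
    DecisionMatrix,
    DegenerateHistogramError,
    decision_histograms,
    histogram_kurtosis,
)

__all__ = ["TactileAvatarModel", "AvatarResults"]


def stratified_split(
    material_ids: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-material train/validation index split (default 80/20)."""
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for mid in np.unique(material_ids):
        idx = np.flatnonzero(material_ids == mid)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(val_fraction * idx.size))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


class TactileAvatarModel:
    """A participant's avatar: network + corpus + histogram targets.

    Parameters
    ----------
    touch, slide : arrays (N, 400) and (N, 500)
        Preprocessed recordings (touch window, sliding spectrum).
    material_ids : (N,) int array
        Reference rank (1..M) of each recording's material.
    target_histograms : (M, M) array
        Row ``m``: the participant's decision histogram for the material
        of reference rank ``m + 1`` (rows sum to 1).
    spec : NetworkSpec, optional
        Defaults to the study architecture with ``n_outputs = M``.
    """

    def __init__(
        self,
        touch: np.ndarray,
        slide: np.ndarray,
        material_ids: np.ndarray,
        target_histograms: np.ndarray,
        spec: NetworkSpec | None = None,
    ):
        self.touch = np.asarray(touch, dtype=float)
        self.slide = np.asarray(slide, dtype=float)
        self.material_ids = np.asarray(material_ids, dtype=int)
        self.target_histograms = np.asarray(target_histograms, dtype=float)
        m = self.target_histograms.shape[0]
        if self.target_histograms.shape != (m, m):
            raise ValueError("target_histograms must be square (M, M)")
        if self.material_ids.min() < 1 or self.material_ids.max() > m:
            raise ValueError("material ids must lie in 1..M")
        if not (len(self.touch) == len(self.slide) == len(self.material_ids)):
            raise ValueError("touch, slide and material_ids must align")
        if spec is None:
            spec = NetworkSpec(n_outputs=m)
        elif spec.n_outputs != m:
            raise ValueError("spec.n_outputs must equal the number of materials")
        self.spec = spec

    @classmethod
    def from_corpus(
        cls,
        library,
        config,
        decision_matrix: DecisionMatrix,
        spec: NetworkSpec | None = None,
    ) -> "TactileAvatarModel":
        """Build from a material library + simulation config + one
        participant's decision matrix (streams the corpus to features)."""
        if decision_matrix.n_materials != len(library):
            raise ValueError("decision matrix and library disagree on M")
        touch, slide, ids = features_for_corpus(library, config)
        return cls(touch, slide, ids, decision_histograms(decision_matrix), spec)

    @property
    def n_materials(self) -> int:
        return self.target_histograms.shape[0]

    def fit(
        self,
        mode: str = "histogram",
        epochs: int = 60,
        batch_size: int = 32,
        learning_rate: float | None = None,
        val_fraction: float = 0.2,
        seed: int = 0,
    ) -> "AvatarResults":
        """Train the network and return an :class:`AvatarResults`.

        ``histogram`` mode fits the softmax output to the participant's
        decision histograms with an MSE loss (the avatar system);
        ``categorical`` mode is the one-hot cross-entropy baseline, with
        each material labelled by the rounded mean human decision.

        The default learning rate is per-mode (2.0 for histogram-MSE,
        0.05 for cross-entropy): the MSE loss averages over output nodes,
        so its gradient scale is ~M times smaller than cross-entropy's.
        """
        if learning_rate is None:
            learning_rate = 2.0 if mode == "histogram" else 0.05
        m = self.n_materials
        if mode == "histogram":
            targets_by_material = self.target_histograms
        elif mode == "categorical":
            means = self.reference_means()
            labels = np.clip(np.floor(means + 0.5).astype(int), 1, m)
            targets_by_material = np.eye(m)[labels - 1]
        else:
            raise ValueError("mode must be 'histogram' or 'categorical'")
        targets = targets_by_material[self.material_ids - 1]
        train_idx, val_idx = stratified_split(self.material_ids, val_fraction, seed)
        net = AvatarNetwork(replace(self.spec, loss_mode=mode), seed=seed)
        history = net.train(
            self.touch[train_idx],
            self.slide[train_idx],
            targets[train_idx],
            epochs=epochs,
            batch_size=batch_size,
            seed=seed + 1,
            mode=mode,
            learning_rate=learning_rate,
        )
        return AvatarResults(
            model=self,
            network=net,
            mode=mode,
            loss_history=np.asarray(history),
            train_idx=train_idx,
            val_idx=val_idx,
        )

    def reference_means(self) -> np.ndarray:
        """Participant's mean decision per material (histogram mean)."""
        ranks = np.arange(1, self.n_materials + 1)
        return self.target_histograms @ ranks


@dataclass
class AvatarResults:
    """Trained avatar with its evaluation machinery.

    Evaluation defaults to the held-out validation split; pass
    ``split="train"`` or ``split="all"`` where noted.
    """

    model: TactileAvatarModel
    network: AvatarNetwork
    mode: str
    loss_history: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    _proba_cache: dict = field(default_factory=dict, repr=False)

    def _indices(self, split: str) -> np.ndarray:
        if split == "val":
            return self.val_idx
        if split == "train":
            return self.train_idx
        if split == "all":
            return np.arange(len(self.model.material_ids))
        raise ValueError("split must be 'val', 'train' or 'all'")

    def predict_proba(self, split: str = "val") -> np.ndarray:
        """Output distributions for the recordings of a split."""
        if split not in self._proba_cache:
            idx = self._indices(split)
            self._proba_cache[split] = self.network.predict_proba(
                self.model.touch[idx], self.model.slide[idx]
            )
        return self._proba_cache[split]

    def expected_decisions(self, split: str = "val") -> np.ndarray:
        """Rounded expected rank per recording of the split."""
        return _decision.expected_decisions(self.predict_proba(split))

    def tolerance_accuracy(self, tolerance: float = 2, split: str = "val") -> float:
        idx = self._indices(split)
        return _decision.tolerance_accuracy(
            self.expected_decisions(split),
            self.model.material_ids[idx],
            self.model.reference_means(),
            tolerance,
        )

    def decision_error(self, tolerance: float = 2, split: str = "val") -> float:
        """Fraction of held-out decisions beyond ``tolerance`` ranks of the
        participant's mean decision."""
        return 1.0 - self.tolerance_accuracy(tolerance, split)

    def accuracy_curve(
        self, tolerances: Sequence[float] | None = None, split: str = "val"
    ) -> _decision.ToleranceAccuracyCurve:
        if tolerances is None:
            tolerances = np.arange(0, self.model.n_materials)
        idx = self._indices(split)
        return _decision.accuracy_curve(
            self.expected_decisions(split),
            self.model.material_ids[idx],
            self.model.reference_means(),
            tolerances,
        )

    def mean_output_distribution(self, split: str = "all") -> np.ndarray:
        """Per-material mean output distribution, shape (M, M)."""
        idx = self._indices(split)
        probs = self.predict_proba(split)
        ids = self.model.material_ids[idx]
        m = self.model.n_materials
        out = np.empty((m, m))
        for mid in range(1, m + 1):
            rows = probs[ids == mid]
            if rows.size == 0:
                raise ValueError(f"no recordings of material {mid} in split")
            out[mid - 1] = rows.mean(axis=0)
        return out

    def output_means(self, split: str = "all") -> np.ndarray:
        """Expected rank of the mean output distribution per material."""
        ranks = np.arange(1, self.model.n_materials + 1)
        return self.mean_output_distribution(split) @ ranks

    def output_kurtosis(self, split: str = "all") -> np.ndarray:
        """Pearson kurtosis of the mean output distribution per material
        (NaN where degenerate)."""
        dists = self.mean_output_distribution(split)
        out = np.empty(len(dists))
        for i, row in enumerate(dists):
            try:
                out[i] = histogram_kurtosis(row)
            except DegenerateHistogramError:
                out[i] = np.nan
        return out

    def output_entropy(self, split: str = "val") -> float:
        """Mean output entropy (nats) over the split's recordings."""
        return _decision.output_entropy(self.predict_proba(split))

    def summary(self, tolerance: float = 2) -> str:
        """Plain-text fit summary (loss, held-out decision metrics)."""
        m = self.model.n_materials
        err = self.decision_error(tolerance)
        target_means = self.model.reference_means()
        mean_dev = float(
            np.mean(np.abs(self.output_means("all") - target_means))
        )
        lines = [
            "Tactile Avatar Results",
            "=" * 46,
            f"{'loss mode':<30}{self.mode:>16}",
            f"{'materials':<30}{m:>16d}",
            f"{'recordings (train/val)':<30}"
            f"{f'{self.train_idx.size}/{self.val_idx.size}':>16}",
            f"{'epochs':<30}{self.loss_history.size:>16d}",
            f"{'initial loss':<30}{self.loss_history[0]:>16.6f}",
            f"{'final loss':<30}{self.loss_history[-1]:>16.6f}",
            f"{'tolerance':<30}{tolerance:>16.0f}",
            f"{'held-out accuracy':<30}{1 - err:>15.1%}",
            f"{'held-out decision error':<30}{err:>15.1%}",
            f"{'mean |output - target| rank':<30}{mean_dev:>16.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)
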