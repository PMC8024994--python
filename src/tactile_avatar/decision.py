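"""Turning output distributions into unique decisions and scoring them.

The network's softmax output is read as a probability distribution over
rank-sorted materials. A unique decision is the rounded expected rank
(probability-weighted mean, rounded half away from zero). Accuracy is
tolerance-bounded: a decision counts as correct when it lies within the
tolerance (in rank units) of the paired human's mean decision for that
material; the decision error is the complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ToleranceAccuracyCurve",
    "expected_decision",
    "expected_decisions",
    "tolerance_accuracy",
    "decision_error",
    "accuracy_curve",
    "curve_tolerance_gap",
    "output_entropy",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # snap to 9 decimals first so accumulated float error cannot push an
    # exact .5 boundary (e.g. the mean of a uniform distribution) off it
    x = np.round(x, 9)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _validate_dist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("activation must be a normalized probability vector")
    return p


def expected_decision(activation: np.ndarray) -> int:
    """Rounded expected rank of one activation distribution.

    ``round(sum_r r * p_r)`` with ranks 1..M and half-away-from-zero
    rounding (so a uniform distribution over 1..42 decides 22).
    """
    p = _validate_dist(activation)
    ranks = np.arange(1, p.size + 1)
    return int(_round_half_away(np.array(ranks @ p)))


def expected_decisions(activations: np.ndarray) -> np.ndarray:
    """Vectorized :func:`expected_decision` over rows."""
    p = _validate_dist(np.atleast_2d(activations))
    ranks = np.arange(1, p.shape[1] + 1)
    return _round_half_away(p @ ranks).astype(int)


def _reference_for(
    material_ids: np.ndarray, reference_means: Mapping[int, float] | np.ndarray
) -> np.ndarray:
    if isinstance(reference_means, Mapping):
        missing = set(np.unique(material_ids)) - set(reference_means)
        if missing:
            raise ValueError(f"no reference mean for materials {sorted(missing)}")
        return np.array([reference_means[int(m)] for m in material_ids], dtype=float)
    ref = np.asarray(reference_means, dtype=float)
    ids = np.asarray(material_ids, dtype=int)
    if ids.min(initial=1) < 1 or ids.max(initial=1) > ref.size:
        raise ValueError("material id outside the reference table")
    return ref[ids - 1]


def tolerance_accuracy(
    decisions: Sequence[int] | np.ndarray,
    material_ids: Sequence[int] | np.ndarray,
    reference_means: Mapping[int, float] | np.ndarray,
    tolerance: float,
) -> float:
    """Fraction of decisions within ``tolerance`` ranks of the reference mean.

    Reference means stay real-valued (only the decision is rounded); a
    deviation of exactly the tolerance counts as correct. ``reference_means``
    is either a mapping material_id -> mean or an array indexed by rank - 1.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    decisions = np.asarray(decisions, dtype=float)
    ref = _reference_for(np.asarray(material_ids, dtype=int), reference_means)
    if decisions.shape != ref.shape:
        raise ValueError("decisions and material_ids must align")
    return float(np.mean(np.abs(decisions - ref) <= tolerance))


def decision_error(
    decisions,
    material_ids,
    reference_means,
    tolerance: float,
) -> float:
    """1 - tolerance accuracy (the classification-error fraction)."""
    return 1.0 - tolerance_accuracy(decisions, material_ids, reference_means, tolerance)


@dataclass(frozen=True)
class ToleranceAccuracyCurve:
    """Accuracy as a function of the tolerance bound (rank units)."""

    tolerances: np.ndarray
    accuracies: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tolerances, dtype=float)
        a = np.asarray(self.accuracies, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("tolerances must be strictly ascending")
        if np.any(np.diff(a) < -1e-12):
            raise ValueError("accuracy must be nondecreasing in tolerance")
        object.__setattr__(self, "tolerances", t)
        object.__setattr__(self, "accuracies", a)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"tolerance": self.tolerances, "accuracy": self.accuracies}
        )

    def tolerance_at(self, accuracy_level: float) -> float:
        """Smallest (interpolated) tolerance reaching ``accuracy_level``."""
        t, a = self.tolerances, self.accuracies
        if accuracy_level > a[-1] + 1e-12:
            raise ValueError("accuracy level never reached on this curve")
        i = int(np.searchsorted(a, accuracy_level, side="left"))
        if i == 0 or a[i] == a[i - 1]:
            return float(t[i])
        frac = (accuracy_level - a[i - 1]) / (a[i] - a[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def accuracy_curve(
    decisions,
    material_ids,
    reference_means,
    tolerances: Sequence[float] | np.ndarray,
) -> ToleranceAccuracyCurve:
    """Pointwise tolerance-accuracy curve over ascending tolerance levels."""
    accs = [
        tolerance_accuracy(decisions, material_ids, reference_means, t)
        for t in tolerances
    ]
    return ToleranceAccuracyCurve(np.asarray(tolerances, float), np.asarray(accs))


def curve_tolerance_gap(
    better: ToleranceAccuracyCurve,
    worse: ToleranceAccuracyCurve,
    n_materials: int,
    accuracy_level: float | None = None,
) -> tuple[float, float]:
    """Horizontal gap between two accuracy curves, in ranks and % of scale.

    Evaluated at ``accuracy_level`` (default: where the better curve
    saturates), with linear interpolation between tolerance levels. A
    4-rank gap on a 42-material scale is 9.5%.
    """
    level = float(better.accuracies[-1]) if accuracy_level is None else accuracy_level
    gap = worse.tolerance_at(level) - better.tolerance_at(level)
    return gap, 100.0 * gap / n_materials


def output_entropy(activations: np.ndarray) -> float:
    """Mean Shannon entropy (nats) of output distributions; a sharpness
    diagnostic for contrasting categorical vs histogram training."""
    p = _validate_dist(np.atleast_2d(activations))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum(axis=1).mean())
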