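"""Generative model of human forced-ranking behaviour and decision metrics.

Each participant repeatedly ranks M texture materials from smoothest/softest
(rank 1) to roughest (rank M). A trial is modelled as noisy latent utilities
``true_rank + bias(m) + sigma(m) * N(0,1)`` which are then sorted, so every
trial is a full permutation of 1..M by construction. Mid-ranked materials
(ranks 11-30 of 42) carry larger decision noise than side materials, and
"dissimilar" (D) participants carry larger noise and bias than "similar"
(S) ones — the two robust features of the human cohort this model emulates.

Metrics: the per-participant decision RMSE against the cohort's grand-mean
reference ranking (used to split the cohort into S/D groups at the mean),
the per-material human-vs-avatar RMSE of trial-mean decisions, the
trial-to-trial decision standard deviation ("tactile confusion", population
normalisation 1/I), and the Pearson kurtosis of a rank histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .simulator import side_middle_masks

__all__ = [
    "Participant",
    "DecisionMatrix",
    "DecisionHistogram",
    "DegenerateHistogramError",
    "CohortParams",
    "sample_participant",
    "sample_cohort",
    "simulate_decision_matrix",
    "decision_histogram",
    "decision_histograms",
    "tactile_decision_rmse",
    "h_a_rmse",
    "decision_std",
    "histogram_kurtosis",
    "split_groups",
]


class DegenerateHistogramError(ValueError):
    """Raised when a moment is undefined (zero-variance histogram)."""


@dataclass(frozen=True)
class CohortParams:
    """Noise geometry of the simulated cohort, in rank units.

    ``sigma_side``/``sigma_middle`` are S-group latent noise scales for side
    and middle materials; D-group scales are multiplied by ``d_noise_mult``.
    ``bias_scale_s``/``bias_scale_d`` scale the per-material idiosyncratic
    offset of each participant's internal ordering.
    """

    sigma_side: float = 0.8
    sigma_middle: float = 2.2
    d_noise_mult: float = 2.2
    bias_scale_s: float = 0.5
    bias_scale_d: float = 1.5
    sigma_jitter: float = 0.2  # lognormal spread of per-material sigmas


@dataclass(frozen=True)
class Participant:
    participant_id: int
    group: str  # "S" (similar) or "D" (dissimilar)
    bias: np.ndarray  # per-material latent offset, rank units
    sigma: np.ndarray  # per-material latent noise scale, rank units
    seed: int

    @property
    def n_materials(self) -> int:
        return self.bias.size


@dataclass(frozen=True)
class DecisionMatrix:
    """Trials x materials integer ranks; every row is a permutation of 1..M.

    Columns follow the reference (true-rank) material order: column ``m``
    holds the rank the participant assigned to the material whose reference
    rank is ``m + 1``.
    """

    participant_id: int
    ranks: np.ndarray  # (I, M) integers

    @property
    def n_trials(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_materials(self) -> int:
        return self.ranks.shape[1]

    def mean_decision(self) -> np.ndarray:
        """Per-material mean assigned rank over trials."""
        return self.ranks.mean(axis=0)


@dataclass(frozen=True)
class DecisionHistogram:
    """Probability distribution of assigned ranks for one material."""

    material_id: int
    probs: np.ndarray  # (M,) nonnegative, sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("histogram must be nonnegative and sum to 1")

    @property
    def mean(self) -> float:
        ranks = np.arange(1, self.probs.size + 1)
        return float(ranks @ self.probs)


def sample_participant(
    group: str,
    m_count: int = 42,
    seed: int = 0,
    params: CohortParams = CohortParams(),
) -> Participant:
    """Draw one participant of the given group ("S" or "D").

    Middle materials get larger latent noise than side materials; D-group
    draws multiply all noise scales and use the wider bias scale.
    """
    if group not in ("S", "D"):
        raise ValueError(f"unknown group {group!r}: expected 'S' or 'D'")
    rng = np.random.default_rng(seed)
    _, middle = side_middle_masks(m_count)
    base = np.where(middle, params.sigma_middle, params.sigma_side)
    if group == "D":
        base = base * params.d_noise_mult
    sigma = base * np.exp(rng.normal(0.0, params.sigma_jitter, size=m_count))
    bias_scale = params.bias_scale_s if group == "S" else params.bias_scale_d
    bias = bias_scale * rng.standard_normal(m_count)
    return Participant(
        participant_id=int(seed), group=group, bias=bias, sigma=sigma, seed=int(seed)
    )


def sample_cohort(
    n_s: int = 7,
    n_d: int = 3,
    m_count: int = 42,
    seed: int = 0,
    params: CohortParams = CohortParams(),
) -> list[Participant]:
    """Sample the study cohort (default 7 S + 3 D participants)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_s + n_d)
    cohort = [
        sample_participant("S", m_count, int(seeds[i]), params) for i in range(n_s)
    ]
    cohort += [
        sample_participant("D", m_count, int(seeds[n_s + j]), params)
        for j in range(n_d)
    ]
    return [
        Participant(i + 1, p.group, p.bias, p.sigma, p.seed)
        for i, p in enumerate(cohort)
    ]


def simulate_decision_matrix(
    participant: Participant, n_trials: int = 20
) -> DecisionMatrix:
    """Simulate ``n_trials`` full rankings for one participant.

    Latent utilities are sorted per trial, so each row is guaranteed to be
    a permutation of 1..M. With all-zero noise and bias every trial is the
    identity permutation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    m = participant.n_materials
    rng = np.random.default_rng(participant.seed)
    true = np.arange(1, m + 1, dtype=float)
    latent = (
        true[None, :]
        + participant.bias[None, :]
        + participant.sigma[None, :] * rng.standard_normal((n_trials, m))
    )
    order = np.argsort(latent, axis=1, kind="stable")
    ranks = np.empty((n_trials, m), dtype=int)
    rows = np.arange(n_trials)[:, None]
    ranks[rows, order] = np.arange(1, m + 1)
    return DecisionMatrix(participant_id=participant.participant_id, ranks=ranks)


def decision_histogram(matrix: DecisionMatrix, material_id: int) -> DecisionHistogram:
    """Histogram of ranks assigned to one material (reference rank index)."""
    m = matrix.n_materials
    if not 1 <= material_id <= m:
        raise ValueError(f"material_id {material_id} outside 1..{m}")
    col = matrix.ranks[:, material_id - 1]
    counts = np.bincount(col, minlength=m + 1)[1:]
    return DecisionHistogram(material_id, counts / matrix.n_trials)


def decision_histograms(matrix: DecisionMatrix) -> np.ndarray:
    """All per-material histograms as an (M, M) row-stochastic array."""
    m = matrix.n_materials
    return np.stack(
        [decision_histogram(matrix, mid).probs for mid in range(1, m + 1)]
    )


def _reference_means(matrices: Sequence[DecisionMatrix]) -> np.ndarray:
    stacked = np.concatenate([mx.ranks for mx in matrices], axis=0)
    return stacked.mean(axis=0)


def tactile_decision_rmse(
    matrices: Sequence[DecisionMatrix],
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Per-participant decision RMSE against the cohort reference ranking.

    The reference is the grand mean assigned rank per material over all
    participants and trials; participant s scores
    ``sqrt(mean over materials and trials of (rank - reference)^2)``.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one decision matrix")
    ref = _reference_means(matrices) if reference is None else np.asarray(reference)
    out = np.empty(len(matrices))
    for i, mx in enumerate(matrices):
        out[i] = np.sqrt(np.mean((mx.ranks - ref[None, :]) ** 2))
    return out


def h_a_rmse(
    human_matrices: Sequence[DecisionMatrix],
    avatar_means: np.ndarray,
) -> np.ndarray:
    """Per-material human-vs-avatar decision RMSE.

    ``avatar_means`` holds each paired avatar's trial-mean decision,
    shape (S, M); the result is, per material, the RMS across participants
    of (human trial mean - avatar trial mean).
    """
    avatar_means = np.atleast_2d(np.asarray(avatar_means, dtype=float))
    if len(human_matrices) != avatar_means.shape[0]:
        raise ValueError("one avatar mean row per participant required")
    if any(mx.n_materials != avatar_means.shape[1] for mx in human_matrices):
        raise ValueError("material sets of humans and avatars differ")
    human_means = np.stack([mx.mean_decision() for mx in human_matrices])
    return np.sqrt(np.mean((human_means - avatar_means) ** 2, axis=0))


def decision_std(matrix: DecisionMatrix) -> np.ndarray:
    """Per-material trial-to-trial decision std ("tactile confusion").

    Population normalisation (divisor I). Requires at least two trials.
    """
    if matrix.n_trials < 2:
        raise ValueError("decision std needs at least 2 trials")
    return matrix.ranks.std(axis=0, ddof=0)


def histogram_kurtosis(histogram: DecisionHistogram | np.ndarray) -> float:
    """Pearson kurtosis (normal = 3) of the rank variable under a histogram."""
    probs = histogram.probs if isinstance(histogram, DecisionHistogram) else histogram
    probs = np.asarray(probs, dtype=float)
    ranks = np.arange(1, probs.size + 1, dtype=float)
    mu = ranks @ probs
    var = ((ranks - mu) ** 2) @ probs
    if var <= 0:
        raise DegenerateHistogramError("kurtosis undefined for zero-variance histogram")
    m4 = ((ranks - mu) ** 4) @ probs
    return float(m4 / var**2)


def split_groups(rmses: np.ndarray | Sequence[float]) -> list[str]:
    """Label participants S (below the mean RMSE) or D (at or above it)."""
    rmses = np.asarray(rmses, dtype=float)
    if rmses.size < 2:
        raise ValueError("need at least 2 participants to split groups")
    mean = rmses.mean()
    return ["S" if r < mean else "D" for r in rmses]
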