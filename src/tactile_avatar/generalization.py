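"""Untrained-material evaluation: leave-one-out prediction and histogram
decomposition.

A trained avatar is shown recordings of a material left out of training
and its output distribution over ranks is read as a tactile prediction.
Separately, an untrained material's human decision histogram is expressed
as the best-fitting convex combination (weights >= 0, summing to 1) of the
trained materials' histograms; the fit RMSE measures how much of the new
material's tactile identity is already spanned by prior experience.
Mid-ranked materials overlap their neighbours, so both prediction error
and fit RMSE are expected to be lower for the middle band than the sides.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model import AvatarResults, TactileAvatarModel
from .network import NetworkSpec
from .psychophysics import DegenerateHistogramError, histogram_kurtosis
from .simulator import side_middle_masks

__all__ = [
    "DecompositionResult",
    "LeaveOneOutResult",
    "GroupComparison",
    "fit_linear_combination",
    "leave_one_out_predict",
    "side_vs_middle_summary",
]


@dataclass(frozen=True)
class DecompositionResult:
    """Convex-combination fit of a target histogram on a basis."""

    weights: np.ndarray  # on the probability simplex
    rmse: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-9) or not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("weights must lie on the probability simplex")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def fit_linear_combination(
    target: np.ndarray,
    basis: Sequence[np.ndarray] | np.ndarray,
    simplex: bool = True,
) -> DecompositionResult:
    """Best-fitting linear combination of basis histograms for a target.

    Minimises the RMS deviation between the target and ``sum_j w_j b_j``
    subject to ``w >= 0`` and ``sum w = 1`` (kept so that the combination
    is itself a histogram). ``simplex=False`` drops both constraints
    (sensitivity analysis only); the returned weights are then not
    validated against the simplex.
    """
    target = np.asarray(target, dtype=float)
    basis = np.atleast_2d(np.asarray(basis, dtype=float))  # (K, R)
    if basis.shape[0] < 1:
        raise ValueError("basis must be nonempty")
    if basis.shape[1] != target.size:
        raise ValueError("target and basis must share the same rank support")
    bt = basis.T  # (R, K)
    if not simplex:
        w, *_ = np.linalg.lstsq(bt, target, rcond=None)
        resid = bt @ w - target
        return _unchecked(w, float(np.sqrt(np.mean(resid**2))))
    k = basis.shape[0]
    gram = bt.T @ bt
    cross = bt.T @ target

    def objective(w):
        resid = bt @ w - target
        return 0.5 * float(resid @ resid), gram @ w - cross

    res = optimize.minimize(
        objective,
        x0=np.full(k, 1.0 / k),
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    resid = bt @ w - target
    return DecompositionResult(w, float(np.sqrt(np.mean(resid**2))))


def _unchecked(weights: np.ndarray, rmse: float) -> DecompositionResult:
    obj = object.__new__(DecompositionResult)
    object.__setattr__(obj, "weights", np.asarray(weights, dtype=float))
    object.__setattr__(obj, "rmse", rmse)
    return obj


@dataclass
class LeaveOneOutResult:
    """Avatar predictions for one held-out material."""

    held_out_material: int
    activations: np.ndarray  # (n_heldout_recordings, M)
    results: AvatarResults  # avatar trained without the material

    @property
    def mean_distribution(self) -> np.ndarray:
        return self.activations.mean(axis=0)

    @property
    def predicted_mean(self) -> float:
        ranks = np.arange(1, self.activations.shape[1] + 1)
        return float(self.mean_distribution @ ranks)

    @property
    def predicted_kurtosis(self) -> float:
        try:
            return histogram_kurtosis(self.mean_distribution)
        except DegenerateHistogramError:
            return float("nan")


def leave_one_out_predict(
    model: TactileAvatarModel,
    held_out_material: int,
    **fit_kwargs,
) -> LeaveOneOutResult:
    """Train on all materials except one; predict its recordings.

    The output layer keeps all M rank-sorted nodes (training targets of
    the remaining materials already spread mass across ranks), so the
    held-out prediction is read purely as a distribution over ranks —
    never as a trained label identity.
    """
    m = model.n_materials
    if m < 2:
        raise ValueError("leave-one-out needs at least 2 materials")
    if not 1 <= held_out_material <= m:
        raise ValueError(f"held-out material {held_out_material} outside 1..{m}")
    mask = model.material_ids != held_out_material
    sub = TactileAvatarModel(
        model.touch[mask],
        model.slide[mask],
        model.material_ids[mask],
        model.target_histograms,
        spec=model.spec,
    )
    fit_kwargs.setdefault("val_fraction", 0.0)
    res = sub.fit(**fit_kwargs)
    activations = res.network.predict_proba(
        model.touch[~mask], model.slide[~mask]
    )
    return LeaveOneOutResult(held_out_material, activations, res)


@dataclass(frozen=True)
class GroupComparison:
    """Side-band vs middle-band summary of a per-material metric."""

    side_mean: float
    middle_mean: float
    side_sem: float
    middle_sem: float
    statistic: float
    pvalue: float
    alternative: str
    n_side: int
    n_middle: int


def side_vs_middle_summary(
    per_material_metric: np.ndarray,
    alternative: str = "less",
) -> GroupComparison:
    """Compare a per-material metric between middle and side rank bands.

    Side = ranks 1-10 and 31-42 (n = 22), middle = 11-30 (n = 20) at the
    42-material scale; other sizes scale proportionally. The one-sided
    two-sample t-test uses ``alternative`` for the middle band relative to
    the side band (``"less"``: middle < side).
    """
    x = np.asarray(per_material_metric, dtype=float)
    side_mask, middle_mask = side_middle_masks(x.size)
    if np.any(~np.isfinite(x)):
        raise ValueError("metric must be finite for all materials")
    side, middle = x[side_mask], x[middle_mask]
    if np.ptp(x) == 0:  # no variation anywhere: trivially non-significant
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(middle, side, alternative=alternative)
    return GroupComparison(
        side_mean=float(side.mean()),
        middle_mean=float(middle.mean()),
        side_sem=float(stats.sem(side)) if side.size > 1 else float("nan"),
        middle_sem=float(stats.sem(middle)) if middle.size > 1 else float("nan"),
        statistic=float(stat),
        pvalue=float(p),
        alternative=alternative,
        n_side=int(side.size),
        n_middle=int(middle.size),
    )
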