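"""Fitting criteria for all three workflow stages.

All residuals are taken on the log10 scale: the substrate and cell series
differ by orders of magnitude, and log-transforming places the two
variables on equivalent scales so neither dominates the joint fit.  The
simplified Gaussian log-likelihood objective reduces to an unweighted sum
of the two per-variable sums of squared log10 residuals (replicate
averaging removes the need for per-variable sigma weights; optional sigma
weighting is retained for users with many replicates).  The per-variable
covariance is treated as negligible (diagonal error model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import BatchDataset, TrajectoryPrediction

__all__ = [
    "ObjectiveValue",
    "AbcTarget",
    "residuals",
    "of1",
    "of_mo",
    "of2_abc",
    "PENALTY_TOTAL",
]

#: Finite total returned for penalty-marked (failed-integration) predictions.
PENALTY_TOTAL = 1e12

#: Predictions are floored here before log10 so near-zero predictions are
#: heavily penalized rather than producing -inf.
PRED_FLOOR = 1e-12


@dataclass(frozen=True)
class ObjectiveValue:
    """Joint objective decomposition.

    ssr_subs / ssr_cells are per-variable sums of squared log10 residuals;
    total = ssr_subs + ssr_cells; pct_* give each variable's percent
    contribution to the total (50/50 by convention, flagged degenerate,
    when total is 0).
    """

    ssr_subs: float
    ssr_cells: float
    total: float
    pct_subs: float
    pct_cells: float
    degenerate: bool = False

    @staticmethod
    def from_ssrs(ssr_subs: float, ssr_cells: float,
                  w_subs: float = 1.0, w_cells: float = 1.0) -> "ObjectiveValue":
        total = w_subs * ssr_subs + w_cells * ssr_cells
        if total > 0:
            pct_subs = 100.0 * w_subs * ssr_subs / total
            # complement, so the percent identity holds to the last bit
            return ObjectiveValue(ssr_subs, ssr_cells, total, pct_subs, 100.0 - pct_subs)
        return ObjectiveValue(ssr_subs, ssr_cells, total, 50.0, 50.0, degenerate=True)


@dataclass(frozen=True)
class AbcTarget:
    """Observed summary statistics and tolerances for the ABC stage.

    observed_stats = (ssr_subs*, ssr_cells*) of the multi-objective
    compromise solution; epsilons are per-statistic tolerances.  A
    candidate is behavioral iff every |S_j - S_j^| <= eps_j, i.e. its
    :func:`of2_abc` fitness is >= 0.
    """

    observed_stats: np.ndarray
    epsilons: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_stats",
                           np.atleast_1d(np.asarray(self.observed_stats, dtype=float)))
        object.__setattr__(self, "epsilons",
                           np.atleast_1d(np.asarray(self.epsilons, dtype=float)))
        if self.observed_stats.shape != self.epsilons.shape:
            raise ValueError("observed_stats and epsilons must have equal lengths")
        if np.any(self.observed_stats < 0):
            raise ValueError("observed_stats must be non-negative")
        if np.any(self.epsilons <= 0):
            raise ValueError("epsilons must be strictly positive")

    @staticmethod
    def from_compromise(ssr_subs: float, ssr_cells: float,
                        rel_eps: float = 0.05, min_eps: float = 0.01) -> "AbcTarget":
        """Default tolerances eps_j = max(rel_eps * S_j, min_eps)."""
        stats = np.array([ssr_subs, ssr_cells], dtype=float)
        eps = np.maximum(rel_eps * stats, min_eps)
        return AbcTarget(stats, eps)


def residuals(dataset: BatchDataset, prediction: TrajectoryPrediction):
    """Per-variable log10 residual vectors (observed minus predicted).

    r_subs[i] = log10(S_obs[i]) - log10(max(S_pred[i], 1e-12)) and likewise
    for cells.  A penalty-marked prediction yields sentinel vectors whose
    squared sums total :data:`PENALTY_TOTAL`.
    """
    if prediction.times.size != dataset.times.size or not np.allclose(
        prediction.times, dataset.times
    ):
        raise ValueError("prediction must be evaluated at exactly the dataset's times")
    if prediction.penalized:
        n = dataset.n_times
        sentinel = np.full(n, np.sqrt(PENALTY_TOTAL / (2 * n)))
        return sentinel, sentinel.copy()
    r_subs = np.log10(dataset.S_obs) - np.log10(np.maximum(prediction.S_pred, PRED_FLOOR))
    r_cells = np.log10(dataset.C_obs) - np.log10(np.maximum(prediction.C_pred, PRED_FLOOR))
    return r_subs, r_cells


def of1(dataset: BatchDataset, prediction: TrajectoryPrediction,
        sigma_subs: float = 1.0, sigma_cells: float = 1.0) -> ObjectiveValue:
    """Simplified Gaussian log-likelihood objective (to minimize).

    Unweighted by default (sigma = 1 for both variables); pass replicate
    sigmas to recover the weighted 1/sigma^2 form.
    """
    r_subs, r_cells = residuals(dataset, prediction)
    return ObjectiveValue.from_ssrs(
        float(np.sum(r_subs**2)),
        float(np.sum(r_cells**2)),
        w_subs=1.0 / sigma_subs**2,
        w_cells=1.0 / sigma_cells**2,
    )


def of_mo(dataset: BatchDataset, prediction: TrajectoryPrediction) -> np.ndarray:
    """Two-component objective vector (ssr_subs, ssr_cells), minimized jointly."""
    v = of1(dataset, prediction)
    return np.array([v.ssr_subs, v.ssr_cells])


def of2_abc(simulated_stats, target: AbcTarget) -> float:
    """ABC fitness (to maximize): min_j (eps_j - |S_j - S_j^|).

    Non-negative iff the candidate is behavioral (every simulated summary
    statistic within tolerance of its observed counterpart).
    """
    sim = np.atleast_1d(np.asarray(simulated_stats, dtype=float))
    if sim.shape != target.observed_stats.shape:
        raise ValueError(
            f"simulated_stats length {sim.size} != observed length "
            f"{target.observed_stats.size}"
        )
    return float(np.min(target.epsilons - np.abs(target.observed_stats - sim)))
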