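"""Step 2: global multi-objective search over (ssr_subs, ssr_cells).

An elitist genetic algorithm in the NSGA-II mould: simulated binary
crossover and polynomial mutation generate offspring, fast non-dominated
sorting ranks the merged parent+offspring population, and crowding-distance
truncation keeps the population diverse.  With exactly two objectives,
reference-direction machinery (NSGA-III/RVEA) adds nothing, so plain
crowding is used.

The returned Pareto front carries a "compromise" member: objectives are
min-max normalized over the front and the member closest (Euclidean) to
the normalized ideal point (0, 0) is selected — standard compromise
programming, which picks the knee of a symmetric front.  The front's
endpoints are cross-checked against the single-objective extreme fits to
verify that both search frameworks converged to the same region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .models import KineticModelSpec, KineticParams
from .objectives import ObjectiveValue
from .optimize_so import make_stage_objective
from .simulate import BatchDataset

__all__ = [
    "MoRunConfig",
    "ParetoFront",
    "nsga2_evolve",
    "fit_pareto",
    "select_compromise",
    "verify_against_so",
    "hypervolume_2d",
]


@dataclass(frozen=True)
class MoRunConfig:
    """Run conditions for the multi-objective stage.

    The published campaign ran 20,000 generations at population 100;
    scaled-down budgets (hundreds of generations) suffice for the small
    synthetic problems exercised in tests.
    """

    n_generations: int = 20_000
    pop_size: int = 100
    seed: int = 0
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0
    crossover_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.pop_size % 2 != 0:
            raise ValueError("pop_size must be even")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


@dataclass
class ParetoFront:
    """Non-dominated archive with its selected compromise member.

    ``objectives`` is (m, 2); ``decisions`` the matching decision vectors
    in the optimizer's coordinates (log10 parameters for kinetic fits).
    """

    objectives: np.ndarray
    decisions: np.ndarray
    ideal_point: np.ndarray
    compromise_index: int
    degenerate: bool = False       # single-point front
    params: list[KineticParams] | None = None   # natural-scale, kinetic fits
    param_names: tuple[str, ...] | None = None  # decision-column names
    hv_trace: np.ndarray | None = None          # per-generation archive hypervolume

    @property
    def compromise_objectives(self) -> np.ndarray:
        return self.objectives[self.compromise_index]

    @property
    def compromise_params(self) -> KineticParams:
        if self.params is None:
            raise ValueError("front was not produced by a kinetic fit")
        return self.params[self.compromise_index]

    def compromise_value(self) -> ObjectiveValue:
        s, c = map(float, self.compromise_objectives)
        return ObjectiveValue.from_ssrs(s, c)


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def _fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    n = F.shape[0]
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt                       # dom[i, j]: i dominates j
    n_dom = dom.sum(axis=0)             # how many dominate each j
    fronts: list[np.ndarray] = []
    remaining = np.arange(n)
    counts = n_dom.astype(int).copy()
    while remaining.size:
        mask = counts[remaining] == 0
        front = remaining[mask]
        fronts.append(front)
        remaining = remaining[~mask]
        if remaining.size:
            counts[remaining] -= dom[np.ix_(front, remaining)].sum(axis=0)
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = fj[-1] - fj[0]
        if span > 0 and n > 2:
            dist[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return dist


def _sbx_crossover(p1, p2, lo, hi, eta, prob, rng):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for j in range(p1.size):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        y1, y2 = sorted((p1[j], p2[j]))
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        a = 0.5 * ((y1 + y2) - beta * (y2 - y1))
        b = 0.5 * ((y1 + y2) + beta * (y2 - y1))
        if rng.random() < 0.5:
            a, b = b, a
        c1[j] = min(max(a, lo[j]), hi[j])
        c2[j] = min(max(b, lo[j]), hi[j])
    return c1, c2


def _polynomial_mutation(x, lo, hi, eta, rng):
    y = x.copy()
    pm = 1.0 / x.size
    for j in range(x.size):
        if rng.random() >= pm:
            continue
        span = hi[j] - lo[j]
        u = rng.random()
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[j] = min(max(y[j] + delta * span, lo[j]), hi[j])
    return y


def nsga2_evolve(
    mo_objective_fn: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[Sequence[float]],
    config: MoRunConfig,
    track_hypervolume: bool = False,
) -> ParetoFront:
    """Evolve the Pareto front of a biobjective function over a finite box.

    Returns the rank-0 set of the final population with the compromise
    member selected (see :func:`select_compromise`).  Deterministic given
    ``config.seed``.  With ``track_hypervolume`` the per-generation
    dominated hypervolume of the rank-0 set (reference point: componentwise
    max of the generation-0 objectives) is recorded.
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(hi <= lo):
        raise ValueError("bounds must be a finite box with high > low")
    d = lo.size
    NP = config.pop_size

    X = lo + (hi - lo) * rng.random((NP, d))
    F = np.array([mo_objective_fn(x) for x in X], dtype=float)
    hv_ref = F.max(axis=0)
    hv_trace: list[float] = []
    arch_F = F[_fast_nondominated_sort(F)[0]]

    for _ in range(config.n_generations):
        fronts = _fast_nondominated_sort(F)
        rank = np.empty(NP, dtype=int)
        crowd = np.empty(NP)
        for r, idx in enumerate(fronts):
            rank[idx] = r
            crowd[idx] = _crowding_distance(F[idx])

        def tournament() -> int:
            i, j = rng.integers(NP), rng.integers(NP)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            if crowd[i] != crowd[j]:
                return i if crowd[i] > crowd[j] else j
            return i
        children = []
        while len(children) < NP:
            a, b = X[tournament()], X[tournament()]
            c1, c2 = _sbx_crossover(a, b, lo, hi, config.crossover_eta,
                                    config.crossover_prob, rng)
            children.append(_polynomial_mutation(c1, lo, hi, config.mutation_eta, rng))
            if len(children) < NP:
                children.append(_polynomial_mutation(c2, lo, hi, config.mutation_eta, rng))
        C = np.asarray(children)
        FC = np.array([mo_objective_fn(x) for x in C], dtype=float)

        XM = np.vstack([X, C])
        FM = np.vstack([F, FC])
        fronts = _fast_nondominated_sort(FM)
        keep: list[int] = []
        for idx in fronts:
            if len(keep) + idx.size <= NP:
                keep.extend(idx.tolist())
            else:
                cd = _crowding_distance(FM[idx])
                order = idx[np.argsort(-cd, kind="stable")]
                keep.extend(order[: NP - len(keep)].tolist())
                break
        X, F = XM[keep], FM[keep]
        if track_hypervolume:
            # external (unbounded) archive: its dominated hypervolume is
            # non-decreasing, unlike the crowding-truncated population's
            arch_F = np.vstack([arch_F, F[_fast_nondominated_sort(F)[0]]])
            arch_F = arch_F[_fast_nondominated_sort(arch_F)[0]]
            hv_trace.append(hypervolume_2d(arch_F, hv_ref))

    rank0 = _fast_nondominated_sort(F)[0]
    # drop duplicate objective vectors so the archive is strictly non-dominated
    Fr, uniq = np.unique(np.round(F[rank0], 12), axis=0, return_index=True)
    members = rank0[uniq]
    objs = F[members]
    front = ParetoFront(
        objectives=objs,
        decisions=X[members],
        ideal_point=objs.min(axis=0),
        compromise_index=0,
        degenerate=members.size == 1,
        hv_trace=np.asarray(hv_trace) if track_hypervolume else None,
    )
    front.compromise_index = _compromise_index(objs)
    return front


def _compromise_index(objs: np.ndarray) -> int:
    lo = objs.min(axis=0)
    span = objs.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    norm = (objs - lo) / span
    dist = np.sqrt((norm**2).sum(axis=1))
    order = np.lexsort((objs[:, 1], objs[:, 0], dist))
    return int(order[0])


def select_compromise(front: ParetoFront):
    """Pick the front member nearest the normalized ideal point.

    Objectives are min-max normalized to [0, 1] over the front; the member
    minimizing Euclidean distance to (0, 0) wins, with deterministic
    lexicographic tie-breaking on the raw objectives.  Returns
    ``(decision_vector_or_params, objective_vector)``.
    """
    if front.objectives.shape[0] == 0:
        raise ValueError("front is empty")
    i = _compromise_index(front.objectives)
    front.compromise_index = i
    who = front.params[i] if front.params is not None else front.decisions[i]
    return who, front.objectives[i]


def fit_pareto(
    spec: KineticModelSpec,
    dataset: BatchDataset,
    bounds: Sequence[Sequence[float]] | None = None,
    config: MoRunConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> ParetoFront:
    """Evolve the (ssr_subs, ssr_cells) Pareto front for one dataset.

    Searches log10 parameter space like the single-objective stage and
    attaches natural-scale :class:`KineticParams` to every front member.
    ``fixed`` pins named parameters, restricting the search.
    """
    config = config or MoRunConfig()
    scalar_fn, log_bounds = make_stage_objective(spec, dataset, "compromise", bounds, fixed)

    def mo_fn(z: np.ndarray) -> np.ndarray:
        v = scalar_fn.evaluate(z)
        return np.array([v.ssr_subs, v.ssr_cells])

    front = nsga2_evolve(mo_fn, log_bounds, config)
    front.params = [scalar_fn.build(10.0 ** z) for z in front.decisions]
    front.param_names = scalar_fn.free_names
    return front


def verify_against_so(
    compromise_vec: Sequence[float],
    so_compromise: ObjectiveValue,
    rel_tol: float = 0.05,
) -> dict:
    """Cross-check the MO compromise total against the SO compromise total.

    Reports the relative gap |total_MO - total_SO| / max(total_SO, 1e-12)
    and whether it passes ``rel_tol``; a failure signals that at least one
    stage has not converged and the ABC step should not yet be trusted.
    """
    total_mo = float(np.sum(compromise_vec))
    total_so = float(so_compromise.total)
    gap = abs(total_mo - total_so) / max(total_so, 1e-12)
    return {
        "total_mo": total_mo,
        "total_so": total_so,
        "relative_gap": gap,
        "rel_tol": rel_tol,
        "passed": bool(gap <= rel_tol),
    }


def hypervolume_2d(objectives: np.ndarray, reference: np.ndarray) -> float:
    """Dominated hypervolume of a biobjective set w.r.t. ``reference``.

    Standard sweep over the non-dominated points sorted by the first
    objective; points not dominating the reference contribute nothing.
    """
    pts = np.asarray(objectives, dtype=float)
    ref = np.asarray(reference, dtype=float)
    pts = pts[np.all(pts < ref, axis=1)]
    if pts.size == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    hv = 0.0
    y_prev = ref[1]
    for x, y in pts:
        if y < y_prev:
            hv += (ref[0] - x) * (y_prev - y)
            y_prev = y
    return float(hv)
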