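"""Step 1: global single-objective search with self-adaptive DE (saDE).

The optimizer evolves a population inside a finite box, choosing per
individual between two mutation strategies — rand/1/bin and
current-to-best/2/bin — with a strategy probability adapted from success
counts over a learning period, crossover rates drawn from an adapting
normal memory per strategy, and scale factors F ~ Normal(0.5, 0.3)
truncated to (0, 2].  Termination: evaluation budget, population
objective-range tolerance, or population parameter-range tolerance.

Kinetic fits search the parameters on the log10 scale internally (bounds
span decades); results are reported on the natural scale.  Three fits are
run per dataset: the two per-variable "extreme" fits (substrate-only and
cells-only error) and the joint "compromise" fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .models import KineticModelSpec, KineticParams, free_param_info
from .objectives import ObjectiveValue, of1
from .simulate import BatchDataset, integrate

__all__ = [
    "SoRunConfig",
    "SadeResult",
    "SoResult",
    "sade_minimize",
    "make_stage_objective",
    "fit_extremes_and_compromise",
]

MODES = ("compromise", "extreme_subs", "extreme_cells")


@dataclass(frozen=True)
class SoRunConfig:
    """Run conditions for one single-objective stage.

    Defaults follow the published run conditions: a 500,000-evaluation
    budget, termination when the population's objective range drops below
    1e-8 or its parameter range below 1e-2, and five independent seeded
    repetitions per fit.  ``learning_period`` (generations) governs the
    strategy/CR adaptation memory.
    """

    max_evals: int = 500_000
    pop_size: int = 50
    obj_range_tol: float = 1e-8
    param_range_tol: float = 1e-2
    seed: int = 0
    n_repetitions: int = 5
    mode: str = "compromise"
    learning_period: int = 50

    def __post_init__(self) -> None:
        if self.pop_size < 5:
            raise ValueError("pop_size must be >= 5")
        if self.obj_range_tol <= 0 or self.param_range_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class SadeResult:
    """Raw outcome of one saDE run on a generic box-constrained objective."""

    best_x: np.ndarray
    best_f: float
    n_evals: int
    termination_reason: str  # budget | obj_range | param_range
    best_trace: np.ndarray   # best-so-far objective per generation
    seed: int


@dataclass
class SoResult:
    """Outcome of a (repeated) kinetic single-objective fit."""

    mode: str
    best_params: KineticParams
    best_objective: ObjectiveValue
    best_stage_value: float          # the value actually minimized in this mode
    n_evals: int                     # summed over repetitions
    termination_reason: str          # of the winning repetition
    repetitions: list[dict] = field(default_factory=list)


def _truncnorm_F(rng: np.random.Generator) -> float:
    # F ~ N(0.5, 0.3) truncated to (0, 2]
    while True:
        f = rng.normal(0.5, 0.3)
        if 0.0 < f <= 2.0:
            return f


def sade_minimize(
    objective_fn: Callable[[np.ndarray], float],
    bounds: Sequence[Sequence[float]],
    config: SoRunConfig,
) -> SadeResult:
    """Minimize ``objective_fn`` over a finite box with self-adaptive DE.

    ``bounds`` is a (d, 2) array of [low, high] per dimension, in the same
    coordinates the objective expects.  Deterministic given
    ``config.seed``.  The recorded best-so-far trace is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be (d, 2)")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(hi <= lo):
        raise ValueError(f"bounds must be a finite box with high > low, got {bounds.tolist()}")
    d = lo.size
    NP = config.pop_size
    LP = config.learning_period

    pop = lo + (hi - lo) * rng.random((NP, d))
    fit = np.array([objective_fn(x) for x in pop], dtype=float)
    if not np.all(np.isfinite(fit)):
        raise RuntimeError("objective returned non-finite values on the initial population")
    n_evals = NP

    p1 = 0.5                      # probability of strategy 1 (rand/1/bin)
    CRm = [0.5, 0.5]              # crossover-rate means per strategy
    ns = [0, 0]                   # success counts over the learning window
    nf = [0, 0]                   # failure counts
    cr_success: list[list[float]] = [[], []]

    best_i = int(np.argmin(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    trace = [best_f]
    reason = "budget"

    gen = 0
    while n_evals + NP <= config.max_evals:
        gen += 1
        gbest = pop[int(np.argmin(fit))]
        use_s1 = rng.random(NP) < p1
        CRs = np.where(
            use_s1,
            rng.normal(CRm[0], 0.1, NP),
            rng.normal(CRm[1], 0.1, NP),
        ).clip(0.0, 1.0)

        for i in range(NP):
            F = _truncnorm_F(rng)
            idx = rng.choice(NP - 1, size=4, replace=False)
            idx[idx >= i] += 1  # distinct from i
            r1, r2, r3, r4 = pop[idx]
            if use_s1[i]:
                v = r1 + F * (r2 - r3)
                k = 0
            else:
                v = pop[i] + F * (gbest - pop[i]) + F * (r1 - r2) + F * (r3 - r4)
                k = 1
            # reflect out-of-box components back inside, then clip
            over, under = v > hi, v < lo
            v[over] = 2 * hi[over] - v[over]
            v[under] = 2 * lo[under] - v[under]
            np.clip(v, lo, hi, out=v)
            # binomial crossover with a guaranteed mutant component
            cross = rng.random(d) < CRs[i]
            cross[rng.integers(d)] = True
            u = np.where(cross, v, pop[i])

            fu = objective_fn(u)
            n_evals += 1
            if fu <= fit[i]:
                pop[i], fit[i] = u, fu
                ns[k] += 1
                cr_success[k].append(float(CRs[i]))
                if fu < best_f:
                    best_f, best_x = float(fu), u.copy()
            else:
                nf[k] += 1

        trace.append(best_f)

        if gen % LP == 0:
            s1 = ns[0] * (ns[1] + nf[1])
            s2 = ns[1] * (ns[0] + nf[0])
            if s1 + s2 > 0:
                p1 = min(max(s1 / (s1 + s2), 0.05), 0.95)
            for k in range(2):
                if cr_success[k]:
                    CRm[k] = float(np.mean(cr_success[k]))
            ns = [0, 0]
            nf = [0, 0]
            cr_success = [[], []]

        if float(fit.max() - fit.min()) < config.obj_range_tol:
            reason = "obj_range"
            break
        if float(np.max(pop.max(axis=0) - pop.min(axis=0))) < config.param_range_tol:
            reason = "param_range"
            break

    return SadeResult(
        best_x=best_x,
        best_f=best_f,
        n_evals=n_evals,
        termination_reason=reason,
        best_trace=np.asarray(trace),
        seed=config.seed,
    )


def make_stage_objective(
    spec: KineticModelSpec,
    dataset: BatchDataset,
    mode: str = "compromise",
    bounds: Sequence[Sequence[float]] | None = None,
    fixed: dict[str, float] | None = None,
):
    """Build the log10-space scalar objective for one fitting mode.

    Returns ``(objective_fn, log_bounds)``: the function maps a log10
    parameter vector to the mode's error (joint total, substrate-only SSR,
    or cells-only SSR), and ``log_bounds`` is the search box in log10
    coordinates.  ``fixed`` pins named parameters at given values,
    restricting the search (and the bounds rows) to the remaining ones.
    The initial biomass X0 = b*C0 moves with each candidate's b, keeping
    the initial condition consistent with the scaling parameter.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    free_names, build = free_param_info(spec, fixed)
    nat = np.asarray(bounds if bounds is not None else spec.bounds_array(), dtype=float)
    if nat.shape[0] == len(spec.param_names) and fixed:
        keep = [i for i, n in enumerate(spec.param_names) if n in free_names]
        nat = nat[keep]
    if nat.shape[0] != len(free_names):
        raise ValueError(f"expected bounds for {len(free_names)} free parameter(s)")
    if np.any(nat <= 0):
        raise ValueError("kinetic parameter bounds must be strictly positive (log10 search)")
    log_bounds = np.log10(nat)

    def evaluate(z: np.ndarray) -> ObjectiveValue:
        params = build(10.0 ** np.asarray(z, dtype=float))
        pred = integrate(spec, params, dataset.S0, dataset.C0, dataset.times)
        return of1(dataset, pred)

    if mode == "compromise":
        def objective_fn(z): return evaluate(z).total
    elif mode == "extreme_subs":
        def objective_fn(z): return evaluate(z).ssr_subs
    else:
        def objective_fn(z): return evaluate(z).ssr_cells

    objective_fn.evaluate = evaluate  # full decomposition, for reporting
    objective_fn.build = build        # free vector (natural scale) -> KineticParams
    objective_fn.free_names = free_names
    return objective_fn, log_bounds


def _fit_one_mode(
    spec: KineticModelSpec,
    dataset: BatchDataset,
    bounds: Sequence[Sequence[float]] | None,
    config: SoRunConfig,
    fixed: dict[str, float] | None = None,
) -> SoResult:
    objective_fn, log_bounds = make_stage_objective(spec, dataset, config.mode, bounds, fixed)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_repetitions) % (2**31)
    reps: list[dict] = []
    best: SadeResult | None = None
    total_evals = 0
    for rep_seed in seeds:
        res = sade_minimize(objective_fn, log_bounds, replace(config, seed=int(rep_seed)))
        total_evals += res.n_evals
        params_vec = 10.0 ** res.best_x
        obj = objective_fn.evaluate(res.best_x)
        reps.append({
            "seed": int(rep_seed),
            "params": params_vec.tolist(),
            "stage_value": res.best_f,
            "ssr_subs": obj.ssr_subs,
            "ssr_cells": obj.ssr_cells,
            "total": obj.total,
            "pct_subs": obj.pct_subs,
            "pct_cells": obj.pct_cells,
            "n_evals": res.n_evals,
            "termination_reason": res.termination_reason,
        })
        if best is None or res.best_f < best.best_f:
            best = res
    assert best is not None
    return SoResult(
        mode=config.mode,
        best_params=objective_fn.build(10.0 ** best.best_x),
        best_objective=objective_fn.evaluate(best.best_x),
        best_stage_value=best.best_f,
        n_evals=total_evals,
        termination_reason=best.termination_reason,
        repetitions=reps,
    )


def fit_extremes_and_compromise(
    spec: KineticModelSpec,
    dataset: BatchDataset,
    bounds: Sequence[Sequence[float]] | None = None,
    config: SoRunConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> dict[str, SoResult]:
    """Run the three single-objective fits on one dataset.

    Returns ``{"extreme_subs": ..., "extreme_cells": ..., "compromise": ...}``
    with per-repetition records and percent error decompositions.  Stage
    seeds derive deterministically from ``config.seed``.
    """
    config = config or SoRunConfig()
    mode_seeds = np.random.SeedSequence([config.seed, 101]).generate_state(3) % (2**31)
    out: dict[str, SoResult] = {}
    for mode, seed in zip(MODES, mode_seeds):
        mode_cfg = replace(config, mode=mode, seed=int(seed))
        out[mode] = _fit_one_mode(spec, dataset, bounds, mode_cfg, fixed)
    return out
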