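"""Step 3: likelihood-free posterior sampling targeting the compromise fit.

A multi-chain Approximate Bayesian Computation sampler with differential-
evolution proposals drawn from a thinned archive of past states.  The
summary statistics are the per-variable sums of squared log10 residuals;
the observed statistics are those of the verified multi-objective
compromise solution, so the sampler explores exactly the compromise region
of parameter space.  The ABC fitness (to maximize) is

    OF2 = min_j ( eps_j - |S_j - S_j_hat| )

and a parameter set is "behavioral" when OF2 >= 0.  Chains hill-climb
monotonically into the behavioral region and then move freely within it,
which yields (in the small-eps limit) a uniform sample of the behavioral
set.  Convergence is monitored with the multi-chain Gelman-Rubin potential
scale reduction factor (overall R below 1.2 taken as converged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import KineticModelSpec, KineticParams, free_param_info
from .objectives import AbcTarget, of_mo, of2_abc
from .simulate import BatchDataset, integrate

__all__ = [
    "AbcConfig",
    "AbcChainHistory",
    "PosteriorSummary",
    "abc_sample",
    "gelman_rubin",
    "summarize_posterior",
    "chain_mean_trace",
    "final_drift",
    "NoBehavioralSampleError",
]


class NoBehavioralSampleError(RuntimeError):
    """Raised when no chain entered the behavioral region within budget."""


@dataclass(frozen=True)
class AbcConfig:
    """ABC run conditions.

    Defaults follow the published campaign: 6 chains and 150,000
    generations (900k model evaluations overall); the Gelman-Rubin
    threshold 1.2 is applied by callers.  ``archive_thin`` controls how
    often current chain states are appended to the proposal archive;
    ``gamma_one_prob`` is the fraction of proposals using the mode-jumping
    scale gamma = 1 instead of 2.38/sqrt(2d).
    """

    n_chains: int = 6
    n_generations: int = 150_000
    seed: int = 0
    archive_thin: int = 10
    gamma_one_prob: float = 0.1
    jitter_rel: float = 1e-6        # proposal jitter sd, relative to box width
    monitor_every: int | None = None  # R-trace cadence; default n_generations // 100

    def __post_init__(self) -> None:
        if self.n_chains < 3:
            raise ValueError("n_chains must be >= 3 (R statistic needs multiple chains)")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.archive_thin < 1:
            raise ValueError("archive_thin must be >= 1")


@dataclass
class AbcChainHistory:
    """Multi-chain ABC sample with fitness and convergence traces.

    samples: (n_chains, n_generations, d) chain states after each
    generation; fitness: matching OF2 values; accepted: proposal-acceptance
    indicators; R_trace: (generation, overall R) monitoring pairs.
    """

    samples: np.ndarray
    fitness: np.ndarray
    accepted: np.ndarray
    R_trace: np.ndarray
    param_names: tuple[str, ...]
    prior_bounds: np.ndarray
    target: AbcTarget
    seed: int
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_generations(self) -> int:
        return self.samples.shape[1]

    def posterior_draws(self, burn_in_fraction: float = 0.5) -> np.ndarray:
        """Post-burn-in draws, flattened to (n_draws, d)."""
        if not 0.0 <= burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        start = int(self.n_generations * burn_in_fraction)
        return self.samples[:, start:, :].reshape(-1, self.samples.shape[2])

    def final_R(self) -> float:
        return float(self.R_trace[-1, 1]) if self.R_trace.size else float("nan")


@dataclass
class PosteriorSummary:
    """Posterior moments, intervals and trajectory uncertainty bands.

    The parameter band is the pointwise 2.5-97.5 percentile envelope of
    trajectories integrated at posterior parameter draws; the predictive
    band widens it by the residual noise scale (log10) of the compromise
    fit, so it covers observation scatter as well as parameter
    uncertainty.
    """

    param_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    n_draws: int
    times: np.ndarray
    S_median: np.ndarray
    C_median: np.ndarray
    S_band: np.ndarray      # (2, n_times) parameter-uncertainty band
    C_band: np.ndarray
    S_predictive: np.ndarray  # (2, n_times) predictive band (>= parameter band)
    C_predictive: np.ndarray
    residual_sd_log10: float


def _reflect_into_box(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def abc_sample(
    spec: KineticModelSpec,
    dataset: BatchDataset,
    target: AbcTarget,
    config: AbcConfig,
    prior_bounds: Sequence[Sequence[float]] | None = None,
    fixed: dict[str, float] | None = None,
) -> AbcChainHistory:
    """Sample the behavioral parameter region around the compromise fit.

    Chains start uniformly in the prior box (uniform prior on the natural
    parameter scale).  Proposals are differential-evolution jumps built
    from two distinct members of a thinned past-states archive, scaled by
    gamma = 2.38/sqrt(2d) (gamma = 1 for a 10% minority of jumps) plus a
    small jitter, reflected back into the prior box.  A proposal is
    accepted when its OF2 fitness is at least the current state's, or when
    it is behavioral (OF2 >= 0).  Fully reproducible from ``config.seed``.

    Raises :class:`NoBehavioralSampleError` if no chain ever becomes
    behavioral — retry with larger epsilons or more generations.
    """
    rng = np.random.default_rng(config.seed)
    free_names, build = free_param_info(spec, fixed)
    bounds = np.asarray(
        prior_bounds if prior_bounds is not None else spec.bounds_array(), dtype=float
    )
    if bounds.shape[0] == len(spec.param_names) and fixed:
        keep = [i for i, n in enumerate(spec.param_names) if n in free_names]
        bounds = bounds[keep]
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi <= lo) or not np.all(np.isfinite(bounds)):
        raise ValueError("prior_bounds must be a finite box with high > low")
    d = lo.size
    if d != len(free_names):
        raise ValueError(
            f"prior_bounds rows ({d}) must match the free parameter count "
            f"({len(free_names)})"
        )
    nC = config.n_chains
    nG = config.n_generations
    gamma_de = 2.38 / np.sqrt(2.0 * d)
    jitter_sd = config.jitter_rel * (hi - lo)
    monitor = config.monitor_every or max(nG // 100, 1)

    def fitness_of(x: np.ndarray) -> float:
        params = build(x)
        pred = integrate(spec, params, dataset.S0, dataset.C0, dataset.times)
        return of2_abc(of_mo(dataset, pred), target)

    state = lo + (hi - lo) * rng.random((nC, d))
    fit = np.array([fitness_of(x) for x in state])

    # preallocated past-states archive; grows by one block per thin interval
    archive = np.empty((nC * (2 + nG // config.archive_thin), d))
    archive[:nC] = state
    nA = nC
    samples = np.empty((nC, nG, d))
    fitness = np.empty((nC, nG))
    accepted = np.zeros((nC, nG), dtype=bool)
    r_trace: list[tuple[int, float]] = []

    for g in range(nG):
        for c in range(nC):
            i = rng.integers(nA)
            j = rng.integers(nA - 1)
            if j >= i:
                j += 1
            gamma = 1.0 if rng.random() < config.gamma_one_prob else gamma_de
            prop = state[c] + gamma * (archive[i] - archive[j]) + rng.normal(0.0, jitter_sd)
            prop = _reflect_into_box(prop, lo, hi)
            f_prop = fitness_of(prop)
            # monotone climb into the behavioral region, then free movement
            # anywhere inside it (OF2 >= 0)
            if f_prop >= min(fit[c], 0.0):
                state[c], fit[c] = prop, f_prop
                accepted[c, g] = True
        samples[:, g, :] = state
        fitness[:, g] = fit
        if (g + 1) % config.archive_thin == 0:
            archive[nA:nA + nC] = state
            nA += nC
        if (g + 1) % monitor == 0 and g > 10:
            r_trace.append((g + 1, gelman_rubin(samples[:, : g + 1, :])))

    if fitness.max() < 0:
        raise NoBehavioralSampleError(
            "no behavioral sample (OF2 >= 0) found within "
            f"{nG} generations; best fitness {fitness.max():.4g}. "
            "Increase the epsilons or the generation budget."
        )
    return AbcChainHistory(
        samples=samples,
        fitness=fitness,
        accepted=accepted,
        R_trace=np.asarray(r_trace, dtype=float).reshape(-1, 2),
        param_names=free_names,
        prior_bounds=bounds,
        target=target,
        seed=config.seed,
        fixed=dict(fixed or {}),
    )


def gelman_rubin(samples: np.ndarray, use_second_half: bool = True) -> float:
    """Overall Gelman-Rubin potential scale reduction factor.

    ``samples`` is (n_chains, n_draws, d) (a 2-D array is treated as one
    parameter).  By convention the second half of each chain is used.  Per
    parameter, with W the mean within-chain variance and B/n the variance
    of chain means,  R = sqrt( ((n-1)/n * W + B/n) / W ); the overall
    statistic is the maximum over parameters.  Returns NaN (degenerate) if
    every chain has zero variance for some parameter and the chains agree.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim == 2:
        s = s[:, :, None]
    if s.ndim != 3 or s.shape[0] < 2:
        raise ValueError("need (n_chains >= 2, n_draws, d) samples")
    if use_second_half:
        s = s[:, s.shape[1] // 2:, :]
    m, n, d = s.shape
    if n < 2:
        raise ValueError("need at least 2 retained draws per chain")
    means = s.mean(axis=1)                    # (m, d)
    W = s.var(axis=1, ddof=1).mean(axis=0)    # (d,)
    Bn = means.var(axis=0, ddof=1)            # B/n, (d,)
    R = np.empty(d)
    for k in range(d):
        if W[k] > 0:
            R[k] = np.sqrt((n - 1) / n + Bn[k] / W[k])
        else:
            R[k] = np.nan if Bn[k] == 0 else np.inf
    return float(np.nanmax(R)) if not np.all(np.isnan(R)) else float("nan")


def chain_mean_trace(history: AbcChainHistory) -> np.ndarray:
    """Across-chain mean parameter values per generation, (n_generations, d).

    Stabilization of this trace over the final generations is the standard
    identifiability diagnostic: a converged, identifiable run shows the
    final-20% relative drift of every parameter below a few percent.
    """
    return history.samples.mean(axis=0)


def final_drift(
    history: AbcChainHistory,
    tail_fraction: float = 0.2,
    burn_in_fraction: float = 0.5,
) -> float:
    """Stabilization measure of the posterior-mean estimate.

    Takes the running mean of the across-chain trace (post burn-in) and
    returns the maximum relative deviation from its final value over the
    last ``tail_fraction`` of generations.  A converged, identifiable run
    drifts by only a few percent; an unconverged one keeps trending.
    """
    trace = chain_mean_trace(history)
    trace = trace[int(trace.shape[0] * burn_in_fraction):]
    running = np.cumsum(trace, axis=0) / np.arange(1, trace.shape[0] + 1)[:, None]
    tail = running[int(running.shape[0] * (1.0 - tail_fraction)):]
    ref = np.abs(tail[-1])
    ref = np.where(ref > 0, ref, 1.0)
    return float(np.max(np.abs(tail - tail[-1]) / ref))


def summarize_posterior(
    history: AbcChainHistory,
    spec: KineticModelSpec,
    dataset: BatchDataset,
    burn_in_fraction: float = 0.5,
    n_trajectory_draws: int = 300,
    n_dense_times: int = 101,
    residual_sd_log10: float | None = None,
    require_converged: bool = True,
    r_threshold: float = 1.2,
) -> PosteriorSummary:
    """Posterior moments, 95% intervals and trajectory uncertainty bands.

    Refuses to summarize an unconverged history (final overall R above
    ``r_threshold``) unless ``require_converged`` is False.  The parameter
    band comes from integrating trajectories at (up to) ``n_trajectory_draws``
    evenly-thinned posterior draws; the predictive band multiplies the
    parameter band by 10**(+-1.96 * residual_sd_log10), the log10 residual
    noise scale of the compromise fit (estimated from the posterior median
    trajectory's residuals when not supplied).
    """
    if require_converged:
        R = history.final_R()
        if not (R < r_threshold):
            raise RuntimeError(
                f"history not converged (overall R = {R:.3f} >= {r_threshold}); "
                "pass require_converged=False to override"
            )
    draws = history.posterior_draws(burn_in_fraction)
    if draws.shape[0] < 500:
        raise ValueError(f"too few post-burn-in draws ({draws.shape[0]} < 500)")

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    q025, q975 = np.percentile(draws, [2.5, 97.5], axis=0)

    step = max(draws.shape[0] // n_trajectory_draws, 1)
    sub = draws[::step][:n_trajectory_draws]
    times = np.linspace(0.0, float(dataset.times[-1]), n_dense_times)
    _, build = free_param_info(spec, history.fixed)
    S_all = np.empty((sub.shape[0], times.size))
    C_all = np.empty_like(S_all)
    for i, vec in enumerate(sub):
        pred = integrate(spec, build(vec), dataset.S0, dataset.C0, times)
        S_all[i], C_all[i] = pred.S_pred, pred.C_pred

    S_med = np.median(S_all, axis=0)
    C_med = np.median(C_all, axis=0)
    S_band = np.percentile(S_all, [2.5, 97.5], axis=0)
    C_band = np.percentile(C_all, [2.5, 97.5], axis=0)

    if residual_sd_log10 is None:
        S_at = np.interp(dataset.times, times, S_med)
        C_at = np.interp(dataset.times, times, C_med)
        res = np.concatenate([
            np.log10(dataset.S_obs) - np.log10(np.maximum(S_at, 1e-12)),
            np.log10(dataset.C_obs) - np.log10(np.maximum(C_at, 1e-12)),
        ])
        residual_sd_log10 = float(res.std(ddof=1)) if res.size > 1 else 0.0
    widen = 10.0 ** (1.959963984540054 * residual_sd_log10)
    S_pred_band = np.vstack([S_band[0] / widen, S_band[1] * widen])
    C_pred_band = np.vstack([C_band[0] / widen, C_band[1] * widen])

    return PosteriorSummary(
        param_names=history.param_names,
        mean=mean,
        sd=sd,
        q025=q025,
        q975=q975,
        n_draws=draws.shape[0],
        times=times,
        S_median=S_med,
        C_median=C_med,
        S_band=S_band,
        C_band=C_band,
        S_predictive=S_pred_band,
        C_predictive=C_pred_band,
        residual_sd_log10=residual_sd_log10,
    )
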