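"""Forward ODE integration and synthetic batch-experiment generation.

Batch biodegradation experiments observe two variables at a handful of
roughly daily timepoints: the substrate (pollutant) concentration S and a
cell measurement C (optical density or plate counts), usually as the mean
of <= 3 replicates.  The generator here emulates that structure: a true
trajectory from the coupled growth/depletion ODEs plus multiplicative
lognormal noise — homoscedastic on the log10 scale, matching the error
model the fitting objectives assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

from .models import KineticModelSpec, KineticParams

__all__ = [
    "BatchDataset",
    "TrajectoryPrediction",
    "SyntheticDesign",
    "integrate",
    "generate_synthetic",
]

STATE_FLOOR = 1e-12


@dataclass
class BatchDataset:
    """Observed two-variable batch time series.

    times are hours, strictly increasing, starting at 0; S_obs/C_obs are
    replicate means (all strictly positive — the objectives take log10);
    S_sd/C_sd are optional per-timepoint replicate standard deviations.
    S0/C0 are the known initial conditions (defaults: first observation).
    """

    times: np.ndarray
    S_obs: np.ndarray
    C_obs: np.ndarray
    S_sd: np.ndarray | None = None
    C_sd: np.ndarray | None = None
    S0: float | None = None
    C0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S_obs = np.asarray(self.S_obs, dtype=float)
        self.C_obs = np.asarray(self.C_obs, dtype=float)
        n = self.times.size
        if self.S_obs.size != n or self.C_obs.size != n:
            raise ValueError("times, S_obs and C_obs must have equal lengths")
        if n < 2:
            raise ValueError("need at least two timepoints")
        if self.times[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("S_obs", "C_obs"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                bad = int(np.flatnonzero(~(arr > 0))[0])
                raise ValueError(
                    f"{name}[{bad}] = {arr[bad]} is not strictly positive; "
                    "log10 observations are required downstream"
                )
        for name in ("S_sd", "C_sd"):
            sd = getattr(self, name)
            if sd is not None:
                sd = np.asarray(sd, dtype=float)
                if sd.size != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, sd)
        if self.S0 is None:
            self.S0 = float(self.S_obs[0])
        if self.C0 is None:
            self.C0 = float(self.C_obs[0])
        if not (self.S0 > 0 and self.C0 > 0):
            raise ValueError("S0 and C0 must be strictly positive")

    @property
    def n_times(self) -> int:
        return int(self.times.size)


@dataclass
class TrajectoryPrediction:
    """Model trajectory at requested times.

    S_pred/X_pred in mg/L; C_pred = X_pred / b in measurement units.
    ``penalized`` marks an integrator failure: downstream objectives then
    return a large finite penalty instead of crashing the optimizer.
    """

    times: np.ndarray
    S_pred: np.ndarray
    X_pred: np.ndarray
    C_pred: np.ndarray
    penalized: bool = False


@dataclass
class SyntheticDesign:
    """Design of an emulated batch experiment.

    Defaults emulate the sparse published experiments the workflow is aimed
    at: 10 daily samples over 9 days (216 h), 3 replicates, and lognormal
    noise with sd 0.02 on the log10 scale (~5% coefficient of variation).
    """

    S0: float = 50.0
    C0: float = 0.05
    n_timepoints: int = 10
    duration_h: float = 216.0
    n_replicates: int = 3
    noise_sd_log10: float = 0.02

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (self.S0 > 0 and self.C0 > 0):
            raise ValueError("S0 and C0 must be positive")


def integrate(
    spec: KineticModelSpec,
    params: KineticParams,
    S0: float,
    C0: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TrajectoryPrediction:
    """Integrate the coupled batch ODEs from (S0, X0=b*C0) over ``times``.

    Uses LSODA (stiff-capable, adaptive).  Returned states are floored at
    1e-12; a solver failure yields a prediction flagged ``penalized``
    rather than an exception, so optimization objectives stay finite.
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted, strictly increasing, starting at 0")
    if not (S0 > 0 and C0 > 0):
        raise ValueError("S0 and C0 must be positive")
    spec.validate_params(params)

    law = spec.growth_law
    inv_Y = 1.0 / params.Y
    kd = params.kd
    X0 = params.b * C0

    def rhs(y, t):
        S = y[0] if y[0] > 0.0 else 0.0
        X = y[1] if y[1] > 0.0 else 0.0
        mu = law(S, X, params)
        return (-inv_Y * mu * X, (mu - kd) * X)

    with np.errstate(all="ignore"):
        y, info = odeint(
            rhs,
            (float(S0), float(X0)),
            times,
            rtol=rtol,
            atol=atol,
            full_output=True,
            mxstep=10_000,
            printmessg=False,
        )
    ok = info["message"] == "Integration successful." and np.all(np.isfinite(y))
    y = np.where(np.isfinite(y), y, STATE_FLOOR)
    S_pred = np.maximum(y[:, 0], STATE_FLOOR)
    X_pred = np.maximum(y[:, 1], STATE_FLOOR)
    return TrajectoryPrediction(
        times=times,
        S_pred=S_pred,
        X_pred=X_pred,
        C_pred=X_pred / params.b,
        penalized=not ok,
    )


def generate_synthetic(
    spec: KineticModelSpec,
    params: KineticParams,
    design: SyntheticDesign,
    seed: int | np.random.SeedSequence,
) -> BatchDataset:
    """Simulate a replicated batch experiment under ``design``.

    Each replicate observation is truth * 10**eps with
    eps ~ Normal(0, noise_sd_log10), i.i.d. per variable and timepoint;
    the dataset holds replicate means and (for >= 2 replicates) standard
    deviations.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, design.duration_h, design.n_timepoints)
    truth = integrate(spec, params, design.S0, design.C0, times)
    if truth.penalized:
        raise RuntimeError("true-trajectory integration failed for this design")
    for name, arr in (("substrate", truth.S_pred), ("cells", truth.C_pred)):
        if np.any(arr < 1e-10):
            raise ValueError(
                f"true {name} trajectory falls below 1e-10 within the design "
                "window; shorten duration_h (log-scale noise is undefined at 0)"
            )
    if design.noise_sd_log10 == 0.0:
        S_obs, C_obs = truth.S_pred.copy(), truth.C_pred.copy()
        S_sd = np.zeros_like(S_obs)
        C_sd = np.zeros_like(C_obs)
    else:
        shape = (design.n_replicates, design.n_timepoints)
        S_reps = truth.S_pred * 10.0 ** rng.normal(0.0, design.noise_sd_log10, shape)
        C_reps = truth.C_pred * 10.0 ** rng.normal(0.0, design.noise_sd_log10, shape)
        S_obs = S_reps.mean(axis=0)
        C_obs = C_reps.mean(axis=0)
        ddof = 1 if design.n_replicates > 1 else 0
        S_sd = S_reps.std(axis=0, ddof=ddof)
        C_sd = C_reps.std(axis=0, ddof=ddof)
    return BatchDataset(
        times=times,
        S_obs=S_obs,
        C_obs=C_obs,
        S_sd=S_sd,
        C_sd=C_sd,
        S0=design.S0,
        C0=design.C0,
    )
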