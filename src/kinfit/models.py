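"""Registry of unstructured kinetic growth laws and the batch ODE system.

Unstructured models treat the degrading biomass as a single lumped state X
(mg/L) whose specific growth rate mu (1/h) is a nonlinear function of the
limiting substrate concentration S (mg/L) and, for some laws, of X itself.
All laws plug into the same coupled batch mass balance with endogenous
decay:

    dS/dt = -(1/Y) * mu(S, X) * X
    dX/dt =  mu(S, X) * X - kd * X

where Y is the biomass yield per substrate consumed (dimensionless), kd the
first-order endogenous decay rate (1/h).  Biomass is observed indirectly
(optical density or plate counts C); X = b * C with b a fitted linear
scaling factor.

Eight laws are registered, addressable by id 1-8 or name: Monod, Tessier,
Contois, Blackman, Dabes, Powell, Moser, Heijnen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

__all__ = [
    "KineticParams",
    "KineticModelSpec",
    "SystemState",
    "MODEL_REGISTRY",
    "get_model",
    "list_models",
    "growth_rate",
    "ode_rhs",
]

CORE_PARAM_NAMES = ("mu_max", "Ks", "Y", "kd", "b")

#: Broad positive default search boxes, scaled per parameter.  Growth rates
#: for pollutant degraders are fractions of 1/h; half-saturation constants
#: span 1e-2..1e3 mg/L; yields are O(1); decay is slow; b and the Moser
#: exponent are O(1).  Overridable everywhere bounds are accepted.
DEFAULT_CORE_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_max": (1e-3, 1e1),
    "Ks": (1e-2, 1e3),
    "Y": (1e-2, 1e1),
    "kd": (1e-4, 1e0),
    "b": (1e-2, 1e2),
}
DEFAULT_EXTRA_BOUNDS: dict[str, tuple[float, float]] = {
    "n": (3e-1, 1e1),       # Moser exponent
    "Ksx": (1e-3, 1e2),     # Contois constant (per unit biomass)
    "A": (1e-3, 1e2),       # Dabes linear constant (h)
    "L": (1e-2, 1e3),       # Powell diffusion-resistance constant (mg/L)
}


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameter set shared by all registered growth laws.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate (1/h).
    Ks : float
        Half-saturation constant (mg/L).
    Y : float
        Yield coefficient, biomass formed per substrate consumed
        (dimensionless, both in mg/L).
    kd : float
        Endogenous decay coefficient (1/h).
    b : float
        Linear scaling from the cell measurement (OD or counts) to biomass
        concentration: X = b * C.
    extras : mapping
        Model-specific parameters, e.g. ``{"n": 2.0}`` for Moser.

    All values must be strictly positive.
    """

    mu_max: float
    Ks: float
    Y: float
    kd: float
    b: float
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # mu_max=0 (growth switched off) and kd=0 (no decay) are physically
        # meaningful limits; the remaining parameters appear in denominators
        for name in ("mu_max", "kd"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be non-negative and finite, got {v}")
        for name in ("Ks", "Y", "b"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be strictly positive and finite, got {v}")
        for k, v in self.extras.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"extra parameter {k!r} must be strictly positive and finite, got {v}")

    def as_vector(self, spec: "KineticModelSpec") -> list[float]:
        """Ordered values following ``spec.param_names``."""
        out = [getattr(self, n) for n in CORE_PARAM_NAMES]
        out.extend(self.extras[n] for n in spec.extra_names)
        return out

    @staticmethod
    def from_vector(spec: "KineticModelSpec", vec) -> "KineticParams":
        """Inverse of :meth:`as_vector`."""
        vec = list(map(float, vec))
        if len(vec) != len(spec.param_names):
            raise ValueError(
                f"{spec.name} expects {len(spec.param_names)} parameters "
                f"({', '.join(spec.param_names)}), got {len(vec)}"
            )
        core = dict(zip(CORE_PARAM_NAMES, vec[:5]))
        extras = dict(zip(spec.extra_names, vec[5:]))
        return KineticParams(**core, extras=extras)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous batch state: substrate S and biomass X, both mg/L, >= 0."""

    S: float
    X: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.X < 0:
            raise ValueError(f"state components must be non-negative, got S={self.S}, X={self.X}")


@dataclass(frozen=True)
class KineticModelSpec:
    """A registered growth law.

    ``growth_law(S, X, params) -> mu`` returns the specific growth rate in
    1/h; it must return 0 at S=0 and be non-negative on the feasible domain.
    ``extra_names`` lists model-specific parameters beyond the shared core
    five (mu_max, Ks, Y, kd, b).
    """

    model_id: int
    name: str
    growth_law: Callable[[float, float, KineticParams], float]
    extra_names: tuple[str, ...] = ()
    literature_sourced: bool = False

    @property
    def param_names(self) -> tuple[str, ...]:
        return CORE_PARAM_NAMES + self.extra_names

    @property
    def default_bounds(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_CORE_BOUNDS)
        for n in self.extra_names:
            out[n] = DEFAULT_EXTRA_BOUNDS[n]
        return out

    def bounds_array(self, overrides: Mapping[str, tuple[float, float]] | None = None):
        """Per-parameter [low, high] rows ordered like ``param_names``."""
        b = self.default_bounds
        if overrides:
            b.update(overrides)
        return [list(map(float, b[n])) for n in self.param_names]

    def validate_params(self, params: KineticParams) -> None:
        missing = set(self.extra_names) - set(params.extras)
        if missing:
            raise ValueError(f"{self.name} requires extra parameter(s) {sorted(missing)}")
        unexpected = set(params.extras) - set(self.extra_names)
        if unexpected:
            raise ValueError(f"{self.name} does not accept extra parameter(s) {sorted(unexpected)}")


# --- the eight growth laws -------------------------------------------------

def _monod(S: float, X: float, p: KineticParams) -> float:
    # mu = mu_max * S / (Ks + S)
    return p.mu_max * S / (p.Ks + S) if S > 0 else 0.0


def _tessier(S: float, X: float, p: KineticParams) -> float:
    # mu = mu_max * (1 - exp(-S/Ks)); exponential saturation (Tessier 1942).
    return p.mu_max * -math.expm1(-S / p.Ks) if S > 0 else 0.0


def _contois(S: float, X: float, p: KineticParams) -> float:
    """Contois (1959): mu = mu_max * S / (Ksx*X + S).

    Biomass-dependent apparent affinity via the extra parameter Ksx; the
    core Ks is retained for interface uniformity but is inert in this law.
    Literature-sourced form.
    """
    if S <= 0:
        return 0.0
    ksx = p.extras["Ksx"]
    return p.mu_max * S / (ksx * X + S)


def _blackman(S: float, X: float, p: KineticParams) -> float:
    # Blackman (1905) piecewise-linear: mu = mu_max * min(1, S/Ks).
    return p.mu_max * min(1.0, S / p.Ks) if S > 0 else 0.0


def _dabes(S: float, X: float, p: KineticParams) -> float:
    """Dabes, Finn & Wilke (1973) implicit law: S = A*mu + Ks*mu/(mu_max - mu).

    Interpolates between Blackman and Monod behaviour.  Solved here as the
    physical (smaller) root of the quadratic
        A*mu^2 - (A*mu_max + Ks + S)*mu + S*mu_max = 0,
    which satisfies 0 <= mu < mu_max, mu(0)=0.  Literature-sourced form.
    """
    if S <= 0:
        return 0.0
    A = p.extras["A"]
    bq = A * p.mu_max + p.Ks + S
    disc = bq * bq - 4.0 * A * S * p.mu_max
    disc = max(disc, 0.0)
    # smaller root, written in the numerically stable form
    return 2.0 * S * p.mu_max / (bq + math.sqrt(disc))


def _powell(S: float, X: float, p: KineticParams) -> float:
    """Powell (1967) diffusion-limited law:

        mu = (mu_max / (2L)) * (S + Ks + L - sqrt((S + Ks + L)^2 - 4*L*S))

    L (mg/L) lumps cell-boundary mass-transfer resistance; L -> 0 recovers
    Monod.  Literature-sourced form.
    """
    if S <= 0:
        return 0.0
    L = p.extras["L"]
    t = S + p.Ks + L
    disc = max(t * t - 4.0 * L * S, 0.0)
    # stable form of the smaller root times mu_max/(2L)
    return p.mu_max * 2.0 * S / (t + math.sqrt(disc))


def _moser(S: float, X: float, p: KineticParams) -> float:
    # Moser (1958), Hill-type: mu = mu_max * S^n / (Ks + S^n); n=1 is Monod.
    if S <= 0:
        return 0.0
    Sn = S ** p.extras["n"]
    return p.mu_max * Sn / (p.Ks + Sn)


def _heijnen(S: float, X: float, p: KineticParams) -> float:
    """Heijnen & Romein (1995): mu = mu_max * (2^(S/(Ks+S)) - 1).

    Saturates at mu_max as S -> inf and vanishes at S=0.
    Literature-sourced form.
    """
    if S <= 0:
        return 0.0
    return p.mu_max * math.expm1(math.log(2.0) * S / (p.Ks + S))


_SPECS = [
    KineticModelSpec(1, "Monod", _monod),
    KineticModelSpec(2, "Tessier", _tessier),
    KineticModelSpec(3, "Contois", _contois, ("Ksx",), literature_sourced=True),
    KineticModelSpec(4, "Blackman", _blackman),
    KineticModelSpec(5, "Dabes", _dabes, ("A",), literature_sourced=True),
    KineticModelSpec(6, "Powell", _powell, ("L",), literature_sourced=True),
    KineticModelSpec(7, "Moser", _moser, ("n",)),
    KineticModelSpec(8, "Heijnen", _heijnen, literature_sourced=True),
]

MODEL_REGISTRY: dict[int, KineticModelSpec] = {s.model_id: s for s in _SPECS}
_BY_NAME: dict[str, KineticModelSpec] = {s.name.lower(): s for s in _SPECS}


def get_model(key: int | str) -> KineticModelSpec:
    """Look up a registered growth law by integer id (1-8) or name."""
    if isinstance(key, str):
        try:
            return _BY_NAME[key.lower()]
        except KeyError:
            raise KeyError(f"unknown model name {key!r}; known: {[s.name for s in _SPECS]}") from None
    try:
        return MODEL_REGISTRY[int(key)]
    except (KeyError, ValueError):
        raise KeyError(f"unknown model id {key!r}; known ids 1-8") from None


def list_models() -> list[KineticModelSpec]:
    """All registered laws in id order."""
    return list(_SPECS)


def free_param_info(
    spec: KineticModelSpec, fixed: Mapping[str, float] | None
) -> tuple[tuple[str, ...], Callable]:
    """Support for restricted fits with some parameters pinned.

    Returns the free parameter names (spec order) and a builder mapping a
    free-parameter vector to a full :class:`KineticParams` with the fixed
    values inserted.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(spec.param_names)
    if unknown:
        raise ValueError(f"fixed parameter(s) {sorted(unknown)} not in {spec.name}'s parameters")
    names = spec.param_names
    free_names = tuple(n for n in names if n not in fixed)
    free_idx = [i for i, n in enumerate(names) if n not in fixed]
    template = [fixed.get(n, 0.0) for n in names]

    def build(free_values) -> KineticParams:
        full = list(template)
        for i, v in zip(free_idx, free_values):
            full[i] = float(v)
        return KineticParams.from_vector(spec, full)

    return free_names, build


def growth_rate(spec: KineticModelSpec, S: float, X: float, params: KineticParams) -> float:
    """Specific growth rate mu (1/h) of ``spec``'s law at (S, X).

    Raises on missing/unexpected extra parameters or negative state.
    """
    if S < 0 or X < 0:
        raise ValueError(f"S and X must be non-negative, got S={S}, X={X}")
    spec.validate_params(params)
    mu = spec.growth_law(S, X, params)
    if not math.isfinite(mu):
        raise FloatingPointError(
            f"non-finite growth rate from {spec.name} at S={S}, X={X}"
        )
    return mu


def ode_rhs(spec: KineticModelSpec, state: SystemState, params: KineticParams) -> tuple[float, float]:
    """Right-hand side (dS/dt, dX/dt) of the batch balance at ``state``.

    dS/dt = -(1/Y) mu X;  dX/dt = (mu - kd) X.
    """
    mu = growth_rate(spec, state.S, state.X, params)
    dS = -(1.0 / params.Y) * mu * state.X
    dX = (mu - params.kd) * state.X
    return dS, dX
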