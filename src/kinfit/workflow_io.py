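"""Pipeline orchestration, dataset CSV dialect, and result persistence.

The three estimation steps are chained here: single-objective extremes +
compromise, multi-objective front with SO cross-verification, then ABC
targeting the verified compromise statistics.  Stage seeds derive
deterministically from one master seed; every artifact embeds the config
hash and seed so mixed-provenance result directories are detectable.

Dataset CSV dialect: header ``time_h,S_mean,S_sd,C_mean,C_sd``; empty sd
fields mean "absent", not zero; ``#``-prefixed comment rows above the
header carry metadata (S0, C0, units).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abc_sampler import (
    AbcChainHistory,
    AbcConfig,
    PosteriorSummary,
    abc_sample,
    summarize_posterior,
)
from .diagnostics import format_report, workflow_report
from .models import KineticModelSpec, get_model
from .objectives import AbcTarget
from .optimize_mo import MoRunConfig, fit_pareto, select_compromise, verify_against_so
from .optimize_so import SoRunConfig, fit_extremes_and_compromise
from .simulate import BatchDataset

__all__ = [
    "WorkflowConfig",
    "WorkflowResult",
    "run_workflow",
    "read_dataset",
    "write_dataset",
    "write_results",
    "load_config",
]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class WorkflowConfig:
    """Configuration of one end-to-end estimation run.

    ``bounds`` optionally overrides per-parameter [low, high] boxes (dict
    keyed by parameter name).  ``skip_mo`` drops step 2 and targets the ABC
    stage at the single-objective compromise statistics instead — the
    documented cheap variant, at some loss of cross-verification.
    """

    model: int | str = "Monod"
    seed: int = 0
    bounds: dict | None = None
    fixed: dict | None = None
    so: SoRunConfig = field(default_factory=SoRunConfig)
    mo: MoRunConfig = field(default_factory=MoRunConfig)
    abc: AbcConfig = field(default_factory=AbcConfig)
    skip_mo: bool = False
    abc_rel_eps: float = 0.05
    abc_min_eps: float = 0.01
    so_mo_rel_tol: float = 0.05

    def stage_seeds(self) -> dict[str, int]:
        so, mo, abc = np.random.SeedSequence([self.seed, 7]).generate_state(3) % (2**31)
        return {"so": int(so), "mo": int(mo), "abc": int(abc)}

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class WorkflowResult:
    """Artifacts from one pipeline run."""

    config: WorkflowConfig
    spec: KineticModelSpec
    dataset: BatchDataset
    so_results: dict
    mo_front: object | None
    verification: dict | None
    abc_target: AbcTarget
    abc_history: AbcChainHistory
    posterior: PosteriorSummary
    report: dict


def run_workflow(config: WorkflowConfig, dataset: BatchDataset) -> WorkflowResult:
    """Run steps 1-3 on a dataset and return all artifacts plus a report.

    Step order: per-variable extreme fits + joint compromise fit (saDE);
    Pareto front with compromise selection (skipped under ``skip_mo``),
    cross-verified against the step-1 compromise (a failed check only
    warns — the report records it); ABC sampling targeting the compromise
    SSR statistics, with Gelman-Rubin monitoring and posterior bands.
    """
    spec = get_model(config.model)
    bounds = spec.bounds_array(config.bounds)
    seeds = config.stage_seeds()

    so_results = fit_extremes_and_compromise(
        spec, dataset, bounds, replace(config.so, seed=seeds["so"]), fixed=config.fixed
    )
    so_comp = so_results["compromise"].best_objective

    mo_front = None
    verification = None
    if config.skip_mo:
        target_ssrs = (so_comp.ssr_subs, so_comp.ssr_cells)
    else:
        mo_front = fit_pareto(
            spec, dataset, bounds, replace(config.mo, seed=seeds["mo"]), fixed=config.fixed
        )
        _, comp_vec = select_compromise(mo_front)
        verification = verify_against_so(comp_vec, so_comp, config.so_mo_rel_tol)
        # convergence diagnostic proper: the front member with the smallest
        # joint total is the fair comparator for the SO optimum (the selected
        # compromise may legitimately sit elsewhere on an asymmetric front)
        front_min_total = float(mo_front.objectives.sum(axis=1).min())
        verification["front_min_total"] = front_min_total
        verification["front_min_gap"] = abs(front_min_total - so_comp.total) / max(
            so_comp.total, 1e-12
        )
        target_ssrs = (float(comp_vec[0]), float(comp_vec[1]))

    target = AbcTarget.from_compromise(
        *target_ssrs, rel_eps=config.abc_rel_eps, min_eps=config.abc_min_eps
    )
    history = abc_sample(
        spec, dataset, target, replace(config.abc, seed=seeds["abc"]),
        prior_bounds=bounds, fixed=config.fixed,
    )
    posterior = summarize_posterior(history, spec, dataset, require_converged=False)

    report = workflow_report(
        so_results=so_results,
        mo_front=mo_front,
        abc_history=history,
        abc_summary=posterior,
        so_mo_verification=verification,
    )
    report["meta"] = {
        "schema_version": SCHEMA_VERSION,
        "model": spec.name,
        "model_id": spec.model_id,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "skip_mo": config.skip_mo,
        "abc_target": {
            "observed_stats": target.observed_stats.tolist(),
            "epsilons": target.epsilons.tolist(),
        },
    }
    return WorkflowResult(
        config=config, spec=spec, dataset=dataset, so_results=so_results,
        mo_front=mo_front, verification=verification, abc_target=target,
        abc_history=history, posterior=posterior, report=report,
    )


# --- dataset CSV dialect ---------------------------------------------------

def write_dataset(dataset: BatchDataset, path: str | Path) -> Path:
    """Write a dataset in the package CSV dialect (lossless round-trip)."""
    path = Path(path)
    df = pd.DataFrame({
        "time_h": dataset.times,
        "S_mean": dataset.S_obs,
        "S_sd": dataset.S_sd if dataset.S_sd is not None else np.nan,
        "C_mean": dataset.C_obs,
        "C_sd": dataset.C_sd if dataset.C_sd is not None else np.nan,
    })
    with open(path, "w") as fh:
        fh.write(f"# S0={dataset.S0!r} mg/L\n")
        fh.write(f"# C0={dataset.C0!r} measurement units\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_dataset(path: str | Path) -> BatchDataset:
    """Read and validate a dataset CSV.

    Rejects non-positive observations (naming the offending row) and
    unsorted times; missing sd fields parse as absent, not zero.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, rest = body.split("=", 1)
                try:
                    meta[key.strip()] = float(rest.split()[0])
                except ValueError:
                    pass
    df = pd.read_csv(path, comment="#")
    required = {"time_h", "S_mean", "C_mean"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required column(s) {sorted(required - set(df.columns))}")
    times = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time_h must be strictly increasing")
    for col in ("S_mean", "C_mean"):
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            raise ValueError(
                f"{path}: {col} must be strictly positive (log10 fitting); "
                f"offending data row {bad[0] + 1} (value {vals[bad[0]]})"
            )

    def _sd(col: str):
        if col not in df.columns or df[col].isna().all():
            return None
        return df[col].to_numpy(dtype=float)

    return BatchDataset(
        times=times,
        S_obs=df["S_mean"].to_numpy(dtype=float),
        C_obs=df["C_mean"].to_numpy(dtype=float),
        S_sd=_sd("S_sd"),
        C_sd=_sd("C_sd"),
        S0=meta.get("S0"),
        C0=meta.get("C0"),
    )


# --- results persistence ---------------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def write_results(result: WorkflowResult, out_dir: str | Path) -> dict[str, Path]:
    """Persist a run's artifacts under ``out_dir``.

    Writes report.json / report.txt, the Pareto front as CSV (one row per
    member: objectives then parameters), thinned ABC samples as CSV, and
    the R-statistic trace.  Every file family shares the embedded config
    hash in report.json's meta block.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report_json"] = out / "report.json"
    with open(paths["report_json"], "w") as fh:
        json.dump(_to_jsonable(result.report), fh, indent=2)
    paths["report_txt"] = out / "report.txt"
    paths["report_txt"].write_text(format_report(result.report) + "\n")

    if result.mo_front is not None:
        names = result.mo_front.param_names or result.spec.param_names
        rows = np.column_stack([
            result.mo_front.objectives,
            10.0 ** result.mo_front.decisions,
        ])
        front_df = pd.DataFrame(rows, columns=["ssr_subs", "ssr_cells", *names])
        paths["front_csv"] = out / "pareto_front.csv"
        front_df.to_csv(paths["front_csv"], index=False, float_format="%.10g")

    hist = result.abc_history
    thin = max(hist.n_generations // 200, 1)
    gens = np.arange(hist.n_generations)[::thin]
    recs = []
    for c in range(hist.n_chains):
        for g in gens:
            recs.append((c, int(g), *hist.samples[c, g], float(hist.fitness[c, g])))
    abc_df = pd.DataFrame(recs, columns=["chain", "generation", *hist.param_names, "of2"])
    paths["abc_samples_csv"] = out / "abc_samples.csv"
    abc_df.to_csv(paths["abc_samples_csv"], index=False, float_format="%.8g")

    paths["r_trace_csv"] = out / "r_trace.csv"
    pd.DataFrame(hist.R_trace, columns=["generation", "overall_R"]).to_csv(
        paths["r_trace_csv"], index=False
    )
    return paths


def load_config(path: str | Path) -> WorkflowConfig:
    """Build a :class:`WorkflowConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``so``/``mo``/``abc``
    blocks map onto the stage config dataclasses.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("model", "seed", "bounds", "fixed", "skip_mo",
                "abc_rel_eps", "abc_min_eps", "so_mo_rel_tol"):
        if key in raw:
            kwargs[key] = raw[key]
    if "so" in raw:
        kwargs["so"] = SoRunConfig(**raw["so"])
    if "mo" in raw:
        kwargs["mo"] = MoRunConfig(**raw["mo"])
    if "abc" in raw:
        kwargs["abc"] = AbcConfig(**raw["abc"])
    if "bounds" in kwargs and kwargs["bounds"] is not None:
        kwargs["bounds"] = {k: tuple(map(float, v)) for k, v in kwargs["bounds"].items()}
    return WorkflowConfig(**kwargs)
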