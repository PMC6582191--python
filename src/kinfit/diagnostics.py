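"""Residual-assumption checks and cross-stage reporting.

The fitting objectives assume log10-scale residuals that are independent,
zero-mean normal and homoscedastic.  With 5-10 timepoints per variable no
formal heteroscedasticity test is reliable, so homoscedasticity is
reported descriptively (variance of the first vs. second half of each
residual series); normality uses an omnibus test where the sample permits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .objectives import residuals as _residuals
from .simulate import BatchDataset, TrajectoryPrediction

__all__ = ["ResidualReport", "residual_report", "workflow_report", "format_report"]


@dataclass
class VariableResiduals:
    """Per-variable residual moments and checks (log10 scale)."""

    residuals: np.ndarray
    mean: float
    skewness: float
    excess_kurtosis: float
    normality_stat: float | None
    normality_pvalue: float | None
    normality_test: str | None
    lag1_autocorr: float | None
    var_first_half: float | None
    var_second_half: float | None
    degenerate: bool = False
    notes: str = ""


@dataclass
class ResidualReport:
    subs: VariableResiduals
    cells: VariableResiduals


def _analyze(r: np.ndarray) -> VariableResiduals:
    n = r.size
    mean = float(r.mean())
    if np.allclose(r, r[0]):
        return VariableResiduals(
            residuals=r, mean=mean, skewness=0.0, excess_kurtosis=0.0,
            normality_stat=None, normality_pvalue=None, normality_test=None,
            lag1_autocorr=None, var_first_half=None, var_second_half=None,
            degenerate=True, notes="constant residuals; autocorrelation undefined",
        )
    skew = float(stats.skew(r))
    kurt = float(stats.kurtosis(r))  # Fisher: excess kurtosis
    test = stat = pval = None
    notes = ""
    if n >= 8:
        s, p = stats.normaltest(r)
        test, stat, pval = "dagostino", float(s), float(p)
    elif n >= 4:
        s, p = stats.shapiro(r)
        test, stat, pval = "shapiro", float(s), float(p)
    else:
        notes = "n < 4: moments only, tests skipped"
    # Pearson correlation of (r_t, r_{t+1}); undefined for constant halves
    a, b = r[:-1], r[1:]
    if np.ptp(a) > 0 and np.ptp(b) > 0:
        lag1 = float(np.corrcoef(a, b)[0, 1])
    else:
        lag1 = None
    half = n // 2
    v1 = float(np.var(r[:half], ddof=1)) if half >= 2 else None
    v2 = float(np.var(r[half:], ddof=1)) if n - half >= 2 else None
    return VariableResiduals(
        residuals=r, mean=mean, skewness=skew, excess_kurtosis=kurt,
        normality_stat=stat, normality_pvalue=pval, normality_test=test,
        lag1_autocorr=lag1, var_first_half=v1, var_second_half=v2, notes=notes,
    )


def residual_report(dataset: BatchDataset, prediction: TrajectoryPrediction) -> ResidualReport:
    """Moments, omnibus normality and lag-1 autocorrelation per variable.

    Homoscedasticity is described by the first-half vs. second-half
    residual variances only — the sparse designs this package targets
    cannot support formal regression-based heteroscedasticity tests.
    """
    r_subs, r_cells = _residuals(dataset, prediction)
    return ResidualReport(subs=_analyze(r_subs), cells=_analyze(r_cells))


def _stage_block(so_result) -> dict:
    v = so_result.best_objective
    return {
        "MinOF": v.total,
        "ssr_subs": v.ssr_subs,
        "ssr_cells": v.ssr_cells,
        "Subs %": v.pct_subs,
        "Cells %": v.pct_cells,
        "params": dict(zip(
            ("mu_max", "Ks", "Y", "kd", "b"),
            (so_result.best_params.mu_max, so_result.best_params.Ks,
             so_result.best_params.Y, so_result.best_params.kd,
             so_result.best_params.b),
        )) | dict(so_result.best_params.extras),
        "n_evals": so_result.n_evals,
        "termination": so_result.termination_reason,
    }


def workflow_report(
    so_results: dict | None = None,
    mo_front=None,
    abc_history=None,
    abc_summary=None,
    so_mo_verification: dict | None = None,
) -> dict:
    """Consolidated machine-readable report over any subset of stages.

    Tabulates per-stage best objectives with their percent error
    decompositions, the SO-MO cross-check, ABC convergence status and
    posterior summaries.  Stages not supplied are marked "not run".
    """
    report: dict = {"stages": {}}

    if so_results is not None:
        report["stages"]["single_objective"] = {
            mode: _stage_block(res) for mode, res in so_results.items()
        }
    else:
        report["stages"]["single_objective"] = "not run"

    if mo_front is not None:
        v = mo_front.compromise_value()
        report["stages"]["multi_objective"] = {
            "front_size": int(mo_front.objectives.shape[0]),
            "compromise": {
                "MinOF": v.total,
                "ssr_subs": v.ssr_subs,
                "ssr_cells": v.ssr_cells,
                "Subs %": v.pct_subs,
                "Cells %": v.pct_cells,
            },
            "ideal_point": mo_front.ideal_point.tolist(),
            "degenerate": mo_front.degenerate,
        }
    else:
        report["stages"]["multi_objective"] = "not run"

    if so_mo_verification is not None:
        report["so_mo_verification"] = so_mo_verification

    if abc_history is not None:
        block: dict = {
            "n_chains": abc_history.n_chains,
            "n_generations": abc_history.n_generations,
            "final_R": abc_history.final_R(),
            "converged": bool(abc_history.final_R() < 1.2),
            "acceptance_rate": float(abc_history.accepted.mean()),
            "target_stats": abc_history.target.observed_stats.tolist(),
            "epsilons": abc_history.target.epsilons.tolist(),
        }
        if abc_summary is not None:
            block["posterior"] = {
                name: {
                    "mean": float(m), "sd": float(s),
                    "q2.5": float(lo), "q97.5": float(hi),
                }
                for name, m, s, lo, hi in zip(
                    abc_summary.param_names, abc_summary.mean, abc_summary.sd,
                    abc_summary.q025, abc_summary.q975,
                )
            }
            block["residual_sd_log10"] = abc_summary.residual_sd_log10
        report["stages"]["abc"] = block
    else:
        report["stages"]["abc"] = "not run"

    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`workflow_report` output."""
    lines: list[str] = ["kinfit workflow report", "=" * 40]
    so = report["stages"]["single_objective"]
    lines.append("Step 1 - single objective:")
    if so == "not run":
        lines.append("  not run")
    else:
        for mode, blk in so.items():
            lines.append(
                f"  {mode:14s} MinOF={blk['MinOF']:.4g}  "
                f"Subs%={blk['Subs %']:.1f}  Cells%={blk['Cells %']:.1f}  "
                f"({blk['termination']}, {blk['n_evals']} evals)"
            )
    mo = report["stages"]["multi_objective"]
    lines.append("Step 2 - multi objective:")
    if mo == "not run":
        lines.append("  not run")
    else:
        c = mo["compromise"]
        lines.append(
            f"  front of {mo['front_size']}; compromise MinOF={c['MinOF']:.4g}  "
            f"Subs%={c['Subs %']:.1f}  Cells%={c['Cells %']:.1f}"
        )
    if "so_mo_verification" in report:
        v = report["so_mo_verification"]
        lines.append(
            f"  SO-MO gap {v['relative_gap']:.3g} "
            f"({'pass' if v['passed'] else 'FAIL'} at {v['rel_tol']})"
        )
        if "front_min_gap" in v:
            lines.append(
                f"  SO vs front-minimum total gap {v['front_min_gap']:.3g} "
                "(search-convergence diagnostic)"
            )
    ab = report["stages"]["abc"]
    lines.append("Step 3 - ABC:")
    if ab == "not run":
        lines.append("  not run")
    else:
        lines.append(
            f"  {ab['n_chains']} chains x {ab['n_generations']} generations; "
            f"R={ab['final_R']:.3f} ({'converged' if ab['converged'] else 'NOT converged'}); "
            f"acceptance {ab['acceptance_rate']:.2f}"
        )
        for name, p in ab.get("posterior", {}).items():
            lines.append(
                f"    {name:8s} {p['mean']:.4g} +- {p['sd']:.2g}  "
                f"[{p['q2.5']:.4g}, {p['q97.5']:.4g}]"
            )
    return "\n".join(lines)
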