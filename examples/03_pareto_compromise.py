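"""Step 2: Pareto front of per-variable errors and compromise selection.

Evolves the (SSR_subs, SSR_cells) trade-off front with the NSGA-II-style
optimizer, picks the compromise member nearest the normalized ideal point,
and cross-checks its total against the step-1 compromise fit — the
redundancy that certifies both searches converged to the same region.
"""

import numpy as np

import kinfit as kf
from kinfit.optimize_mo import MoRunConfig, fit_pareto, select_compromise, verify_against_so
from kinfit.optimize_so import SoRunConfig, fit_extremes_and_compromise

spec = kf.get_model("Monod")
truth = kf.KineticParams(mu_max=0.04, Ks=20.0, Y=0.4, kd=0.005, b=1.0)
ds = kf.generate_synthetic(
    spec, truth, kf.SyntheticDesign(noise_sd_log10=0.02, n_replicates=3), seed=7)
fixed = {"mu_max": 0.04, "Ks": 20.0, "b": 1.0}

so = fit_extremes_and_compromise(
    spec, ds, config=SoRunConfig(max_evals=5_000, n_repetitions=1, seed=1),
    fixed=fixed)
front = fit_pareto(spec, ds, config=MoRunConfig(n_generations=500, pop_size=40, seed=2),
                   fixed=fixed)
params, comp_vec = select_compromise(front)

print(f"front size: {front.objectives.shape[0]} non-dominated members")
print(f"ideal point: ({front.ideal_point[0]:.4g}, {front.ideal_point[1]:.4g})")
v = front.compromise_value()
print(f"compromise:  SSR_subs={v.ssr_subs:.4g}, SSR_cells={v.ssr_cells:.4g} "
      f"({v.pct_subs:.1f}% / {v.pct_cells:.1f}%)")

check = verify_against_so(comp_vec, so["compromise"].best_objective)
print(f"\nSO compromise total {check['total_so']:.4g} vs selected MO compromise "
      f"{check['total_mo']:.4g}; gap {check['relative_gap']:.3g} -> "
      f"{'PASS' if check['passed'] else 'FAIL'} at {check['rel_tol']:.0%}")
front_min = float(front.objectives.sum(axis=1).min())
gap = abs(front_min - check["total_so"]) / max(check["total_so"], 1e-12)
print(f"front-minimum total {front_min:.4g}; gap vs SO {gap:.3g} "
      "(search-convergence diagnostic)")
print(
    "\nWhen the two per-variable error ranges are very unequal (a strongly\n"
    "asymmetric front, as here), the knee member chosen by normalized\n"
    "distance-to-ideal legitimately differs from the joint-total minimum -\n"
    "the front-minimum gap is what certifies that both search frameworks\n"
    "reached the same region.  The selected compromise SSRs become the\n"
    "observed summary statistics for the ABC stage."
)
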