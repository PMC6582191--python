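# kinfit

Global, multi-objective and Bayesian (ABC) parameter estimation for
unstructured microbial growth kinetics fitted to sparse, noisy batch
biodegradation time series.

## The problem

Batch biodegradation experiments — a pollutant as the sole limiting carbon
source, a degrading bacterial population measured by optical density or
plate counts — typically yield 5–10 roughly daily observations of two
variables, each the mean of three or fewer replicates.  Calibrating a
nonlinear growth model against such data is a hard non-convex optimization
problem: local regression routines stall in local optima, and joint fits of
two variables on different scales tend to overfit one of them.  `kinfit`
implements a three-step global workflow that addresses both failure modes
and quantifies the resulting parameter and prediction uncertainty:

1. **Global single-objective search** — self-adaptive differential
   evolution (saDE) locates the joint best *compromise* fit and the two
   per-variable *extreme* fits (each variable fitted alone).
2. **Global multi-objective search** — an NSGA-II-style evolutionary
   algorithm evolves the Pareto front of the per-variable errors and
   selects the compromise member nearest the normalized ideal point; its
   agreement with step 1 certifies that two independent search frameworks
   converged to the same region.
3. **Approximate Bayesian Computation** — a multi-chain sampler with
   differential-evolution proposals targets the compromise solution's
   summary statistics, yielding a posterior over parameters, Gelman–Rubin
   convergence traces, and 95% parameter / predictive uncertainty bands.

## The model

All eight registered growth laws (Monod, Tessier, Contois, Blackman,
Dabes, Powell, Moser, Heijnen) plug into the same batch mass balance with
endogenous decay:

```
dS/dt = -(1/Y) μ(S, X) X          dX/dt = μ(S, X) X - kd X
```

with `S` the substrate (mg/L), `X = b·C` the biomass inferred from the
cell measurement `C` through the fitted scaling factor `b`, `Y` the yield,
and `kd` the first-order decay rate (1/h).  Monod sets
`μ = μ_max·S/(Ks+S)`; Moser generalizes it to `μ = μ_max·Sⁿ/(Ks+Sⁿ)`.

Fitting criteria operate on log10 residuals (placing the two variables on
equivalent scales): the joint objective is the unweighted sum of the two
per-variable sums of squared log10 residuals, and its percent
decomposition (`Subs % / Cells %`) reports how the error splits.  The ABC
fitness `min_j(ε_j − |S_j − Ŝ_j|)` is non-negative exactly when every
simulated statistic is within tolerance of the compromise's.

## Worked example

`examples/` contains one narrative script per capability (simulation,
single-objective fits, Pareto/compromise, ABC posterior, full workflow).
The full pipeline on a synthetic Monod dataset (10 daily samples over
9 days, 3 replicates, 2% lognormal noise, the identifiable pair (Y, kd)
free) prints:

```
$ python scripts/acceptance.py --seed 1 --out results/acceptance.json
kinfit workflow report
========================================
Step 1 - single objective:
  compromise     MinOF=0.004528  Subs%=56.6  Cells%=43.4  (param_range, 4600 evals)
  extreme_subs   MinOF=0.166     Subs%=1.5   Cells%=98.5  (param_range, 10750 evals)
  extreme_cells  MinOF=0.01249   Subs%=86.4  Cells%=13.6  (param_range, 7300 evals)
Step 2 - multi objective:
  front of 38; compromise MinOF=0.004604  Subs%=55.7  Cells%=44.3
  SO-MO gap 0.0168 (pass at 0.05)
  SO vs front-minimum total gap 0.0168 (search-convergence diagnostic)
Step 3 - ABC:
  6 chains x 10000 generations; R=1.000 (converged); acceptance 0.33
    Y        0.4057 +- 0.069   [0.2914, 0.5361]
    kd       0.005022 +- 0.00033 [0.004468, 0.005628]
```

Reading this: `MinOF` is the summed squared log10 residual each mode
minimizes; each extreme's own-variable error bounds the compromise's from
below, and the compromise balances the split (56/43) where the extremes
are lopsided.  The step-2 gap under 5% certifies SO/MO agreement.  The ABC
stage converges (overall Gelman–Rubin R below the 1.2 threshold) and its
95% intervals cover the generating values Y = 0.4, kd = 0.005.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic dataset from the seed, runs the complete
three-step workflow (saDE extremes + compromise, Pareto compromise with
SO cross-verification, 6-chain ABC with Gelman–Rubin monitoring), prints
the consolidated report, and writes the results JSON.  Everything is
recomputed at run time; the same seed reproduces every number bit for bit.
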