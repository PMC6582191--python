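# Methods

## Model family and state equations

`kinfit` estimates parameters of unstructured kinetic models: the degrading
population is a single lumped biomass state `X` (mg/L) whose specific
growth rate `μ` (1/h) depends on the limiting substrate `S` (mg/L) and, in
one registered law, on `X` itself.  Every law shares the batch balance

    dS/dt = -(1/Y) μ X,      dX/dt = (μ - kd) X,      X = b·C,

with `Y` the yield (mg biomass per mg substrate), `kd` endogenous decay
(1/h), and `b` the linear scaling from the measured cell signal `C`
(optical density or counts) to biomass.  `X0 = b·C0` is recomputed inside
every objective evaluation, so the initial condition moves consistently
with each candidate's `b`.

Registered laws 1–8: Monod `μ_max S/(Ks+S)`; Tessier
`μ_max (1−e^{−S/Ks})`; Contois `μ_max S/(Ksx·X+S)` (extra `Ksx`; the core
`Ks` is inert for this law and retained only for interface uniformity);
Blackman `μ_max·min(1, S/Ks)`; Dabes–Finn–Wilke implicit law
`S = A·μ + Ks·μ/(μ_max−μ)` solved as the physical quadratic root (extra
`A`); Powell diffusion-limited square-root form (extra `L`);
Moser `μ_max Sⁿ/(Ks+Sⁿ)` (extra `n`); Heijnen–Romein
`μ_max (2^{S/(Ks+S)} − 1)`.  The Dabes, Powell, Heijnen and Contois forms
are literature-sourced (flagged in the registry) and overridable by
registering a custom `KineticModelSpec`.

Non-goals: structured/segregated biomass, substrate inhibition (Haldane),
temperature/pH dependence, fed-batch or chemostat operation.

## Error model and objectives

Observations are replicate means; residuals are taken as
`log10(obs) − log10(pred)`, which places substrate and cell series —
often orders of magnitude apart — on equivalent scales and matches a
multiplicative (lognormal) measurement-error model.  The joint objective
is the unweighted sum of the two per-variable sums of squared log10
residuals (`σ = 1`; replicate averaging removes the need for per-variable
σ weights, and with ≤3 replicates per point those σ's cannot be estimated
reliably anyway — optional σ weighting is kept in the API).  Covariance
between the two variables is neglected (diagonal error model).
Predictions are floored at 1e-12 before the log, penalizing near-zero
predictions heavily instead of producing −∞; an integrator failure marks
the prediction and the objective returns the large finite penalty 1e12 so
population-based optimizers continue unharmed.

## Numerical integration

LSODA (via `scipy.integrate.odeint`) at rtol 1e-8 / atol 1e-10, states
floored at 1e-12 on return.  `odeint` was chosen over `solve_ivp` for its
~5× lower per-call overhead — the evolutionary stages spend essentially
all their time in single-trajectory solves.  Halving the tolerances moves
endpoint states by <1e-5 relative on the designs used in the tests.

## Step 1 — self-adaptive differential evolution

Two mutation strategies (rand/1/bin and current-to-best/2/bin) compete;
the strategy probability is re-estimated every learning period (50
generations) from success/failure counts, crossover rates are drawn from
per-strategy normal memories `N(CRm_k, 0.1)` whose means adapt to the
successful CRs, and `F ~ N(0.5, 0.3)` truncated to (0, 2].  Population 50
by default.  Termination: evaluation budget (default 500,000), population
objective range < 1e-8, or population parameter range < 1e-2; the
parameter-range rule is applied on the internal log10 search scale (the
kinetic parameters span decades, so the box is searched in log10
coordinates and results are reported on the natural scale).  Out-of-box
proposals are reflected, then clipped.  Each fit runs five independent
seeded repetitions by default and keeps the best.  Three fits per dataset:
substrate-only error, cells-only error (the two "extremes"), and the joint
total (the compromise).

## Step 2 — Pareto front and compromise selection

An elitist genetic algorithm with simulated binary crossover (η = 15,
p = 0.9), polynomial mutation (η = 20, p = 1/d), fast non-dominated
sorting and crowding-distance truncation — the NSGA-II recipe.  With
exactly two objectives, reference-direction machinery (NSGA-III/RVEA
style) adds nothing, so plain crowding is used deliberately.  Defaults:
population 100, 20,000 generations (desk-scale runs use hundreds).

The compromise member is selected by min–max normalizing the front's
objectives to [0,1] and taking the member nearest (Euclidean) to the
normalized ideal point (0,0) — standard compromise programming, with a
deterministic lexicographic tie-break.  On a symmetric front this is the
knee; on strongly asymmetric fronts (per-variable error ranges differing
by orders of magnitude) it can sit far from the member minimizing the
plain sum.  The cross-stage verification therefore reports two numbers:
the relative gap between the selected compromise's total and the step-1
optimum (the headline check, 5% tolerance), and the gap between the
front's minimum total and the step-1 optimum, which isolates search
convergence from selection geometry.

## Step 3 — ABC sampler

Likelihood-free inference targeting the verified compromise: the observed
summary statistics are the compromise's per-variable SSRs, with
tolerances `ε_j = max(0.05·S_j*, 0.01)` by default (the tolerance is
inherently a user choice; it is reported in every output).  The fitness
`min_j(ε_j − |S_j − Ŝ_j|)` is maximized; a candidate is *behavioral* when
it is non-negative.

Chains (default 6, 150,000 generations) start uniformly in the prior box
— uniform on the *natural* parameter scale, so a flat prior means flat in
the units a microbiologist reports.  Proposals are differential-evolution
jumps built from two members of a thinned archive of past chain states,
scaled by γ = 2.38/√(2d) (γ = 1 for a 10% minority, enabling mode jumps)
plus a small reflected jitter.  Acceptance: a proposal is accepted when
its fitness is at least the current state's *or* it is behavioral — a
monotone climb into the behavioral region followed by free movement within
it, which in the small-ε limit samples the behavioral set uniformly.  This
is a deliberate simplification of adaptive multi-chain ABC samplers
(crossover adaptation, outlier-chain correction and snooker updates are
omitted); the properties the workflow relies on — convergence of the
overall R statistic below 1.2, coverage of the generating parameters, and
monotone posterior concentration as ε shrinks — are algorithm-agnostic and
are what the tests assert.

Convergence is monitored with the Gelman–Rubin potential scale reduction
factor computed on the second half of each chain (per parameter
`R = √((n−1)/n + B/(nW))`; overall R is the maximum), recorded on a
monitoring grid.  Posterior summaries use a burn-in fraction of 0.5 and
require ≥500 retained draws.  The 95% *parameter* band is the pointwise
2.5–97.5 percentile envelope of trajectories integrated at ≤300 evenly
thinned posterior draws; the *predictive* band multiplies it by
`10^(±1.96 σ_res)` with `σ_res` the log10 residual sd of the compromise
fit (estimated from the posterior-median trajectory when not supplied) —
with ≤3 replicates per point, a per-point noise estimate is not viable.
An identifiability diagnostic tracks the across-chain mean parameter
trace; its running mean's relative drift over the final 20% of
generations is reported (a converged, identifiable run drifts <5%).

## Synthetic data

The generator emulates the sparse batch experiments this workflow is
designed for: defaults of 10 equally spaced samples over 216 h (9 days),
S0 = 50 mg/L, C0 = 0.05, 3 replicates, and multiplicative noise
`truth·10^ε`, `ε ~ N(0, 0.02)` — homoscedastic on the log10 scale,
matching the objective's error model, with ~5% coefficient of variation
typical of HPLC/OD measurements.  The canonical test truth (Moser:
μ_max = 0.04 1/h, Ks = 20 mg/L, Y = 0.4, kd = 0.005 1/h, b = 1, n = 1.5)
was chosen so substrate depletion and biomass turnover span the full
sampling window; faster kinetics exhaust the substrate between the first
two daily samples and leave the data uninformative.  What the generator
does *not* emulate: heteroscedasticity on the natural scale beyond the
lognormal form, detection-limit censoring, replicate-count imbalance, and
model error (the fitted law generated the data) — a green recovery test
therefore establishes optimizer and sampler correctness, not robustness
to model misspecification.  An additive-natural-scale noise mode is not
endorsed but can be emulated by post-processing the replicate draws.

## Identifiability: the (Y, b) ray

With `X = b·C` and `X0 = b·C0`, the transformation `(Y, b) → (cY, cb)`
scales the latent biomass trajectory by `c` while leaving both observed
variables exactly unchanged, for every growth law without explicit `X`
dependence.  `Y` and `b` are therefore identified only through their
ratio; any point on the ray is an exact global optimum.  Empirically saDE
recovers μ_max, Ks, kd, n and Y/b to ≪1% on zero-noise data (cross-seed
cv ~1e-5) while `Y` and `b` individually wander along the ray (cv ~0.9).
Consequences: (i) the recovery test asserting individual `Y` and `b`
recovery fails by design; (ii) full-model ABC marginals for `Y` and `b`
span the ray's intersection with the prior box — which is the honest
uncertainty statement; (iii) practical calibrations should fix `b` from an
instrument calibration curve or report Y/b.  Restricted fits (any subset
of parameters pinned via `fixed=`) are supported throughout for exactly
this purpose.

## Seeding and determinism

Every stochastic component takes a seed; workflow stage seeds derive from
one master seed via `SeedSequence` spawning (kept below 2³¹).  Identical
config + seed reproduces every array bit for bit, and written artifacts
embed the config hash so result directories of mixed provenance are
detectable.
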