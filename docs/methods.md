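# Methods

## Model and assumptions

TXA disposition is linear and two-compartmental: central amount A1 (volume
V1) with first-order elimination CL and exchange Q with a peripheral amount
A2 (volume V2). Typical values scale allometrically with body weight (power
0.75 on the flows CL and Q, 1.0 on the volumes, reference 70 kg), and
clearance carries three covariate power terms — platelet count normalized to
196 K/µL (exponent 0.468), NIRS muscle oxygen saturation normalized to 88 %
(−0.29), and IL-8 unnormalized (−0.0873). The unnormalized IL-8 term is kept
exactly as the final model prints it, even though it makes the "typical"
clearance depend on the IL-8 unit scale; the reference identity CL = 190
mL/min therefore holds at IL-8 = 1 pg/mL.

Two printed variants of the parameter set exist (clearance 190 vs 192
mL/min/70 kg^0.75, IL-8 exponent −0.0873 vs −0.0887, a ~1 % difference in
CL). The defaults are the final-model equation values (190, −0.0873), since
those are stated to be the model used for the simulations; the alternative
is available via `PopPKParameters.with_overrides(cl_typ=192.0,
exp_il8=-0.0887)` or the `model_parameters` config block.

Between-subject variability is lognormal and diagonal: each parameter is
multiplied by exp(η), η ~ N(0, ω²), with ω² = 0.106 (CL), 0.0688 (V1),
0.879 (Q), 0.0589 (V2) and no covariances (none are reported). The
multiplicative exponential terms printed in the model equations are read as
these random-effect placeholders, not as fixed multipliers — fixed
multipliers would bias every typical value upward and contradict their
labeling as inter-individual variability. Residual error is proportional:
c_obs = c_true · (1 + ε), ε ~ N(0, 0.0238), truncated at zero (the
truncation is inert in practice: ε < −1 is a 6.5σ event).

Covariates are constant over the 8-h horizon, there is no inter-occasion
variability, and no maturation term — the model is not intended for
children under ~4 years, where glomerular-filtration maturation would have
to be added.

## Simulation

The central concentration under a zero-order infusion of duration T is
computed in closed form from the micro constants k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2 and the eigenvalues α > β > 0 of the disposition matrix
(α+β = k10+k12+k21, αβ = k10·k21):

C(t) = R0 · Σ_{λ∈{α,β}} c_λ (1 − e^{−λ·min(t,T)}) e^{−λ·max(t−T,0)},
c_α = (k21−α)/(V1·α·(β−α)), c_β = (k21−β)/(V1·β·(α−β)),

which is continuous at t = T, linear in dose, superposes across doses, and
integrates to exactly dose/CL over [0, ∞). The degenerate α = β case (a
measure-zero parameter set) is handled by flooring the eigenvalue split at a
relative 1e-9 and flagging the result rather than switching to the L'Hôpital
limit form; the perturbation error is far below every tolerance used.
Implementation correctness is established in the test suite against an
independent adaptive-ODE oracle (`scipy.integrate.solve_ivp`, rtol 1e-11) at
relative tolerance 1e-6 on random parameter sets spanning wide scales.

Default sampling grid: 0–5 min every minute, then 10, 15, 20, 30, 45, 60
min, then every 30 min to 480 min. The grid is an assumption (the original
simulation grid is not reported): dense early sampling captures the 1-min
peak, and the 8-h horizon covers the longest AUC window. Both grid and
horizon are configurable.

## Virtual populations

The adult reference cohort fixes all covariates at the trial medians
(WT 80.1 kg, PLT 197 K/µL, NIRS 88 %, IL-8 20.3 pg/mL) and varies only the
etas — it emulates parameter uncertainty-free Monte Carlo over the model's
between-subject distribution at the median patient. Note the adult weight
80.1 kg is used as a real covariate (V1 ≈ 19.8 L), not a 70-kg reference
subject.

The pediatric cohort samples each covariate independently and uniformly from
its published range (weight 17.7–58.2 kg, PLT 205–433 K/µL, NIRS 51–80 %,
IL-8 6.6–50.2 pg/mL, age 4.7–15.4 y; endpoints inclusive). "Uniform,
independent" is the simplest reading of "random sampling from ranges"; the
ranges themselves are interquartile or ±SD summaries, so the generator
emulates the published study conditions, not pediatric physiology: it has no
weight–age correlation, no tails beyond the quartiles, and age is carried
for reporting only. Passing tests therefore show fidelity to the published
simulation design, not validated predictions for real children — the
underlying extrapolation (adult covariate relationships and allometry
applied to children) is itself unvalidated, as the source analysis states.

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawning, with separate streams for population generation and residual
error, so toggling the error mode does not perturb the cohort.

## Noncompartmental analysis and comparison

Cmax is the maximum over grid observations (earliest time on ties). AUC uses
the linear trapezoid (log-linear would differ by <1 % at the default grid
density, inside every tolerance band); time above 10 mg/L interpolates each
bracketing segment linearly and sums across multiple crossings. Metrics use
the observed (noise-perturbed) series by default. This convention is
inferred rather than reported: the published median peaks (117.1 mg/L adult,
114.6 mg/L pediatric at 25 mg/kg) exceed the noiseless ceiling dose/V1
(~101 mg/L, weight-invariant under per-kg dosing because V1 scales linearly
with weight) by the amount expected for the maximum of ~5 near-peak
observations with 15.4 % proportional noise. A noiseless mode backs the
property tests.

Summaries are median (Q1–Q3) with numpy's linear-interpolation quantile
convention (unstated in the source; differences are negligible at n=1000).
"Most similar" exposure is operationalized as the candidate minimizing
|median ratio − 1| against the adult reference, ties broken toward the lower
dose; a shortfall flag marks an AUC window in which every candidate median
is below the adult median. On the published medians this flag is set for
AUC 0–8h but not AUC 0–4h, where the 35 mg/kg median (8770 mg·min/L) sits
marginally above the adult value (8738) — the simulation reproduces that
borderline behavior, with the 0–4h flag sensitive to the Monte Carlo seed.

## Problem sizes and numerical choices

Cohorts of n=1000 per regimen (the published design) run in well under a
second each; the distributional property tests use n=1e4–1e5 draws, and the
ODE cross-checks use 25–100 random parameter sets. Tolerances: machine-level
(1e-9 relative) for algebraic identities, 1e-6 for analytic-vs-ODE
agreement, Monte Carlo bands of a few percent for distributional recovery.

## Limitations

- Uniform, independent covariate sampling within quartile ranges understates
  real covariate spread and correlation.
- The residual-error-on-observations convention for NCA is an inference;
  noiseless metrics run ~10–15 % lower on Cmax (AUC and time-above are
  essentially unaffected in the median).
- No pharmacodynamics: 10 mg/L is an in-vitro antifibrinolytic threshold,
  not an outcome model; no toxicity weighting enters the dose selection.
- Single-bolus regimens only by default (multiple `dose_times` are supported
  mechanically, but no re-dosing recommendation logic is provided).
- Not applicable below ~4 years of age (no GFR maturation model).
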