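# txasim — model-based tranexamic acid dose extrapolation for pediatric trauma

Tranexamic acid (TXA) is an antifibrinolytic used early in trauma-related
bleeding. Adult practice has converged on a 2 g IV bolus, but there are no
pharmacokinetic data in bleeding children to set an equivalent pediatric dose.
`txasim` addresses this by simulation: it extrapolates a published adult
population-pharmacokinetic (popPK) model of TXA in severe trauma to a virtual
pediatric trauma population and asks which per-kg bolus reproduces the adult
exposure.

The package is aimed at clinical pharmacologists and pharmacometricians who
want a reproducible, scriptable implementation of that dose-extrapolation
analysis — or who want to swap in their own parameter values, covariate
ranges or regimens and rerun it.

## The model

TXA disposition is a linear two-compartment model (central volume V1,
clearance CL, peripheral volume V2, intercompartmental clearance Q) with
allometric weight scaling and covariate effects on clearance:

    CL = 190 · (WT/70)^0.75 · (PLT/196)^0.468 · (NIRS/88)^−0.29 · IL8^−0.0873 · e^η_CL
    V1 = 17300 · (WT/70) · e^η_V1
    Q  = 80.1 · (WT/70)^0.75 · e^η_Q
    V2 = 11400 · (WT/70) · e^η_V2

with η ~ N(0, ω²) (ω²: CL 0.106, V1 0.0688, Q 0.879, V2 0.0589) and
proportional residual error σ² = 0.0238 on observed concentrations. Units are
mg, mL, min internally; concentrations are reported in mg/L.

The pipeline:

1. **Virtual populations** — an adult reference cohort (n=1000, fixed
   trial-median covariates WT 80.1 kg, PLT 197 K/µL, NIRS 88 %, IL-8
   20.3 pg/mL) and a pediatric trauma cohort (n=1000, covariates sampled
   uniformly and independently from literature ranges: weight 17.7–58.2 kg,
   PLT 205–433 K/µL, NIRS 51–80 %, IL-8 6.6–50.2 pg/mL).
2. **Exposure simulation** — closed-form (biexponential) solution of the
   two-compartment system under zero-order infusion; a "bolus" is a 1-min
   infusion; per-kg doses are capped at 2 g.
3. **Noncompartmental analysis** — Cmax, AUC 0–4 h and 0–8 h (linear
   trapezoid), and total time above 10 mg/L (the in-vitro concentration
   giving ~80 % inhibition of fibrinolysis), by linear interpolation.
4. **Dose comparison** — median (Q1–Q3) summaries per regimen, the
   Cmax-matched and AUC-matched pediatric doses relative to the adult 2 g
   reference, and an administration-time sweep.

## Worked example

The shipped default configuration runs the whole analysis (adult 2 g
reference plus the 20/25/30/35 mg/kg pediatric sweep, n=1000 each):

```bash
txasim simulate --out demo_out
```

prints

```
Parameter               adult 2 g           20 mg/kg           25 mg/kg            30 mg/kg             35 mg/kg
---------------------------------------------------------------------------------------------------------------------------
Time above 10 mg/L (h)  5.08 (3.79-6.60)    2.53 (1.95-3.40)   2.96 (2.30-3.93)    3.31 (2.53-4.49)     3.64 (2.75-4.88)
Cmax (mg/L)             115.0 (98.7-137.2)  90.6 (76.1-107.6)  111.9 (94.8-134.0)  135.1 (113.2-161.7)  158.6 (134.3-189.9)
AUC 0-4h (mg*min/L)     9008 (7721-10130)   5163 (4249-6032)   6405 (5334-7589)    7694 (6382-9073)     8966 (7472-10534)
AUC 0-8h (mg*min/L)     10994 (9154-12992)  5839 (4613-7038)   7268 (5788-8784)    8735 (6952-10508)    10109 (8109-12271)

Cmax-matched dose: 25 mg/kg
AUC 0-4h-matched dose: 35 mg/kg (all candidates below the adult median)
AUC 0-8h-matched dose: 35 mg/kg (all candidates below the adult median)
```

Reading the table: a 2 g adult bolus keeps plasma TXA above 10 mg/L for a
median ~5.1 h with a median peak of ~115 mg/L. In children, 25 mg/kg
reproduces the adult peak (111.9 vs 115.0 mg/L) — the Cmax-matched dose —
while every candidate dose clears faster than adults (higher platelet counts
and lower NIRS in the pediatric covariates outweigh the allometric slowdown),
so total exposure (AUC) falls short of the adult value at all but the highest
dose and the time above 10 mg/L is roughly 2.5–3.7 h versus ~5 h in adults.
That is the quantitative case for a 25 mg/kg (max 2 g) bolus with possible
re-dosing rather than a single larger bolus.

The same run writes the cohort tables, per-regimen profiles and metrics,
`summary.csv`, `report.txt` and a run log (seed, config hash, versions) to
`demo_out/`. Other verbs: `txasim population`, `txasim nca`, `txasim report`
(see `--help`); everything is equally usable as a library
(`txasim.run_pipeline`, `txasim.simulate_cohort`, …), and all randomness
derives from the single seed in the config.

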