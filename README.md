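# serinepkpd

Population pharmacokinetic-pharmacodynamic (PK-PD) modelling of oral
L-serine (AST-001) in pediatric autism spectrum disorder, and
simulation-guided weight-tiered dose selection.

L-serine improves adaptive behavior in children with autism, but the
response builds up over months and the efficacious dose must be practical
for 10-60 kg children taking a syrup twice daily.  This package implements
the full quantitative workflow for that problem, for pharmacometricians and
trial statisticians:

- a **structural model**: two-compartment kinetics with zero-order
  absorption (closed-form superposition over dose events), allometric
  pediatric scaling (exponents 0.75/1.0 on clearances/volumes), an effect
  compartment `dCe/dt = ke0 (Cp - Ce)` whose equilibration half-life
  `ln 2/ke0 ≈ 15 weeks` explains the slow response, and a score model

  `score(t) = E0·(age/5)^β_age · e^η_E0 + (Kprog + η_Kprog)·t + Deff·e^η_Deff · Ce(t) + ε`

  for the K-VABS-II-ABC adaptive-behavior composite;
- a **synthetic trial generator** emulating a 145-child, three-arm
  phase-II design (titration, placebo crossover, weight-tiered BID dosing,
  visits at weeks 0/12/24/36);
- a **nonlinear mixed-effects estimator** (SAEM with a deterministic
  Laplace polish; Laplace likelihood for LRTs, covariate search, standard
  errors, case bootstrap);
- **diagnostics** (goodness-of-fit tables, prediction-corrected VPC) and a
  **dose-scenario engine** (Δscore percentiles and target attainment per
  weight band, fixed-dose vs mg/kg comparison, covariate forest ratios).

The confidential clinical dataset is replaced by the synthetic generator;
the adult PK values come from a separate publication and are shipped as
documented placeholders (see `docs/methods.md`).

## Worked example

The numbered scripts under `analysis/` form the narrative pipeline;
each writes its tables under `results/`.

```bash
python analysis/01_simulate_trial.py      # virtual phase-II trial -> long CSV
python analysis/02_fit_model.py           # SAEM fit, ~90 s single core
python analysis/03_diagnostics.py         # GOF + pcVPC
python analysis/04_dose_scenarios.py      # weight-tiered dose tables
```

Step 02 prints the recovered parameters next to the generating values
(one simulated trial; single-trial estimates scatter — ke0 and the
correlation fluctuate visibly at n=145):

```
parameter       generating    estimate
ke0                 0.0065    0.003381
e0                   48.51        47.8
beta_age             -0.21     -0.1582
deff                0.0022     0.00392
kprog                0.015     0.01538
...
sigma_add              1.6       1.657
OFV: 3250.0  method: saem+polish  converged: True
```

Step 04 prints the dose-scenario table (per band: week-12 score-change
percentiles and the percentage of children improving by more than 2
points):

```
    band  dose_g_bid     arm    p5  p50   p95  attainment_pct    n
 14-21kg         0.0 placebo -2.68 1.37  5.55            38.0  200
 14-21kg         4.0 treated -1.44 3.80 13.95            67.0  200
 ...
50-infkg        14.0 treated -1.65 4.00 34.79            71.0  200
```

Treated bands beat placebo everywhere, attainment grows with the banded
dose, and the tiered fixed doses track 200 mg/kg BID (median paired
difference well inside the between-subject spread) — the qualitative
pattern that motivates the 2/4/6/10/14 g weight-tiered regimen.

The same stages are available as a CLI (`serine-pkpd simulate-trial`,
`fit`, `bootstrap`, `vpc`, `dose-scenarios`); every stochastic stage
requires `--seed` and all artifacts embed the package version, seed and a
config hash.

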