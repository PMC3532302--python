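# cprharvest

Adaptive common-pool-resource (CPR) harvest model: a coupled
resource/harvest/behavioral-trait ODE system in which a group of users
adapts a continuous harvest trait along the fitness gradient of current
harvest plus discounted future resource productivity, minus optional
punishment costs. The package bundles:

- **`cprharvest.core`** — pure functions for every term of the system:
  logistic resource growth, Monod harvest with a trait-dependent
  half-saturation constant, Gaussian punishment kernel, trait- and
  time-dependent discount weight, fitness and its analytic gradient.
- **`cprharvest.simulate`** — fixed-step RK4 round integration (numba
  kernel, cross-checked against the pure functions and a scipy oracle)
  plus diagnostics: cooperation `A`, relative productivity `omega`,
  resource affinity `1/k`, total harvest `H_T`.
- **`cprharvest.calibration`** — fits the maximum discount factor
  `phi_max` (one-parameter mode) or `(phi_max, a, b)` (three-parameter
  mode) to an observed resource series by RMSE grid search +
  golden-section refinement; one-at-a-time RMS sensitivity scans.
- **`cprharvest.behavior`** — between-round analysis: exponential
  discount rate implied by a fitted weight (bisection on
  `(1-exp(-rho*T))/rho = phi_max`), four-parameter logistic fit of the
  rate against the previous round's total harvest, and the
  sustainability threshold from the previous-vs-current regression
  fixed point.
- **`cprharvest.synth`** — synthetic pseudo-experiments: 6 sessions ×
  6 rounds with a treatment switch after round 3 (treatments NCP, C, P,
  CP) and a logistic between-round feedback from realized harvest to
  the next round's discount ceiling.
- **`cprharvest.config` / `cprharvest.io` / `cprharvest.cli`** — YAML
  config (validated, lossless round-trip), CSV I/O, and the pipeline
  CLI.

## CLI

```sh
# one round at a given discount ceiling -> trajectory CSV
cprharvest simulate --phi-max 16.5 --out traj.csv

# full pipeline on a synthetic study
cprharvest synth --seed 1 --out-dir study/
cprharvest calibrate --manifest study/manifest.csv --mode one --out report.csv
cprharvest analyze-feedback --report report.csv --out-prefix feedback
cprharvest sensitivity --report report.csv --manifest study/manifest.csv --out-dir scans/
```

All commands accept `--config cfg.yaml`; an empty file means all
defaults. Example config:

```yaml
model:
  phi_max: 16.5
  T: 240.0
solver:
  dt: 0.05
  dt_out: 1.0
design:
  n_sessions: 6
  noise_sigma: 2.0
seed: 0
```

Trajectory CSVs have columns `t,R,H,theta,G,phi,P,A,omega,affinity`
(time, resource, cumulated harvest, trait, harvest rate, discount
weight, punishment rate, cooperation, relative productivity, resource
affinity); observed-round CSVs have `t,R` (optional `G`); the study
manifest lists `session_id,round_index,treatment,path`.

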