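# cometpool

Kinetics of bead-propelled actin comet tails in sealed microwells with a
limited actin monomer pool.

A conserved pool, measured in length-equivalent micrometres
(`l = l_max * G / G_bar`), is partitioned into tail F-actin, non-tail
F-actin, ADP-G-actin, ATP-G-actin, and an aged (polymerization-incompetent)
bookkeeping compartment. The package provides:

- **`model_core`** — the deterministic turnover ODEs (assembly,
  disassembly `gamma`, recycling `k_DT`, aging `psi`), the closed-form
  assembly-only solution, the analytic aging-free steady state
  (`alpha = k~/k_DT`, `beta = k~/gamma`), and named condition presets
  (assembly / disassembly / recycling, fitted and deduced variants).
- **`calibration`** — algebraic deduction of rates from dimensionless
  velocity/length ratios, the speed-law efficiency factor `phi`, and
  multi-start bounded least-squares fitting of the ODE model to comet
  tracks with profile-flatness identifiability flags.
- **`trajectory_analysis`** — per-track statistics: instantaneous
  velocity, motility half-life (exponential fit), cumulative polymerized
  length, monomer-pool cycle counting, consumption rate, tail fraction,
  defect-decay time constants, disassembly speed, and barbed-end k+
  estimation. Tracks are plain CSV (one row per track per frame).
- **`estimates`** — back-of-envelope compartment estimates: well volume,
  molecule counts, filament number, mesh size, pool length equivalent,
  bead density comparison, with explicit significant-figure rounding.
- **`synthetic_data`** — seeded generator of synthetic cohorts (noisy
  tracks plus a ground-truth manifest) and defect-decay traces, enabling
  closed-loop parameter-recovery tests.
- **`cli`** — a `cometpool` command wiring everything together.

## CLI examples

```sh
# integrate the recycling preset for 20 h, write trajectory.csv
cometpool simulate --preset recycling --duration-h 20 --out runs/sim

# analytic steady state of the deduced disassembly parameters
cometpool steady-state --preset disassembly_deduced --out runs/ss

# rates from observable ratios (velocity 1/2 of max, tail 1/3 of l_max)
cometpool calibrate --v-ratio 0.5 --l-ratio 0.3333 --k-tilde 0.01 --out runs/cal

# synthetic cohort -> per-track analysis -> ODE fit
cometpool synth --preset recycling --n 16 --duration-h 20 --noise-cv 0.1 --seed 42 --out runs/synth
cometpool analyze --tracks runs/synth/tracks.csv --lmax 110 --gbar 3 --out runs/analysis
cometpool fit --tracks runs/synth/tracks.csv --free gamma,k_DT,psi --starts 32 --seed 0 --out runs/fit

# back-of-envelope estimate report
cometpool estimate --out runs/estimates
```

Every command writes a run manifest (tool version, echoed arguments,
seed) next to its outputs; existing outputs are never overwritten without
`--force`.

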