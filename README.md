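# comfeedback

Identification of the sensorimotor feedback underlying the ankle balance
strategy: estimate **delayed linear feedback gains** from center-of-mass (COM)
or ankle-joint kinematics to reactive ankle moments and muscle activity in
perturbed standing and walking.

The package provides:

- **`comfeedback.dataset`** — a canonical columnar trial format (UTF-8 CSV
  with a `#`-prefixed `key=value` header), validators, and a mapping-driven
  importer for the original MATLAB archives.
- **`comfeedback.preprocessing`** — gait-event detection from vertical force,
  stride-phase normalization, phase-locked reference trajectories from
  unperturbed data, deviations, non-dimensionalization (positions / `l_max`,
  velocities / `sqrt(g l_max)`, torques / `m g l_max`), and delayed signals
  (60/100 ms for the COM model, 40/80 ms for the joint model; masked, never
  imputed).
- **`comfeedback.identify`** — two-parameter no-intercept least-squares fits
  with uncentered R² and RMSE: discrete-onset fits (input at onset + 150 ms,
  output at + delay), 16-bin phase-dependent fits over stance, constant-gain
  fits, gain modulation by vertical GRF or the COP-to-foot-bound distance,
  and delay-sensitivity sweeps. Moment fits pool both perturbation
  directions; EMG fits are per-subject and direction-split.
- **`comfeedback.stats`** — Fisher z-transform, paired t-tests, one-way
  repeated-measures ANOVA with Bonferroni-corrected post-hocs.
- **`comfeedback.simulate`** — a synthetic generator (delayed PD feedback of
  COM kinematics embedded in a linearized inverted pendulum, with
  phase-dependent gain profiles, direction-gated EMG, and discrete/continuous
  perturbations) so that every identification stage is verifiable by exact
  parameter recovery.

## CLI

```bash
comfeedback simulate --protocol belt_continuous --seed 7 --n-strides 60 -o data/sim
comfeedback fit data/sim --model com --bins 16 -o results/binned
comfeedback fit data/sim --model com --delay-grid 0:0.2:0.01 -o results/sweep
comfeedback compare results/a/fits.csv results/b/fits.csv -o results/cmp.csv
comfeedback report results -o report
comfeedback import DataStandingBalance.mat --protocol standing_translation -o data/standing
```

Every run writes a `manifest.json` (config + input hashes) next to its
outputs; logs go to stderr, results to files.

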