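# posturelab

A toolkit for posturography balance-control experiments built around
support-surface tilt perturbations:

- **`posturelab.prts`** — pseudo-random ternary stimulus design: GF(3)
  maximal-length shift-register sequences, symbol-to-velocity mapping,
  exact piecewise-linear integration and cycle concatenation. The default
  configuration (found by a canonical search over primitive 4-stage tap
  sets, initial states and sign mappings) reproduces the classic geometry:
  80 states of 0.25 s at ±1.78 °/s, a 20-s cycle with ~4° peak-to-peak
  tilt, and 13 cycles per 260-s trial.
- **`posturelab.com`** — center-of-mass calibration: COP from ankle torque,
  least-squares fit of `x_com = a + b·x_hip + c·x_sho` on quasi-static
  data, COM reconstruction for dynamic trials, and the angular excursion
  `arcsin(x_com / h_com)`.
- **`posturelab.metrics`** — sway outcomes: zero-phase Butterworth
  filtering, mean sway velocity (sway path per unit time after a discard
  window), and the periodic/random decomposition of cyclic tilt responses
  (across-cycle mean and SD, power as the sum of the squared trace).
- **`posturelab.anova`** — balanced within-subject one- and two-way
  repeated-measures ANOVA with per-effect error strata, eta squared,
  optional Greenhouse–Geisser correction, simple contrasts against a
  reference level, and per-level post-hoc analyses.
- **`posturelab.simulate`** — a synthetic stander: a delayed-PD-controlled
  inverted pendulum with weighted proprioceptive/visual/vestibular
  feedback and per-channel sensory noise, a two-segment kinematic readout
  for the hip/shoulder sway rods, a sway-referencing servo, a quasi-static
  calibration motion, and full-study generation (4 visual × 3 platform
  conditions per subject) with ground truth.
- **`posturelab.io` / `posturelab.pipeline`** — trial CSV format with JSON
  metadata sidecars, validated run configuration, and the end-to-end
  pipeline (calibration → COM angle → metrics → ANOVA/contrasts).

The simulator is a stand-in plant for exercising the analysis chain, not a
validated physiological model; its presets are tuned so the qualitative
pattern EO ≈ LAB < ABS < EC emerges across platform conditions.

## Command-line usage

```sh
# export the default tilt stimulus
posturelab prts --stages 4 --v-peak 1.78 --state-duration 0.25 \
    --cycles 13 --rate 1000 --out stimulus.csv

# generate a synthetic 10-subject study
posturelab simulate --subjects 10 --seed 42 --out data/

# fit COM calibration coefficients
posturelab calibrate --recording data/trials/S01_none_calibration.csv \
    --mass 70 --hcom 0.95 --out coeffs.yaml

# per-trial metrics
posturelab metrics --recording data/trials/S01_EO_tilt.csv \
    --coeffs coeffs.yaml --mode tilt --out metrics.csv

# statistics on a long metrics table (subject,visual,platform,value)
posturelab anova --metrics metrics_long.csv --reference EO --out stats/

# full pipeline from a YAML config
posturelab run --config run.yaml
```

A `run.yaml` contains `data_dir`, `out_dir` and optional analysis settings
(`discard_s`, `window_s`, `cycle_duration_s`, `n_cycles`, `normalization`,
`reference`, `exclude`, …); unknown keys are rejected.

## Notes

- The peak-to-peak amplitude of the default stimulus is 9 × 1.78 °/s ×
  0.25 s = 4.005°, the closest value to the nominal 4° that an integrated
  ternary sequence can produce at those exact state parameters.
- The combined ANOVA mixes outcome parameters of different units (two
  sway velocities, two sway powers) as levels of the platform-condition
  factor; each outcome column is z-scored across subjects by default
  (`normalization: zscore`), which makes the platform main effect zero by
  construction while leaving the visual effect, the interaction, and all
  contrasts meaningful. `raw` and `log` are available.
- Filtering (2nd-order Butterworth, 5 Hz) is applied zero-phase
  (forward–backward) and, by default, only to spontaneous-sway trials;
  set `filter_tilt_trials: true` to filter tilt trials too.
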