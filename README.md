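# corridor-neuro

Analysis toolkit for a visually guided reward task on a virtual linear
corridor, paired with a synthetic session generator that plants known ground
truth. A head-fixed animal runs on a treadmill that drives a virtual
corridor; licking within the first half of a reward zone (80–100 cm) earns
an early reward, otherwise a default reward is delivered at 100 cm. Some
trials hide the visual cue (uncued) and some reduce the treadmill-to-corridor
gain from 1 to 0.75, dissociating physical running distance from virtual
position.

The package covers:

- **`synthetic_session`** — simulates full session bundles: per-frame
  behavior (treadmill/virtual position, speed, licks), trial table with
  reward events, and raw fluorescence from planted neuron tunings passed
  through a calcium-indicator forward model (exponential kernel,
  inhomogeneous-Poisson events, 40 Hz). Plain-text on-disk format
  (CSV + JSON sidecar) with validated round trips.
- **`behavior_analysis`** — success rate and the spatial modulation index
  (SMI): observed success rate divided by the mean success rate of a
  1,000-fold permutation null in which each trial's pre-reward licks are
  re-placed uniformly along the pre-reward corridor. Drinking (post-reward)
  licks are excluded.
- **`trace_processing`** — ΔF/F₀ extraction (F₀ = 5th percentile of the
  1-Hz low-pass, zero-phase, 60th-order FIR-smoothed trace) and spatial
  binning into trials × position-bins matrices (half-open 2-cm bins, NaN
  for unvisited bins). Input traces are assumed neuropil-decontaminated.
- **`neuron_classification`** — task-responsive neurons (paired Wilcoxon
  signed rank on R_pre vs R_post around the reward-zone onset, α = 0.001),
  response categories (corridor / locomotion / lick / reward_zone),
  reward-location neurons (one-sided R_post > R_pre in cued *and* uncued
  trials), gain-modulated neurons (trial-averaged peak within −5/+20 cm of
  the (expected) reward-zone onset in treadmill coordinates under both
  gains), a lick-response control, and a distance-vs-time consistency
  measure.
- **`population_decoder`** — leave-one-out template-matching decoder
  (Pearson correlation to class-mean templates, majority-class subsampling
  for imbalance) for trial outcome (early vs default) and cue type
  (cued vs uncued, successful trials only).
- **`pipeline`/`cli`** — one-config multi-day experiment runner and a
  `corridor-neuro` command-line interface.

## CLI

```sh
corridor-neuro simulate --config config.yaml --out session_dir --seed 1
corridor-neuro behavior --session session_dir --permutations 1000 --seed 1 --out behavior.json
corridor-neuro dff      --session session_dir --out dff.csv
corridor-neuro classify --session session_dir --dff dff.csv --out labels.csv
corridor-neuro decode   --session session_dir --dff dff.csv --task outcome --seed 1 --out decoder.json
corridor-neuro run      --config experiment.yaml --out summary.json
```

A minimal simulation config:

```yaml
geometry: {uncued_period: 5, gain_period: 5}
lick_policy: {mode: expert, rate: 0.03, target_center: 88.0, anchor: cue_dependent}
neurons:
  - {category: reward_zone, anchor_pos: 86.0, peak_rate: 8.0, n: 5}
  - {category: untuned, n: 5}
n_trials: 40
```

An experiment config for `run` replaces `lick_policy`/`n_trials` with a
`days:` schedule (one lick policy per day) plus an `analysis:` block
(`permutations`, `alpha`, `window_cm`).

## Notes

- All stochastic operations take explicit seeds; session bundles, analyses
  and the experiment runner are bit-reproducible given the same seeds.
- Statistical conventions that the underlying methods leave open (permutation
  domain of the SMI null, FIR window design, category-cascade thresholds,
  decoder similarity metric) are documented in the relevant docstrings and
  surfaced as configurable arguments and in output metadata.
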