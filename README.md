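# flyforage

Trajectory-based analysis of single-fly patch foraging in a circular arena
with yeast and sucrose food patches. The package takes per-fly tracking
tables (50 fps head/body centroids) plus an arena description and produces:

- **kinematics** — Gaussian-smoothed positions (0.32 s support), head/body
  speed, signed angular speed from the head–tail axis, head/tail identity
  disambiguation, lost-frame QC (tracks with >10% lost frames are excluded);
- **ethogram** — per-frame rest (≤0.2 mm/s) / micromovement / walk
  (>2 mm/s) classification on extra-filtered head-speed channels (1.2 s for
  walking, 2.4 s for resting), plus a sharp-turn overlay (|angular speed|
  local maxima >125 °/s at body speed <4 mm/s);
- **events** — patch encounters (head ≤3 mm from a patch center, merged by a
  2-px / 0.31 mm displacement rule and a 5 mm proximity rule), food
  micromovements (micromovement frames with head ≤2.5 mm), and visits
  (consecutive same-patch food micromovements with the head never >5 mm away
  in between);
- **metrics** — the per-fly exploitation/exploration/locomotion parameter
  set: micromovement and visit totals and counts, encounter rate, P(stop),
  latency to the first ≥30 s yeast visit, per-visit minimum distance and
  head-covered area, in-visit body and angular speed, same/adjacent/distant
  transition probabilities (16 mm rules), distance to the next yeast visit,
  sliding-window visit duration, yeast quartiles, speed outside patches, and
  population summaries (non-eater fraction, CV);
- **stats** — Wilcoxon rank-sum with Bonferroni correction, Fisher's exact
  test with modified-Wald proportion CIs, and bootstrap difference-of-median
  confidence intervals (5%/95%);
- **synthetic** — a seeded semi-Markov forager simulator with ground-truth
  event logs (per-substrate stop probability, leaving hazard, revisit bias,
  local/global targeting range), five internal-state condition presets, and
  a handcrafted fixture suite for every segmentation edge case.

All intervals are half-open `[start, end)` in frames; coordinates are mm in
an arena-centered frame (pixel inputs are converted once at load with
0.155 mm/px).

## CLI

```sh
# simulate a cohort and write trajectory CSVs + arena YAML + ground truth
flyforage simulate --preset mated_aa_deprived --n-flies 5 \
    --duration-s 7200 --seed 1 --out-dir scratch/sim

# full pipeline: QC -> ethogram -> events -> per-fly metrics
flyforage run scratch/sim/mated_aa_deprived_*.csv \
    --arena scratch/sim/arena.yaml --out-dir scratch/out

# group comparisons on a metrics table
flyforage compare scratch/out/metrics.csv --value-col yeast_total_visit_min \
    --bootstrap --out scratch/out/comparisons.csv
```

Other subcommands: `qc`, `classify`, `events`, `metrics`, `transitions`,
`quartiles`, `report` (stacked ethogram PNG). All thresholds default to the
published constants and can be overridden with a YAML config (`--config`).

Trajectory CSV schema: `frame, time_s, body_x, body_y, head_x, head_y
[, tail_x, tail_y]`, with units declared in the config or by `_px`/`_mm`
column suffixes.

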