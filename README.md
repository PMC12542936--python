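# nanotwin

A desk-scale digital twin of a label-free robotic mitochondrial-biopsy
nanoprobe. The package simulates, end to end and on purely synthetic data:

- **`nanotwin.dep_physics`** — frequency-dependent polarizability
  (Clausius–Mossotti factor, including the single-shell organelle model) and
  the DEP force/potential around the nanoelectrode tip. The tip field is a
  one-parameter analytic power law (`∇|E_rms|² ∝ V²/(s+r0)⁷`) calibrated so a
  reference organelle at contact feels 1 nN at 7 V pp / 1 MHz; trapping radii
  follow from an energy criterion `|U| = kT`.
- **`nanotwin.trapping_sim`** — overdamped Euler–Maruyama Brownian dynamics of
  bead/organelle capture at the tip, cluster release after drive-off,
  retention during probe translation (drag-balance shedding), and Monte-Carlo
  biopsy success surfaces over voltage × dwell.
- **`nanotwin.electrochem`** — linear amperometric calibration with analyte
  selectivity, the sealed-chamber depletion model
  `i(t) = baseline + i0·exp(−t/τ)` with nonlinear-least-squares fitting and
  volume estimation, zero-phase low-pass filtering, penetration-spike
  detection, and the 8-pA debounced mitochondrion detector.
- **`nanotwin.vision`** — tip localization by background subtraction,
  pluggable cell detection with a classical watershed fallback, the
  motion-history image (MHI), and the pixel-mean-value (PMV > 1) contact
  criterion.
- **`nanotwin.controller`** — the automation state machine: nucleus-avoiding
  insertion-point planning, nearest-neighbour target ordering,
  contact → penetrate → sense → decide → biopsy → retract execution with
  full event logging, and per-attempt survival reporting.
- **`nanotwin.synthetic_world`** — seeded generators for everything the other
  modules consume: virtual dishes with ground truth, paired
  current/fluorescence draws with tunable correlation, amperometric traces
  with programmed events, and rendered bright-field-like image stacks.
  Regime defaults live in one place, `src/nanotwin/data/fixtures.yaml`.

## CLI

All functionality is exposed through a `nanotwin` entry point:

```sh
nanotwin dep spectrum                      # Re[K] vs frequency table
nanotwin dep force-curve                   # |F| vs distance table
nanotwin dep trap-radius                   # trapping radius (um)
nanotwin trap run|release|translate|surface --seed N
nanotwin sense simulate --out trace.tsv
nanotwin sense fit trace.tsv
nanotwin sense detect trace.tsv --threshold-pa 8
nanotwin vision tip|cells|contact stack.tiff
nanotwin synth dish|trace|frames|pairs --seed N
nanotwin protocol run --dish dish.json --seed N --out rundir/
```

Current traces are tab-separated text with a `# sample_rate` header; dishes
and event records are JSON; image stacks are multi-page TIFF.

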