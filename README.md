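# surftrack

Marker-based optical surface tracking for quantifying patient setup
accuracy in upright radiotherapy.

Upright treatment platforms position a seated patient on a rotating chair
in front of fixed horizontal beams. How reproducibly a patient can be set
up (inter-fractional setup error) and how much they drift while immobilized
(intra-fractional displacement) determine whether a given immobilization
scheme — thermoplastic masks, backrest attachments, shin rests — is
clinically usable. `surftrack` implements the full optical measurement
chain used to answer that question from three high-resolution cameras
imaging 26 labeled surface markers on the body and mask:

1. **Detection** — sub-pixel marker positions as centroids of dark pixels
   in binarised per-marker patches.
2. **Triangulation** — DLT + reprojection refinement per camera pair
   (front+left for left-side markers, front+right for right-side), after
   extrinsic calibration by reprojection-error minimisation on a 41 × 58
   grid plate; accuracy verified on a held-out plate pose.
3. **Registration** — ICP (Kabsch inner step) of body and mask marker
   clouds against the reference frame; respiratory surrogate markers are
   smoothed over five frames first; thigh markers tracked individually.
4. **Metrics** — 6-DoF displacement series (LR/AP/SI translations, pitch/
   roll/yaw) about the rotation-axis origin; relative body-vs-mask motion
   `M_rel = M_body · M_mask⁻¹`; setup-error decomposition per axis

   * μ — mean of per-subject mean errors,
   * Σ (systematic) — SD over subjects of the per-subject means,
   * σ (random) — mean over subjects of the per-subject SDs,

   and the **beam delivery time** (BDT): the time during a 20-min session
   for which all six components stay within tolerance (±2 mm/±1°
   abdominal, ±1.5 mm/±1° head-and-neck).
5. **Statistics** — Welch's t (means), Brown–Forsythe (variances),
   Holm–Bonferroni adjustment across setup-pair families at α = 0.05.

Because measured study data of this kind are typically not shareable, the
package ships a first-class synthetic scene simulator (camera rig, marker
layouts, saturating drift A(1 − e^(−t/τ)), aliased respiration, marker
dropout, calibration fixtures) with full ground truth, so every stage is
verifiable end-to-end by simulate-then-recover. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

```python
from surftrack.pipeline import run_demo
report = run_demo(seed=1, out_dir="demo_out", n_subjects=15)

print(report["bdt"]["total_min"])                      # 20.0
print(report["body_displacement_at_end_mm_deg"])
# {'lr': 0.155, 'ap': 0.467, 'si': -1.657,
#  'pitch': 0.294, 'roll': 0.095, 'yaw': 0.079}
for ax in ("lr", "ap", "si"):
    mu, sys, rand = report["interfraction_summary"]["per_axis"][ax]
    print(ax, round(mu, 2), round(sys, 2), round(rand, 2))
# lr -0.51 1.75 1.20
# ap -0.15 1.83 1.47
# si  0.38 2.65 1.57
```

Reading the output: the simulated abdominal subject drifted ~1.7 mm
inferior and ~0.5 mm anterior over 20 minutes (the prescribed saturating
drift, minus the respiratory offset of the smoothed reference frame —
see the methods note), staying inside the ±2 mm/±1° tolerance the whole
session, hence a BDT of 20 min. The inter-fractional summary decomposes
the per-axis setup errors of 15 simulated subjects × 5 repetitions into
overall (μ), systematic (Σ) and random (σ) components; with generator
truth Σ* = 2.0 mm and σ* = 1.5 mm, the recovered values above are within
sampling error at n = 15 (σ is additionally biased low by c₄(5) ≈ 0.94,
a property of the mean-of-SD definition). `demo_out/` also contains the
grid-accuracy table (sub-0.2-mm 3D errors at 0.5-px detection noise), the
full displacement series CSV, and `report.json` with provenance (seed,
config hash, version).

The same stages are available as a CLI for file-based use:

```bash
surftrack simulate --seed 1 --out sim/            # clouds, detections, truth
surftrack intrafraction --clouds sim/clouds.csv --setup abdominal --out series.csv
surftrack bdt --series series.csv --setup abdominal --out bdt.json
surftrack report --seed 1 --out demo_out/         # full demonstration
```

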