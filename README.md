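# laatrack

Speckle tracking of the **left atrial appendage (LAA)** and its thrombus in
2D echocardiographic sequences: anatomically constrained affine optical-flow
contour tracking, the LAA longitudinal strain curve, and an **isolated
thrombus-mobility metric** that separates the thrombus's own motion from the
motion it inherits from the appendage wall.

It is aimed at cardiac-imaging researchers studying LAA thrombi under
anticoagulation (e.g. whether strain and thrombus mobility relate to
thrombus resolution), and ships a speckle phantom simulator with exact
analytic ground truth so the whole chain can be validated without patient
data.

## Method

**Tracking.** Contours segmented at end-diastole (LAA: open 80-point arc;
thrombus: closed 40-point ring) are propagated pairwise between consecutive
frames, half of the cycle forward and half backward around the reference
frame. Each step is a two-stage affine Lucas–Kanade fit over
Gaussian-weighted regions of interest anchored on the contour points
(window half-width 6 mm for the LAA, 3 mm for the thrombus; kernel σ
0.4 mm, truncated at 25 % of the window radius): a single *global* affine
pooled over all ROIs absorbs bulk cardiac motion, then a *localized* affine
per point refines the contour to the anatomy. Tracking is deterministic.

**Strain.** With `L_t` the tracked contour's length (sum of
consecutive-point distances) and `L_ref` its end-diastolic length,

    strain_t = 100 · (L_t − L_ref) / L_ref   [%]

The minimal peak (≤ 0) marks the strongest contraction, the maximal peak
(≥ 0) the strongest relaxation.

**Thrombus mobility.** At each step the thrombus contour is also
propagated by the *LAA motion field alone*, interpolated from the LAA
contour points by inverse-distance weighting with global support
(`w_i = 1/(‖q−a_i‖+ε)²`, all anchors). This *compliant* contour is where
the thrombus would sit if it moved rigidly with the wall;

    d_t = ‖ centroid(compliant_t) − centroid(tracked thrombus_t) ‖   [mm]

isolates the thrombus-specific motion. A fully compliant thrombus gives
`d_t = 0`; the per-case summaries are the mean and maximum of `d_t`.

**Statistics.** Per-case summaries feed a pooled-variance Student t-test,
rank-based ROC/AUC (inversely related variables are inverted first, so
minimum strain reports a c-statistic above 0.5 when predictive), and a
median split into higher-/lower-mobility groups.

## Worked example

```python
import laatrack as lt

cfg = lt.default_scenarios()["responder-like"]   # contracting LAA, mobile thrombus
seq, truth = lt.render_sequence(cfg)             # phantom + analytic ground truth

laa = lt.track_sequence(seq, cfg.reference_laa_contour())
thr = lt.track_sequence(seq, cfg.reference_thrombus_contour())

mn, mx = lt.peak_strain(lt.strain_curve(laa))
mob = lt.mobility_series(laa, thr)
print(f"min peak strain : {mn:6.2f} %   (analytic truth {truth.min_strain_pct:.1f})")
print(f"max peak strain : {mx:6.2f} %")
print(f"mean mobility   : {mob.mean_mm:6.3f} mm  (configured mean step {truth.mean_step_mm:.2f})")
print(f"max mobility    : {mob.max_mm:6.3f} mm")
```

prints

```
min peak strain :  -3.02 %   (analytic truth -3.0)
max peak strain :   2.98 %
mean mobility   :  0.334 mm  (configured mean step 0.33)
max mobility    :  0.538 mm
```

i.e. the tracked strain recovers the phantom's prescribed −3 % peak
contraction to ~0.02 percentage points, and the mobility metric recovers
the configured 0.33 mm mean independent thrombus step to ~0.004 mm —
despite the thrombus also being carried along by the contracting,
translating, rotating appendage.

The same pipeline runs from the shell on saved sequences (multi-page TIFF
+ JSON sidecar with `spacing_mm`/`ref_index`, contours as CSV):

```sh
laatrack simulate --preset responder-like --seed 1 --out run/sim
laatrack track --sequence run/sim/sequence.tiff \
               --laa run/sim/laa_ed.csv --thrombus run/sim/thrombus_ed.csv \
               --out run/trk
laatrack mobility --track-dir run/trk --out run/report
laatrack compare --table cases.csv --out run/stats   # per-case cohort table
```

`run/report/report.json` then carries `min_peak_strain_pct`,
`max_peak_strain_pct`, `mean_mobility_mm`, `max_mobility_mm` and the
per-frame curves.

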