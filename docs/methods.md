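# Methods

This note documents the models, parameters and numerical choices behind
`laatrack`, and what the synthetic validation does and does not show.

## Problem setting

In atrial fibrillation, thrombi form preferentially in the left atrial
appendage (LAA). Two quantities are extracted from a single-cycle 2D
B-mode sequence with a known end-diastolic reference frame: the LAA
longitudinal strain curve, and an *isolated thrombus mobility* — how much
the thrombus moves beyond the motion it inherits from the appendage wall.
Both require tracking contours through the cycle.

## Anatomically constrained affine optical flow

Tracking is ROI-based rather than whole-image: motion is estimated only in
Gaussian-weighted windows anchored on the contour points, which keeps the
estimate local to the structure and insensitive to appearance changes
elsewhere in the sector.

Each frame-to-frame step is a two-stage affine fit:

1. **Global stage.** One affine warp `x → c + A(x−c) + b` (c = contour
   centroid) is fitted by pooling every contour point's ROI pixels into a
   single weighted least-squares problem. It absorbs bulk motion — cardiac
   translation, probe motion, fast contraction of the whole appendage.
2. **Localized stage.** Per contour point, a second affine is fitted in
   the ROI around that point, starting from the global prediction, and
   applied to that point only. It captures the small local adaptation of
   the anatomy.

Both stages minimize the weighted sum of squared intensity differences
between the source ROI and the warped target frame, solved by Gauss–Newton
on the six affine parameters (the affine Lucas–Kanade construction):
residual `r_k = I_b(W(x_k)) − I_a(x_k)`, Jacobian from the target-frame
intensity gradient and the affine basis, weighted normal equations per
iteration. The solver is single-scale (no pyramid) and fully
deterministic.

Defaults (all overridable via `TrackerConfig` / CLI):

| parameter | default | meaning |
|---|---|---|
| `laa_points` / `thrombus_points` | 80 / 40 | contour discretization |
| `laa_window_radius_mm` / `thrombus_window_radius_mm` | 6 / 3 | ROI half-width per axis |
| `kernel_sigma_mm` | 0.4 | isotropic Gaussian ROI weight |
| `support_fraction` | 0.25 | weights truncated to zero beyond this fraction of the window radius |
| `max_iterations` / `tol_px` | 50 / 0.01 | Gauss–Newton cap and max-point-update stop |
| `presmooth_sigma_px` | 1.0 | image pre-smoothing for gradient stability |

The "localized support" is implemented as a hard radial truncation of the
Gaussian at `support_fraction × window_radius`; with the defaults the
effective support is a ±1.5 mm disc inside the nominal 6 mm window. The
truncation keeps the fit strictly local; the wide window exists so the
mask size is stated in physical units.

LAA contours are open ("constant" boundary, an arc across the ostium);
thrombus contours are closed ("periodic"). Both structures are tracked
independently with the same machinery and their own window radius.

**Propagation.** Tracking is pairwise between consecutive frames with a
bidirectional scheme: from the reference, `ceil((T−1)/2)` steps forward
and the remaining frames backward (cyclic indexing). This bounds
accumulated drift symmetrically around end-diastole. The two chains never
meet — each non-reference frame is owned by exactly one chain, so no
blending rule is needed and the result is deterministic.

**Degeneracy handling.** If the normal equations are ill-conditioned
(texture-free ROI) or a solution loses orientation (`det A ≤ 0`), the fit
returns its initialization and warns. A point whose global-stage position
leaves the image skips its local stage (global result kept, flagged);
there is deliberately no out-of-field-of-view regularization.

## Longitudinal strain

`strain_t = 100 (L_t − L_ref)/L_ref` with `L_t` the sum of
consecutive-point distances of the tracked open contour (no closing
segment). The value at the reference frame is exactly zero, so the
minimal peak is ≤ 0 (strongest contraction) and the maximal peak ≥ 0
(strongest relaxation). This whole-contour form equals the
length-weighted mean of per-segment strains; segmental values are exposed
as a diagnostic (`segmental_strain`) only.

## Isolated thrombus mobility

At every propagation step into frame `t`:

1. the thrombus contour at the source frame is propagated by the **LAA
   motion field alone** — each thrombus point receives the
   inverse-distance-weighted (Shepard) average of the LAA anchors' step
   displacements, `w_i = 1/(‖q−a_i‖+ε)^p` over *all* anchors (global
   support). This *compliant* contour is where the thrombus would be if it
   moved rigidly with the wall;
2. `d_t` = Euclidean distance between the compliant contour's centroid
   and the directly tracked thrombus centroid at `t`.

Choices: IDW power `p = 2`, `ε = 1e-6 mm` (both configurable). Global
support with inverse-square weighting reproduces constant fields exactly
— whole-image translation contributes nothing to `d_t` by construction.
Centroids are vertex means (the tracked point set is what the motion
displaces; no polygon-area weighting). `d` at the reference frame is
defined as 0 and excluded from the mean/max summaries, since no step
exists there. `d_t` is computed per step from each track's own
previous-frame contour, not cumulatively from frame 0.

A known property of the decomposition: IDW reproduces constant fields
exactly but is biased for spatially *linear* fields (rotation, scaling,
contraction), because the interpolated value equals the field at the
weighted anchor centroid rather than at the query. On the contracting
phantom this bias is ~0.005 mm per step at the default geometry — two
orders below the signal of interest, but it is why metric-purity checks
(perfect contours in, expected step out to 1e-3 mm) are run on the
translation-dominated scenario.

## Phantom simulator

The phantom provides exact ground truth for every downstream metric: a
fully developed speckle texture (complex white noise × Gaussian PSF,
magnitude taken → Rayleigh-like statistics) modulated by a smooth
echogenicity map (dim cavity, bright wall annulus, echogenic thrombus
disc), deformed per frame by the composition of

* a global similarity (translation / rotation / scale about the image
  centre),
* a tapered radial contraction about the cavity centre — pure scaling
  where the LAA contour lives, so the true strain is exactly
  `100 (σ_t·scale_t − 1)` in closed form,
* a rigid thrombus translation inside a smooth bump around the thrombus —
  the independent motion the mobility metric must recover.

All schedules are sinusoids over the cycle, zero at the reference frame.
The thrombus oscillation runs at two cycles per cardiac cycle: a wobble
faster than the heartbeat is what a mobile thrombus looks like, and the
shorter period keeps the required excursion small enough that the bump
deformation stays fold-free (|p|·max|∇w| < 1) at the scenario magnitudes.
`amplitude_for_mean_step` inverts the closed-form relation between
amplitude and the mean per-step displacement along the propagation plan.

Images are rendered by backward warping (bilinear); the backward map
inverts the analytic forward map by vectorized 2D Newton iteration
(converges to <1e-10 mm). Ground-truth contours are transformed by the
closed-form forward maps, never through the pixel grid. Identity
deformations bypass resampling so a static phantom has bit-identical
frames. One RNG stream per config seed covers texture and per-frame noise.

Preset magnitudes anchor to values observed clinically in this setting:
`responder-like` (min strain −3.0 %, mean independent step 0.33 mm),
`nonresponder-like` (−1.5 %, 0.18 mm), plus `static`, `rigid`
(whole-image translation) and `oscillating` (translation + independent
thrombus motion only) nulls/controls. Default imaging: 256×256 px,
0.2 mm/px, T = 20 frames, amplitude SNR 20. These sizes keep a full
render + track + analyze run at a few seconds while leaving per-frame
motions in the 0.5–3 px range typical of cine loops.

What the phantom does **not** emulate: beamforming geometry, attenuation,
shadowing, out-of-plane motion, probe decorrelation of speckle, operator
segmentation variability, and anatomy beyond a circular-arc appendage.
Passing phantom tests therefore demonstrates correctness of the tracking
and metric computations under realistic speckle statistics and motion
magnitudes — not clinical-grade accuracy on patient recordings.

## Cohort statistics

Group comparisons use the classical pooled-variance two-sample Student
t-test (`df = n_a+n_b−2`, two-tailed); zero pooled variance with unequal
means is flagged and reported as p = 0. AUC is the rank-based c-statistic
(ties count ½); variables inversely related to the outcome (minimum
strain) are negated before computing it, so a predictive variable reports
AUC > 0.5 either way. The median split labels values strictly above the
sample median "higher" and values at or below it "lower" — exact-median
ties deliberately resolve to "lower". `binormal_auc`
(Φ(Δμ/√(σ_a²+σ_b²))) is a closed-form oracle used to validate the
empirical AUC on simulated cohorts.

## Known limitations

* Single-scale flow: per-frame displacements beyond the pre-smoothed
  speckle correlation length (~3 px) can fall outside the Gauss–Newton
  convergence basin; the global pooled stage mitigates but does not
  eliminate this.
* The mobility metric's IDW bias under strongly non-uniform wall motion
  (see above); very large appendages with freely floating thrombi are
  outside the metric's assumptions.
* The strain is whole-contour; segmental statistics around the thrombus
  attachment are exposed but unvalidated.
* Phantom realism limits listed above.
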