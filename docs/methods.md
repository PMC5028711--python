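# Methods

This note records the models, conventions and numerical choices behind
`asoct`, in the order the pipeline applies them.

## Coordinate and unit conventions

Lateral position `x` is in micrometres and increases *away from the
limbus*, so arc distance from the scleral spur is non-negative in both
meridians and nasal/temporal scans share one code path. Depth
increases downward; row 0 is the top of the B-scan. Boundary traces
carry a coordinate-space tag: `image` (device-exported, depths scaled
at a uniform tissue index), `optical` (depths below the ACB are
cumulative optical path length) and `physical` (true geometric
micrometres). The default device model is a 1536 × 678-pixel scan over
16 mm (30°), axial resolution 3.9 µm, centre wavelength 870 nm. The
axial *sampling pitch* is not published for this device class, only
the resolution; the default of 3.87 µm/px (in tissue at n = 1.40) is
of the right order and is exposed in `DeviceModel` — no computation in
the package depends on the specific default, because all thickness
arithmetic is done in micrometres.

## Synthetic phantom

The phantom is an analytic cross-section of the limbal region used as
ground truth for every downstream stage.

*Geometry.* The posterior scleral boundary (PSB) is a shallow arc
(`d0 + (x−xc)²/2R`, R drawn 40–70 mm, vertex depth ≈ 1.45 mm) plus a
smooth random perturbation (PCHIP through 9 coarse knots, SD 25 µm).
Conjunctival and scleral thickness are drawn per eye at the five
spur-referenced arc locations from a normative in-vivo table
(`asoct.normative`): a shared eye-level deviation (0.8 SD) plus
per-location jitter (0.35 SD), clipped to ±3 SD of each cell, then
monotone-cubic interpolated over `x`. After sampling, the
characteristic profile shape seen in vivo is enforced deterministically
(scleral maximum and conjunctival minimum at the spur); the anchor
floor keeps the conjunctival compartment at least 60 µm thicker than
the episcleral band. All three boundary curves are single-valued PCHIP
interpolants; `acb < asb < psb` and implied thickness ≤ 1.5 mm are
validated at construction. The scleral spur sits at a drawn
`spur_x` (2.2–2.8 mm from the left edge), leaving > 4 mm of PSB arc in
the image.

*Forward optics.* Per A-scan column the incident ray is vertical. The
ACB is drawn at its geometric depth (the beam above it travels in
air); the ray then refracts at the ACB (1.00 → 1.38) and the ASB
(1.38 → 1.41) using local surface normals, and every deeper interface
appears at (cumulative optical path)/1.40 below the ACB — the inverse
of the correction the analysis applies. Surface normals use the same
5-column smoothed discrete slope estimator as the correction module,
so forward model and inverse share one normal convention; with that
convention the round trip closes to ≲ 0.15 µm (the residual is
interpolation error), comfortably inside the 0.5 µm validation bound.
Ray–curve intersections are solved by fixed-point iteration, which
contracts rapidly because physiologic surface slopes are small (≲ 10°);
total internal reflection raises an error rather than clamping, since
it cannot occur at these indices and slopes and indicates bad input.

*Rendering.* Layers are piecewise-constant in reflectivity
(background 0.03, conjunctiva 0.60, episcleral band 0.30, sclera 0.80,
sub-scleral 0.30, extraocular muscle 0.65 — chosen so the air–tissue
edge is the strongest dark-to-light transition and the posterior
scleral edge the strongest light-to-dark transition, the qualitative
contrast ordering of real anterior-segment B-scans). Edges are
smoothed with an erf profile at the axial resolution. Speckle is
fully developed multiplicative noise (unit-mean gamma, per-frame
sigma = 1.0) averaged over 50 frames — the mean of 50 unit-mean gamma
variates is itself gamma, so the average is drawn exactly. The
hypo-reflective episcleral vessel band (default 60 µm) ends exactly at
the ASB. The optional EOM wedge ramps in from its insertion distance
and sits inside the conjunctival compartment above the band, so by
construction it thickens the conjunctiva, not the sclera. The quality
index is defined as 10·log10(mean scleral signal power / background
intensity variance) in dB, capped at 99; it increases with frame
count, decreases with speckle, and lands near 42–46 dB under the
defaults, comfortably above the 25 dB inclusion gate.

*What the phantom does not emulate:* physically rigorous OCT speckle
statistics (no coherent PSF, no confocal/sensitivity roll-off), motion
artefacts, specular reflections (beyond an optional bright block),
vessels within tissue, or operator variability in scan placement.
Passing tests therefore demonstrate correctness of the *measurement
chain* under realistic contrast and noise, not performance on clinical
images.

## Segmentation

Boundaries are exact minimum-cost monotone paths in a node-per-pixel
DAG: edge weight `2 − (g_a + g_b) + 1e−5` with `g` the polarity-signed
vertical gradient normalised to [0, 1]; vertical moves limited to
±2 rows/column (boundaries are smooth at the 10.4 µm lateral pitch);
ties broken toward the smaller row; dynamic programming gives the
global optimum (validated against exhaustive enumeration), and a
parabolic fit of the gradient across the winning row gives sub-pixel
depth. The protocol searches the ACB over the full depth minus a 5-px
top margin, the PSB strictly below ACB + 100 µm, and the ASB inside the
ACB–PSB band.

Numerical choices that matter:

* **Log-domain gradients for ACB/PSB.** Speckle is multiplicative, so
  gradients are taken on log intensity for the two primary searches;
  this makes the noise additive and the air–tissue edge dominant
  (log contrast ≈ 3.0 vs ≈ 1.0 for deeper edges), preventing the ACB
  path from locking onto the brighter scleral edge at unlucky noise
  draws. `segment_boundary` itself is domain-agnostic; the transform
  is part of the scan protocol.
* **ASB detection.** Within each column the episcleral band is the
  minimum of a smoothed intensity profile between ACB and PSB (with an
  8-px clearance so edge-blur tails are not mistaken for the band); a
  column "has" a band if that minimum is < 0.75 × the median of the
  profile. If > 20 % of columns lack a band the scan errors out
  recommending a manual trace (and a 0-µm band phantom does exactly
  that); isolated gaps are bridged by interpolation. The ASB is then
  the dark-to-light minimum-cost path in a 30-px window below the band
  minimum — which also keeps it below an EOM wedge.
* **Trace polish.** Final traces get a quadratic Savitzky–Golay smooth
  over 21 columns (~220 µm). Anatomy is smooth at that scale, and the
  per-column sub-pixel jitter (~0.3 px) would otherwise contaminate the
  slope estimates used for ray tracing, occasionally to the point of
  refracted rays crossing.
* **Manual corrections** are applied as depth *offsets* interpolated
  (monotone cubic) between operator control points, blended linearly
  over 10 columns at each end — control points equal to the existing
  trace are a no-op, and a single point produces a local bump confined
  to the blend window.

The segmentation lateral extent defaults to spur − 0.5 mm through
spur + 4.8 mm: the measured region plus margin, which is also where
the anatomy is well-behaved.

## Refraction correction

`to_optical_path` multiplies sub-ACB image-space separations by 1.40
(the device's uniform-index assumption); the ACB itself is geometric.
`correct_refraction` then re-propagates each A-scan: refract the
vertical ray at the ACB (1.00 → 1.38) using the 5-column smoothed local
normal, advance (optical segment)/1.38 to the ASB, refract
(1.38 → 1.41), advance (optical segment)/1.41 to the PSB. The episcleral
band lies above the ASB and therefore carries the conjunctival index —
the ASB delimits the scleral index region — and an EOM wedge inherits
the conjunctival index for the same reason. Bent rays land at
irregular lateral positions, so corrected polylines are resampled onto
a uniform 10 µm grid by linear interpolation; rays crossing (fold-over)
or sin(refracted angle) > 1 raise errors naming the offending column.
Whether the real instrument also refracts at the PSB is immaterial
here — nothing deeper than the PSB is measured — so no PSB refraction
is applied. The uncorrected mode (`uniform_scale`) keeps the device
scaling with no bending and is paired with straight-line measurement
locations in the pipeline's sensitivity re-analysis, mirroring how
such re-analyses are done.

The spur annotation (marked in image space) is carried through the
correction by following its A-scan to the corrected PSB intersection,
then projected to the nearest point on the PSB polyline.

## Profiling

Measurement points are found by cumulative chord length along the PSB
polyline from the spur projection (`arc_psb`), or by lateral offset
(`straight_line`). Thickness is `lower(x) − upper(x)` for the axial
metric; the normal metric anchors a line on the reference boundary
(default the ASB — which scleral boundary anchors the normal is a
genuinely open convention; both are available behind
`MeasurementScheme.normal_reference`) along its local normal and takes
the distance between intersections with the two traces. On flat
geometry axial = normal exactly, and for a uniform tilt θ,
axial = normal/cos θ — both are used as closed-form checks. Repeats
are averaged per location.

## Statistics

ICC(2,1) — two-way random effects, absolute agreement, single
measures — is computed from the mean squares
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`; this is the
standard model for test–retest of a single device, and single rather
than average measures is the conservative choice when the reporting
convention is unstated. It is validated against an independent
variance-components oracle and pingouin's `ICC(A,1)`. Identical
columns give exactly 1; zero total variance raises. Repeat-difference
statistics are the mean and SD (ddof = 1) of (measure 2 − measure 1);
within-subject SD is the pooled per-location SD across repeats.
Cohort grids report per-cell mean ± SD across eyes with the meridian
mean as the unweighted mean of the five location cells (this
reproduces the published whole-meridian averages from the published
location means to printed precision: 506/504 µm sclera and 270/249 µm
conjunctiva). Higher-level model fits (repeated-measures ANOVA,
pairwise contrasts, stepwise regression) are deliberately out of
scope: the pipeline emits tidy per-eye tables that any statistics
package can model directly.

## Problem sizes

Validation suites use 20-phantom batches (round-trip optics,
end-to-end recovery, sensitivity direction), 100 random instances for
path optimality against exhaustive enumeration (images up to 8 × 8,
where enumeration is exact and tractable), and 10–40-scan cohorts in
the analysis scripts — sizes at which every check runs in seconds to a
couple of minutes on one CPU while exercising the full image-scale
pipeline (1536 × 678 scans throughout).

## Known limitations

* The phantom's hypo-reflective band is uniform; real episcleral
  vasculature is patchy, so automated ASB detection on clinical images
  would lean more heavily on the manual-correction hooks.
* The spur position is accepted as an annotation (or phantom truth);
  anatomical spur localisation is out of scope.
* Refraction correction is 2-D (single line scans); no corneal-region
  or volumetric correction.
* Repeatability on re-rendered phantoms reflects segmentation noise
  only (within-subject SD well below 1 µm); in-vivo repeatability is
  dominated by scan re-positioning, which the phantom does not model.
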