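# asoct — anterior-segment OCT scleral and conjunctival thickness analysis

The anterior sclera and its overlying conjunctiva can be imaged in vivo
with anterior-segment optical coherence tomography (AS-OCT), but turning
a raw B-scan into comparable thickness numbers takes several non-trivial
steps: the tissue boundaries must be delineated, the device's
refractive-distortion (it scales depth assuming a single uniform tissue
index and ignores ray bending at tissue interfaces) must be undone, and
measurement locations must be defined anatomically — at fixed distances
from the scleral spur measured *along the arc* of the curved posterior
scleral boundary. `asoct` implements that full measurement pipeline,
together with a synthetic B-scan phantom generator that provides exact
ground truth for validating every stage, and the repeatability/cohort
statistics used to report such measurements.

It is written for researchers analysing anterior-eye OCT (ophthalmic
imaging, myopia research, contact-lens and surgical planning) and for
anyone who needs a tested reference implementation of OCT refraction
correction or graph-based layer segmentation.

## Methods at a glance

**Boundaries.** Three boundaries are traced per scan: the anterior
conjunctival boundary (ACB), the anterior scleral boundary (ASB — the
posterior edge of the hypo-reflective episcleral vessel band) and the
posterior scleral boundary (PSB). Each is found as the exact
minimum-cost left-to-right path through a node-per-pixel graph with
edge weights

```
w(a → b) = 2 − (g_a + g_b) + ε ,     ε = 10⁻⁵
```

where *g* is the polarity-signed vertical intensity gradient normalised
to [0, 1]; vertical moves are limited to ±2 rows per column, and the
winning row is refined to sub-pixel precision by a parabolic fit.
Scans are gated on the device quality index (QI > 25 dB).

**Refraction correction.** Exported depths (scaled at a uniform
n = 1.40) are converted back to optical path length and each A-scan is
re-propagated with Snell's law: refraction at the ACB into conjunctival
tissue (n = 1.38), then at the ASB into scleral tissue (n = 1.41),
using local surface normals from 5-column smoothed slopes. The
uncorrected uniform-index mode is kept for sensitivity re-analysis.

**Profiling.** Conjunctival (ACB→ASB) and scleral (ASB→PSB) thickness
are evaluated at 0, 1, 2, 3 and 4 mm of PSB arc length from the scleral
spur, with axial (vertical) or boundary-normal metrics, and repeated
scans are averaged.

**Statistics.** Test–retest agreement uses ICC(2,1) (two-way random
effects, absolute agreement, single measures) computed from the mean
squares of the subjects × measurements layout, plus mean/SD of repeat
differences, pooled within-subject SD, and mean ± SD cohort grids whose
per-meridian means are the unweighted mean over the five locations.

## Worked example

```python
from asoct import make_phantom_spec, render_bscan, true_thickness_profile, RunConfig
from asoct.pipeline import analyze_scan

spec = make_phantom_spec(seed=1, meridian="nasal")   # exact analytic geometry
image, _ = render_bscan(spec)                        # speckled 1536x678 B-scan
print(f"quality index: {image.quality_index:.1f} dB")

profile = analyze_scan(image, RunConfig(), eye_id="demo")["snell_corrected"]
truth = true_thickness_profile(spec)
```

prints

```
quality index: 45.6 dB
location (mm)  sclera (um)  truth  conjunctiva (um)  truth
           0        577.9  578.9             196.1  194.4
           1        450.0  448.9             210.8  209.1
           2        486.8  486.4             202.0  199.8
           3        469.4  469.1             266.6  264.1
           4        400.6  400.4             332.2  330.7
```

i.e. the full render → segment → correct → profile chain recovers the
phantom's true thickness to a couple of micrometres despite realistic
speckle — the scleral maximum at the spur and the conjunctival rise
towards 4 mm are the characteristic in-vivo profile shapes the phantom
generator draws from its normative table.

A command-line interface mirrors the library
(`asoct simulate|segment|correct|profile|run|compare|stats|defaults`), and the
numbered scripts under `analysis/` run the whole study arc: cohort
simulation (01), pipeline recovery (02), repeatability (03),
correction-mode and metric sensitivity (04) and the cohort summary
grid (05), writing their tables under `results/`.

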