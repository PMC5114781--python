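# Methods

## The segmentation model

`renovol` assumes that within a coarsely traced kidney ROI the parenchyma
(cortex + medulla) is the *predominant* tissue and has characteristic
intensity values, so the ROI intensity PDF shows a single dominant mode with
a low-intensity shoulder (vessel flow voids, partial-volume dark rim) and a
high-intensity shoulder (calyces/fluid). The method removes those shoulders
by a two-sided corner ("unimodal"/Rosin-style) criterion and keeps the
closed intensity interval `[lower, upper]` as parenchyma. It fails, by
design, when the assumption fails: tissue with parenchyma-like intensity
inside the ROI (spleen, partial-volume margins) is kept, and a
non-parenchyma mode taller than the parenchyma mode would capture the
default peak selection.

Pipeline, in execution order:

1. **Sample** — all ROI voxel intensities; sample SD uses denominator
   `n − 1`. A constant ROI is an error.
2. **PDF** — exact Gaussian-kernel density estimate with Scott bandwidth
   `h = s·n^{−1/5}`, evaluated on an even grid.
3. **Peaks** — strict interior local maxima with topographic prominence
   ≥ 1% of the global density maximum; the global maximum is the default
   working peak, overridable by 1-based left-to-right ordinal.
4. **Chords** — a line per side from the peak point to the PDF point at
   `peak ∓ 1` sample SD (snapped to the grid, clipped to the grid range).
5. **Corners** — per side, the grid point maximising the perpendicular
   distance to the chord line among points on that side strictly *below*
   the (extended) line. For a fixed line this equals the argmax of the
   vertical deviation `line(x) − f̂(x)`, which is what the code computes;
   the test suite checks index-exact agreement with an explicit
   point-to-line distance search.
6. **Volumetry** — closed-interval keep rule; volumes are voxel counts ×
   voxel volume from the header zooms. No morphological post-processing of
   any kind: kept + below + above is an exact integer partition of the ROI.

The corner search runs along the *whole* flank, not merely between peak and
sigma-point: the sigma anchoring fixes the line's slope (so right-tail
outliers cannot flatten the upper chord), while the corner itself usually
lies beyond the sigma-point — on a pure Gaussian flank the segment inside
1 SD is concave, hence strictly above the chord, and the corner lands near
1.7 SD, removing ~8% of a clean Gaussian rather than ~32%.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `grid_points` | 1024 | — | sub-grid threshold error ≪ 1 intensity unit on 12-bit MR ranges |
| `pad` | 3 | bandwidths | grid captures ≥ 0.99 of the KDE mass |
| `min_prominence_fraction` | 0.01 | fraction of max density | suppresses sampling-jitter maxima while keeping genuine bimodality detectable |
| `endpoint_policy` | `sigma` | — | the method itself; `tail` (chords to the grid ends) exists only for comparison experiments |
| `fallback_on_missing_corner` | off | — | batch robustness aid: uses the chord endpoint when no grid point lies below a chord (exactly triangular flanks); always logged |
| peak choice | global max | ordinal | manual override for bimodal histograms |

Numerical conventions: ties between equal-height global maxima resolve to
the lower-intensity peak; ties in corner deviation resolve to the candidate
farthest from the peak (the more conservative removal boundary); chord
endpoints snap to the nearest grid point (error ≤ half a grid step); voxels
exactly at a threshold are kept. Masks binarize at stored value > 0.5 so
float- and label-coded ROI files load deterministically. A trailing
degenerate 4th NIfTI axis is squeezed; any other 4-D input is rejected.
Header scale slope/intercept are applied on read; no other intensity
normalisation ever is. Image and mask must share a voxel grid — there is no
resampling.

The KDE is evaluated by an exact chunked kernel sum rather than a binned or
FFT approximation so that the density, the peak locations and therefore the
thresholds are reproducible to machine precision and directly comparable to
a per-point oracle. With an explicit `bandwidth` argument the estimator also
accepts a constant sample (useful for single-kernel sanity checks); the
Scott rule itself requires `s > 0`.

## The phantom generator

`PhantomSpec` builds an ellipsoidal kidney (default semi-axes 32 × 19 × 12.6
voxels at 1.0 × 1.0 × 4.4 mm spacing → ~120–150 ml, a realistic single-kidney
parenchyma volume) with per-seed jitter of centre and axes; vessels are
random-walk tubes of radius 1–2 voxels, calyces central blobs, grown until
they occupy the requested fraction of the ROI. The coarse ROI is the body
dilated in-plane by `roi_margin` voxels (tracing is per-slice; dilating
across 4.4 mm slices would not mimic a human overshoot).

Intensity laws (arbitrary units, 12-bit-like scale):

* parenchyma 300 ± 30 — the dominant mode;
* vessels 130 ± 95, 8% of the ROI — flow voids smeared by partial volume
  over a wide dark range;
* calyces 560 ± 150, 5% of the ROI — bright fluid, likewise smeared;
* background 60 ± 20 outside the ROI;
* the dilated rim inside the ROI draws from the *parenchyma* law: it stands
  for partial-volume kidney margin, which the method deliberately does not
  remove.

All laws are normals truncated at zero by resampling — truncation by
clipping would deposit an atom of probability exactly at 0 and hence an
artifactual KDE peak no real histogram has. The broad contaminant SDs are a
modelling choice with a measurable consequence: they produce the
unimodal-with-shoulders PDFs this method presupposes. Tightening the
contaminant SDs to ~30 creates genuinely multi-modal histograms (useful for
removal-recall tests, and so used in the suite); the default regime instead
keeps the secondary shoulders below the 1% prominence floor.

The default contaminant load (8% + 5% of the ROI) places phantoms in the
~13% removal regime reported for coarse kidney pre-segmentations.
`bimodal_spec()` splits the parenchyma 50/50 into sub-modes 290 ± 15 and
335 ± 15 (45 units apart, under twice the combined parenchyma SD of ~27)
with a lighter, wider contaminant load, yielding exactly two detected peaks.

What the phantoms do **not** emulate: anatomy beyond an ellipsoid, MR noise
correlations, bias fields, motion, neighbouring organs of similar intensity,
or operator variability in tracing. Passing the phantom-recovery tests
therefore shows the *algorithmic* chain is correct and well-conditioned in
its intended regime; it does not certify accuracy on clinical data.

## Expected behaviour in the design regime

On the default phantoms the thresholds land near ±1.9 parenchyma SDs of the
mode, so the pipeline over-removes slightly (mean removed fraction ~0.165
against a planted 0.13): ~5% of parenchyma tail voxels go with the
contaminants while a small tail of each broad contaminant law survives
inside the kept band. The net ground-truth tracking error stays under 0.05
with kept/parenchyma Dice ≥ 0.91, and switching the working peak on bimodal
phantoms moves the kept volume by < 0.3% of the ROI volume — the override
insensitivity expected when the two modes sit well inside both chords.

## Agreement statistics

Differences `d = a − b` per kidney: two-tailed paired t with
`df = n − 1` and t-quantile 95% CI; MAD = mean(|d|); Pearson r with
Fisher-z CI (normal quantile, `n − 3` scaling); Bland–Altman bias ± 1.96·SD
limits of agreement (SD with `ddof = 1`). The 1.96 multiplier is fixed: it
reproduces published kidney-volumetry agreement intervals from their printed
bias/SD to rounding, e.g. bias 2.9 ml and SD 4.5 ml give limits
(−5.92, 11.72) ml against a printed (−6.1, 11.8) — the discrepancy is the
print-rounding of the inputs, ≤ 0.05 + 1.96 × 0.05 ≈ 0.15 ml plus 0.05 ml on
the limits themselves, hence the 0.25 ml test tolerance.

## Problem sizes

The test suite and the acceptance script size their simulations for a
single-CPU desk run: unit tests use a reduced 64 × 64 × 20 phantom
(~9 000-voxel kidney), the end-to-end batch uses twenty full 96 × 96 × 28
phantoms (~30 000 ROI voxels each), mixture oracles use 3 000-point samples,
and agreement checks use n = 48 pairs, matching a 24-subject/48-kidney
cohort shape.

## Known limitations

* One ROI = one kidney per run; batch processing iterates externally.
* No DICOM ingestion, no registration/resampling, no bias-field correction.
* The corner criterion needs the PDF to sag below the chord on each side; a
  perfectly triangular (or heavily discretised) flank has no corner and is
  reported as an error unless the endpoint fallback is enabled.
* Results on real scans depend on the coarse tracing: tissue of
  parenchyma-like intensity included in the ROI is never removed.
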