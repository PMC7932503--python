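# Methods

This note documents the models, algorithms and numerical choices behind
`bari`, the assumptions they rest on, and what the synthetic phantom does
and does not emulate.

## Coordinate and unit conventions

Frames are indexed `(frame, row, column)`; the row index is axial depth
*y* increasing downward (as on a B-mode display) and the column index is
lateral position *x*, so the anterior (top) wall satisfies `y_t < y_b`.
Contours are tracked in pixel rows; diameters are converted to millimetres
via the axial pixel spacing and time is in seconds throughout.  Spacing
and frame timing are always taken from file metadata (DICOM `PixelSpacing`
and `FrameTime`/`FrameTimeVector`/`CineRate`, or the JSON sidecar of a
TIFF stack); a file without them is refused rather than defaulted, because
every downstream quantity is physical.

## Wall segmentation

The lumen boundary is found per frame by a morphological geodesic active
contour — an edge-stopping level-set evolution (scikit-image
implementation) — with an inverse-Gaussian-gradient edge indicator
`g = 1/sqrt(1 + α·|∇G_σ I|)` and a positive balloon force, initialised at
the boundary of the user rectangle and therefore evolving *outwards* until
the wall's brightness contrast stops it.  The assumptions: the rectangle
lies wholly inside the lumen with a margin from both walls at every phase
of the cycle, and the lumen-wall interface is the strongest axial edge in
its neighbourhood.

All constants live in `LevelSetConfig`.  Defaults (σ = 2 px, α = 1000,
balloon threshold 0.5, one smoothing pass) were fixed by the phantom
benchmark: with them the edge indicator stays near 1 in the speckled lumen
and tissue but falls well below the balloon threshold in the wall-edge
trough.  The evolution runs in blocks of 10 iterations and is declared
converged when fewer than 0.5 % of region pixels change per block for two
consecutive blocks — a morphological front keeps flickering by a few
boundary pixels at equilibrium, so demanding an exactly static region
would spuriously fail.  A frame is flagged failed (never silently
returned) when the budget (400 iterations) is exhausted, when the region
reaches the top/bottom image border (nothing stopped it — e.g. a uniform
frame), or when the converged contour does not surround the seed.

Frames after the first warm-start from the previous frame's converged
region eroded by 7 px; the erosion covers the fastest inward wall motion
between frames (early-diastolic collapse at ~6 mm/s is ~5 px/frame per
wall at 30 frames/s and 21 µm pixels), and the seed rectangle is always
unioned back in.  A flag (`warm_start=False`) forces independent
re-initialisation for ablation.  The evolution domain is cropped laterally
to the rectangle plus a 6-px margin; lateral border contact is harmless
(the vessel normally spans the full field of view laterally).

Contour points are split into anterior/posterior groups by the vertical
midline of the seed rectangle; at each column of the rectangle's lateral
grid, multiple row values within a group ("S"/"Z"-shaped contours) are
reduced by their arithmetic mean, and a column with no point in a group is
QC-masked.  An optional sub-pixel refinement (default on) then moves each
wall sample to the parabolic peak of the smoothed axial intensity gradient
within ±5 px of the level-set estimate (Gaussian smoothing σ = 1 px axial,
2 px lateral — lateral smoothing is safe because walls are locally
near-horizontal).  The level set contributes robustness and topology; the
refinement contributes precision: on the phantom it reduces the mean
localisation error from the half-pixel quantisation of a binary region
boundary to well under a tenth of a voxel.

Recording-level QC (`QcThresholds`) excludes a recording when more than
50 % of (x, t) cells are masked, when the column-median frame-to-frame
wall displacement exceeds 5 px anywhere (discontinuous tracking), or when
the mean intensity inside the detected lumen exceeds 35 % of the frame's
99th-percentile brightness — the proxy for a slice-thickness artefact,
the most common cause of unusable clinical recordings.  Thresholds are
explicit configuration; the exclusion *criteria* are a design choice of
this package.

## Cycle partitioning

Systolic peaks are detected on a 5-sample moving-average copy of each
cross-section's waveform with a prominence of 25 % of the robust
(5th–95th percentile) amplitude, then snapped to the raw-waveform maximum
within one smoothing window (smoothing shifts extrema on asymmetric
pulses).  Troughs are the raw minima between consecutive peaks; before the
first peak the last minimum is used and after the last peak the first, so
flat diastolic plateaus at the recording edges resolve to the sample
adjacent to the cycle.  Cycles cut off by the recording edge fail the
minimum-window-length check (4 samples) and are dropped.  Detection is
automated but a manual annotation mapping (per cross-section lists of
trough/peak/trough sample indices) overrides it entirely, reproducing a
hand-marked workflow.  Smoothing is used for *detection only* — fits
always run on raw samples, to avoid biasing time constants.

## Exponential fitting

Dilatation windows are fitted with `D_d(t) = A_d − B_d e^{−(t−C_d)/T_d}`
and relaxation windows with
`D_r(t) = A_r + B_R1 e^{−(t−C_r)/T_R1} + B_R2 e^{−(t−C_r)/T_R2}`,
minimising the summed squared residuals with the Nelder–Mead simplex.
Choices worth recording:

* **Initialisation.**  A and C start at the midpoints of the window's
  diameter and time ranges; every exponential amplitude starts at the size
  of one pixel; T_R2 starts at the window duration and T_R1 = T_R2/10.
  The dilatation rise constant starts at a quarter of the window duration
  (a rise constant comparable to the upstroke keeps the model peaked, see
  below).
* **Positivity.**  Time constants and amplitudes are optimised in
  log-space; Nelder–Mead is unconstrained and the raw parameterisation can
  cross zero.  A and C remain unconstrained; C is mathematically redundant
  given free amplitudes (`B e^{(C)/T}` is the identified combination) but
  is fitted for fidelity to the initialisation scheme.
* **Restarts.**  3 starts by default; starts beyond the first jitter the
  positive parameters log-normally (sd 0.2) and A/C additively, with a
  fixed seed, so fits are deterministic.  Tolerances 1e-8 on cost and
  simplex, 2000 iterations.
* **Relabelling.**  After convergence the time constants are relabelled so
  T_R1 < T_R2 regardless of the initial ordering.
* **Rejection.**  A relaxation fit is rejected when the optimiser failed,
  when rmse > 2 pixels, when T_R2 falls outside [0.05, 10] s, or when
  T_R2/T_R1 < 2 (timescale collapse: the decay is effectively
  mono-exponential and carries no two-timescale information).  The
  thresholds are explicit configuration standing in for what is, in
  clinical practice, a judgment call.

**Identifiability.**  Bi-exponential decay with a free asymptote is
notoriously ill-conditioned when the observation window is shorter than
the slow time constant: A_r, B_R2 and T_R2 trade off almost linearly.  A
Fisher-information calculation at typical conditions (window ≈ 1 s at
50 Hz, amplitudes a few tenths of a millimetre, diameter noise of half a
pixel) puts the attainable relative standard error of a single window's
T_R2 at several tens of percent.  `recovery_experiment` measures exactly
this: noiseless windows are recovered essentially exactly (the cost
landscape is benign — the Nelder–Mead solution is never worse than a
dense (T_R1, T_R2) grid with exact linear-amplitude solves), while at
voxel-scale noise the per-window scatter is large.  This is why BARI is
defined as a *mean* over all accepted windows of a recording, and why the
per-window values should never be interpreted individually.

## BARI and cohort statistics

BARI = arithmetic mean of T_R2 over all accepted (cross-section, cycle)
fits, pooling cycles and positions; a per-cross-section-first average and
a T_R1 aggregation are available behind flags for sensitivity analyses.
A recording with no accepted fit has an explicitly missing BARI with the
reason recorded.  Classification against the pilot threshold (1.5 s)
requires the caller to state which side means "fast"; a value exactly at
the threshold goes to the ≥ side.

Size groups follow the printed clinical bands — small 30–39 mm, moderate
40–55 mm (both ends closed), large strictly >55 mm; diameters in the open
interval (39, 40) mm, unassigned by the printed bands, are labelled small
(the band boundary is read as "below 40").  Sub-aneurysmal or absent APD
maps to the healthy-volunteer label.  The two-group comparison reports
*both* an unpaired t-test and a Mann–Whitney U next to medians/IQRs (a
rank test is the one consistent with the median/IQR summary; both are
emitted, labelled).  The size-group comparison uses Kruskal–Wallis with
pairwise Mann–Whitney follow-ups, Bonferroni-adjusted.  The growth
analysis reports the Spearman correlation and the ordinary-least-squares
slope of BARI against %growth/year, counting only participants with
complete follow-up.

## The phantom

`simulate_diameter_trace` builds the waveform directly from the forward
model: per cycle, the exponential rise over trough→peak and the
bi-exponential decay over peak→next-trough, with amplitudes re-solved at
each junction so the waveform is continuous (the fitting stages treat
windows independently, but a ground-truth generator must be unambiguous).
Defaults program four cycles with systolic peaks at 0.5, 1.5, 3.0 and
4.0 s — note the irregular beat-to-beat spacing of a real recording — a
~3 mm diastolic diameter, and T_R1 = 0.08 s, T_R2 = 1.2 s.  The dilatation
rise constant (0.25 s) is comparable to the upstroke duration so the
systolic peak stays peaked rather than plateauing at the asymptote, as in
real arterial waveforms.

`simulate_cine` rasterises the trace into frames: a dark lumen band
between two bright wall bands (8 px thick) in a mid-gray tissue
background, with wall edges anti-aliased by exact pixel-coverage so the
true sub-pixel positions are well defined.  Echogenic regions carry
multiplicative unit-mean Rayleigh-envelope speckle (the standard
first-order B-mode model), blended by a contrast parameter (default 0.5);
the whole frame gets additive Gaussian noise (default sd 2 % of full
scale) and is quantised to uint16.  Pixel spacing defaults to 21 µm, the
voxel size of the clinical recordings this emulates.

What the phantom does *not* emulate: point-spread-function convolution of
a scatterer field (speckle here is spatially uncorrelated), attenuation
and time-gain compensation, out-of-plane motion, wall-thickness texture
(intima/media layers), vessel curvature or tilt, and probe/patient motion.
Passing phantom tests therefore demonstrates the correctness and noise
robustness of the *algorithms*, not clinical-grade performance on real
recordings — in particular, real slice-thickness artefacts are only
approximated by the injected bright-band surrogate used in the QC tests.

## Problem sizes in the shipped experiments

The wall-accuracy experiment (`wall_error_experiment`, also run by
`scripts/acceptance.py`) uses 20 seeded replicates of a two-cycle loop at
30 frames/s (60 frames of 232×64 px): per-seed error statistics stabilise
well below a replicate's worth of variation at this size, and the error is
a per-cell statistic pooled over ~5 000 (x, t) cells per loop, so longer
loops only replicate the same measurement.  The recovery experiment uses
100 replicates per noise level on 1.2 s windows at 50 Hz with true
parameters drawn uniformly from ranges centred on the cohort-typical
values (T_R2 ∈ [0.6, 1.4] s, T_R1 ∈ [0.05, 0.12] s, amplitudes 0.2–0.6 mm,
asymptote ≈ 3 mm).

## Known limitations

* Per-window T_R2 precision at realistic noise is bounded by the model's
  intrinsic degeneracy (see *Identifiability*); BARI inherits a positive
  small-sample bias from averaging a constrained, right-skewed estimator.
* The ROI must be placed by the user; there is no automatic lumen
  detection, and a rectangle that touches a wall at any cardiac phase
  invalidates the outward-evolution premise.
* The segmentation assumes a roughly horizontal vessel in the field of
  view; strongly tilted or curved vessels violate the top/bottom midline
  split.
* `write_cine` emits a minimal multi-frame grayscale DICOM (image module
  only) intended for phantoms and round-tripping, not a clinically
  conformant object.
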