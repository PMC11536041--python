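# Methods

This note records what each estimator computes, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices made where the written measurement procedure left room.

## Morphological classification

A neuron is classified AcD when its axon distance — the arc length of the
annotated stem-dendrite polyline from the soma edge to the axon origin —
strictly exceeds both 2 µm and the stem-dendrite diameter
`d = (d₁ + d₂) / 2`. Both inequalities are strict ("longer than",
"larger than"); an axon distance of exactly 2 µm is nonAcD. Cells whose
axon leaves the soma directly have axon distance 0 and need no width
chords; cells with a nonzero distance but missing chords are rejected
rather than guessed. Shared-root cells (axon fused with a dendrite) are
annotated like any other cell and fall out as nonAcD. Cells with more
than one axon are excluded before classification.

**Oblique axon origins.** When the short segment marking the border of
the axon start is not parallel to the local soma-edge tangent, the
distance is taken from the soma edge point to the axis through the centre
of that segment, perpendicular to it. The written construction gives no
angular criterion for "not parallel"; we trigger it above 15°, large
enough that annotation jitter on near-parallel edges cannot flip the
measurement mode. This threshold is a package choice and is exposed as
`OBLIQUE_ANGLE_DEG`.

Classification is invariant under rigid motion of all annotation
geometry, and arc length is additive over concatenated paths; both are
property-tested.

**Event summaries.** Developmental event tables hold one row per (cell,
event). Proportions are category counts over the total; numeric events
(formation-time bins, in hours) additionally get the count-weighted mean
of bin centres — e.g. bins 27/33/39/45/51 h with counts 3/7/9/4/4 average
to 38.78 h ≈ 39 h.

## AIS geometry

The AnkG profile is smoothed with a centred boxcar of
`round(4 µm / pixel)` samples — a moving *window*, not a Gaussian scale —
with edges shrinking to the valid part so length is preserved. The peak
of the smoothed curve (ties → smallest index) anchors a two-sided walk
that stops at the last sample still ≥ 40 % of the peak; the crossing
sample itself is excluded. The 40 % threshold is applied to the smoothed
curve (the walk is defined on it); this interpretation choice is noted
here because the alternative — walking the raw profile — is equally
readable from the procedure's description. Start/end convert to µm as
`index × pixel`, length = end − start, and AIS distance = start.

A peak at the profile boundary, or a walk that reaches the boundary while
still above threshold, flags the measurement **censored** instead of
silently truncating it; censored cells stay in the per-cell table but are
excluded from group mean ± SEM summaries. Relative thresholding makes
edges exactly invariant to intensity scaling; on noiseless profiles a
plateau shift moves both edges by the same amount up to one pixel.

Expected accuracy: the 4 µm window blurs each edge by up to half a
window, so recovered edges are trusted to ±2 µm; the test suite checks a
median absolute length error ≤ 2 µm over 100 profiles at noise SD 0.1 and
1 µm shoulders.

## MPS periodicity

**Direct spacing.** 5-px boxcar smoothing, then `scipy.signal.find_peaks`
with a relative prominence of 0.2 × (max − min) — the original script's
peak finder has unstated selectivity, so the default is intensity-scale
free and configurable. Spacings are integer index differences × pixel
size (20 nm for STED data), deliberately quantized exactly as the direct
method is; peaks cannot occur at the first/last sample, so truncated edge
rings never enter the spacing list. A 190 nm lattice therefore yields
alternating 180/200 nm index spacings that average back to 190 nm.

**Autocorrelation period.** Mean-subtracted, *unbiased* (per-lag
normalized) autocorrelation; the biased estimator's linear taper drags
peaks toward smaller lags on short profiles. The period is the **first**
local maximum above a confidence floor (default 0.2) in the 100–400 nm
search range, refined by a parabola through the three lags around it.
The first — not the highest — maximum is used because for any periodic
signal the maxima at one and two periods are nearly equal in height:
with a ~195 nm period both fall inside the search range and noise would
otherwise flip the estimate to the second harmonic. Sub-pixel refinement
is what lets a 196 nm period be representable at 20 nm sampling. The
estimator is exactly invariant to affine intensity transforms, rejects
profiles shorter than 3× the upper search bound, and rejects aperiodic
profiles (white noise autocorrelates at O(1/√n), far below the floor).
Its median error shrinks monotonically as profile length doubles from
~2 µm to ~8 µm (tested over 50 seeds).

**Cross-correlation offset.** Normalized cross-correlation between two
equally calibrated channels; the lag of the maximum within ± one period
(period from channel a's autocorrelation), parabola-refined. Positive
offsets mean channel b is shifted toward increasing position. The
alternation flag is set when |offset| ∈ [0.25, 0.75] × period — the
signature of spectrin bands interleaving actin rings, which sit at half
a period.

## Kymograph motility

Kymographs are built by sampling each frame along the annotated polyline
at 1-px arc steps (bilinear interpolation), averaging over the line
width (default 3 px) along the local normal; rows are frames. Extraction
paths are drawn soma → distal, so increasing arc position is anterograde.

Segmentation operates on the n−1 frame-to-frame displacement intervals
of an n-point trace; every interval ends in exactly one of run / pause /
passive / unclassified (the partition is property-tested, and the scanner
is verified against an exhaustive window-enumeration oracle on *all*
{−1, 0, +1} traces up to 12 frames).

* **Runs.** "Five continuous pixels and frames" is read conjunctively: a
  stretch of same-sign displacements spanning ≥ 5 frames *and* ≥ 5 px of
  total displacement; both minima are separate parameters so looser
  readings remain expressible. A run may absorb **at most one**
  zero-displacement frame in total (`absorb_zero_frames ∈ {0, 1}`,
  default 1): a single dropped frame inside a genuine run — pixel
  quantization of sub-pixel motion — does not split it, while the
  canonical passive pattern (move 1 px, stop 1 frame, repeatedly), which
  contains a zero every other frame, can never be promoted to a run.
  Back-to-back runs of opposite sign are distinct segments; sign flips
  between consecutive runs are the direction-change count.
* **Pauses.** A stall of k zero displacements occupies k + 1 frames;
  "stalled for at least three frames" → k ≥ 2. Position equality is
  exact by default (`position_tol_px = 0`, matching the integer pixel
  coordinates of hand-traced kymograph tracks); for sub-pixel traces set
  `position_tol_px = 0.5`.
* **Passive.** Remaining intervals with |move| ≤ 1 px, cargo preset
  only.
* **EB3 preset.** run ≥ 2 px over ≥ 2 frames (the published threshold
  names only the 2 px; the symmetric 2-frame minimum is our choice),
  pauses of 2–10 frames, no passive class (plus-end growth is
  unidirectional); a stall occupying more than 10 frames is a
  catastrophe that terminates the comet trace.

A track is mobile iff it has at least one run; direction follows the
sign of net displacement (last − first position). Time fractions are
computed over the full frame span; velocities are
|displacement| × pixel / (intervals × frame interval), so doubling the
frame interval exactly halves every velocity. Comet density is reported
per µm of path per minute of recording — the normalization was not
stated in the original description, so it is fixed here and documented.

## Puncta and colocalization

Puncta detection thresholds the channel (explicit value, or Otsu
computed from ROI pixels when unspecified — Otsu is a test default, not
a scientific recommendation), applies a gradient-magnitude (fine-edges)
step to delineate outlines, and labels connected components of
≥ 4 px² (configurable) as puncta. Components are labelled on the whole
thresholded image; the ROI acts through the centroid rule — a cluster
straddling the ROI border keeps its full area and counts iff its
centroid is inside. Linear density is count / AIS length × 5 µm.

Axis mapping projects each centroid to the nearest point of the
reference polyline (shapely projection, verified against a dense-
sampling oracle); centroids farther than a 10 px gate are flagged
unmapped. Colocalization uses the inclusive per-axis box — |Δx| ≤ 8 px
and |Δy| ≤ 8 px, "(x and y)" reading — with greedy one-to-one matching
by increasing Euclidean centre distance: one presynaptic punctum pairs
with one postsynaptic punctum. On fields whose planted pairs are
separated by more than the box from all other points, greedy matching
equals maximum-cardinality matching (tested against a bipartite-matching
oracle). ROI intensity is mean(ROI)/mean(background), with the automatic
background defined as pixels outside the ROI below the image's 20th
percentile. The IQR rule keeps values in [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
with linearly interpolated quartiles; fewer than four values pass
through with a warning.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed); identical calls are
bit-identical. Noise is additive Gaussian on intensity, scaled to the
signal amplitude and clipped at zero — a desk-scale stand-in for
fluorescence background statistics. Defaults mirror the study
conditions: 20 nm/px and ~190–200 nm periods for MPS profiles (ring FWHM
80 nm ≈ STED PSF), 0.08–0.13 µm pixels, 0.2–1.3 s frame intervals, AcD
axon distances lognormal around the 7.75 µm population median, stem
diameters ~2 µm, soma radius 7.5 µm.

* MPS profiles are Gaussian combs on the pixel grid; the antiphase
  partner is shifted exactly half a period.
* AnkG profiles are unit plateaus with error-function shoulders, sampled
  at pixel centres `x_i = (i + 0.5)·px`, so a 5–35 µm plateau at
  0.08 µm/px occupies indices 62..437 exactly.
* Kymographs integrate a state schedule (pause → hold; passive → the
  deterministic move-1/stop-1 alternation with sign reversals) and
  render one Gaussian spot per frame — no photobleaching, no drift, no
  multi-particle crossings, so per-row argmax recovers the planted trace
  exactly in the noiseless case.
* Neuron tables realize each planted label as concrete geometry (circular
  soma, straight stem path) that satisfies or violates the
  classification rule by construction.
* Puncta fields plant exactly n colocalized pairs and keep every other
  point farther than the box from the opposite channel.

Passing recovery tests on these inputs demonstrates that the estimators
are correct for their stated models; it does not certify performance on
real images with uneven background, clustered or crossing particles,
curved/blurred AIS edges, or annotation error — those effects are
deliberately outside the generators.

## Problem sizes and tolerances

Simulation-recovery checks use 50–100 profiles per condition (noise SD
0.1–0.25), 50 planted puncta fields, 100 annotated cells, and exhaustive
trace enumeration up to 12 frames — sizes at which every suite's
statistics are stable from seed to seed. The acceptance script reports
mean autocorrelation periods over 50 profiles per condition at noise SD
0.15, with all per-profile seeds derived from a single `--seed` via
`numpy.random.SeedSequence`.
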