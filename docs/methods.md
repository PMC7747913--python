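# Methods

This note documents the models, numerical choices and limitations of
`octmosaic`: what each stage assumes, which parameters matter, what the
synthetic scenes do and do not emulate, and where the design was
genuinely open.

## Coordinate and unit conventions

2D images are indexed `(y, x)`; B-scans `(z, x)` with depth z increasing
away from the vitreous; volumes `(b_scan, z, x)`. Offsets are `(dy, dx)`
such that `frame == roll(reference, (dy, dx))`, resolved to the centred
interval `(−N/2, N/2]` (smallest-motion hypothesis on ties). Angular
extent converts to retinal distance at 1° = 300 μm. The acquisition
geometry defaults to the wide-field protocol: 28° × 21° volumes of
1024 × 250 A/B-scans at (8.2, 25.2) μm lateral pitch, seven fixation
regions overlapping by one third, three repeats each. Desk-scale
experiments use `AcquisitionGeometry.desk()` (256 × 128 samples at the
same pitch, 128 depth samples of 3 μm), chosen so a full closed-loop
simulation plus segmentation runs in seconds on one CPU; all spatial
parameters that depend on image width (ILM smoothing window, pyramid
minimum part size) are scaled proportionally when used at desk scale.

## SLO preprocessing

Saturated reflections are detected by thresholding. The instrument's
threshold was tuned on histograms; here the default is the 98th
intensity percentile (saturated reflexes occupy the extreme tail), a
config key (`slo.threshold_percentile`) since no published value
exists. Mask cleanup uses closing with a disk S (default 15 px) and
growth by a disk T (default 5 px); S ≥ T is enforced rather than S > T
so degenerate 1-px cases remain expressible. The closed mask is
smoothed with an 11 px box filter and applied as
`F = I · min(1 − CM_smooth, H)` with a separable 2D Hamming window, so
masked regions and frame borders both decay smoothly to zero before the
FFT.

The tracking reference averages the 10 frames with the highest
usable-pixel counts out of 20, after registering the other 9 to the
best one by integer phase-correlation offsets. The average is
re-preprocessed before use. On static noisy scenes this reduces pixel
noise by ≈ √10, which the test suite checks to 20%.

## Phase correlation and the high-pass filter

The correlation surface is
`r = F⁻¹[ G · FF* / (|G · FF*| + ε·m) ]` where `FF` is the reference
spectrum multiplied twice by the high-pass gain and `m` is the median
cross-power magnitude, making ε (default 1e-9) dimensionless. The
high-pass is implemented as `1 − exp(−|ω|²/(2s²))` — a unit-peak
Gaussian notch at DC — with `s = X/8` by default; only sharp edges
(vessels) should drive the correlation, and double application lets the
per-frame loop skip filtering entirely. The exact functional form of
the original instrument's filter is not published; this form satisfies
the stated intent (DC suppressed below 1e-3, unit gain at high
frequency) and is a config key.

Subpixel peaks: the surface is smoothed with a 3×3 Gaussian, and the
fractional offset is the centroid of the row/column marginals of the
3×3 neighbourhood around the argmax **after subtracting each marginal's
minimum**. The subtraction matters: the flat correlation floor
otherwise biases the centroid toward the integer bin (measured max
error 0.26 px vs. 0.21 px with subtraction over 100 random subpixel
shifts; two equal adjacent bins land exactly on their midpoint only
with it).

## Tracker gating and the retake loop

Estimates are rejected when the step since the last valid offset
exceeds `tracker.max_step` (default 50 px/frame — a scanner-safety
bound, deliberately generous) or the peak falls below
`tracker.peak_factor` (default 0.5) times the rolling mean of the last
60 valid peaks; with an empty history an absolute floor (0.02) applies.
The 0.5 factor is a package choice: the dynamic rule is only specified
as "derived from the recent average", and half the running mean rejects
blinks (peak ≈ 0.01 on lid-closed frames) while tolerating the ~2×
peak variation of normal frames.

The closed loop runs at 60 Hz with ~1.14 B-scans per SLO frame and
one-frame latency between estimate and scanner correction (the real
system responds in 4.5–21 ms). An invalid frame rewinds the B-scan
index by 4 (`tracker.rollback_bscans`) — enough to cover the 2–3
B-scans that may already be compromised when a blink is first detected,
since lid closure takes ~110 ms (≈ 6 frames) — and acquisition resumes
only on valid tracking, overwriting the rewound positions. The final
volume therefore contains only B-scans acquired under valid tracking;
the trajectory log retains every scan event including overwrites.

For a ±50 μm, 0.5 Hz sinusoidal fixation drift the worst-case loop
error is (max drift speed ≈ 157 μm/s) × (latency ≈ 17–33 ms) ≈ 3–5 μm
plus estimator noise, i.e. well under 1 SLO pixel (10 μm) — the
simulations measure ≈ 0.2 px SD, comfortably inside the 2.5 px bound
used in the tests.

## Layer segmentation

The per-A-scan threshold `t(x)` is the mean of the top
`ceil(top_fraction · depth)` values (default 0.5, reproducing "top 512
of 1024" at full depth while scaling to desk volumes). Cleanup uses a
1 px closing disk and removal of patches under 50 px. The closing disk
default was reduced from an initial 2 px: at noise levels of 20% of
band contrast, a 2 px closing merges suprathreshold noise specks into
blobs large enough to survive the patch filter and corrupt the topmost-
pixel ILM estimate, while 1 px closing leaves them removable. Both are
config keys.

The ILM is the smoothed topmost foreground pixel (101 px window at full
width; shrink-at-border normalization; gaps interpolated from
neighbours). IS/OS weights are a large-kernel (15 px) antisymmetric
axial gradient — mean below minus mean above — clipped at zero and
masked for `z < ILM + kernel/2` so the ILM's own edge cannot win. The
RPE uses `1 − DOPU` masked to below the IS/OS; without a DOPU channel
an intensity-gradient fallback runs with a warning. The path model is
dynamic programming over columns with |Δz| ≤ 1, maximizing accumulated
weight; it equals exhaustive enumeration on all small grids tested and
is the standard graph formulation for layer boundaries. All-zero weight
fields return a flat mid-depth path with a warning rather than failing.

Flattening shifts each A-scan by an integer number of samples so the
RPE sits at the median RPE depth; the shift map is retained and
`unflatten_volume` inverts it exactly on interior samples.

## En-face projection and repeats

The projection sums intensity over a 30 μm band centred at the
flattened RPE. Band placement relative to the segmented line is not
published beyond a figure; centred is the default and the band centre
is overridable. Band edges falling between samples get fractional
weights, so the projection is continuous in the band thickness.
Repeated volumes are aligned by integer phase-correlation offsets to
the first projection and averaged with a per-pixel divisor; a member
whose peak falls below a threshold is dropped with a warning — the
automated stand-in for visual rejection of motion-corrupted scans.

## Registration

The fundus reference is the photo's green channel (highest vessel
contrast), rescaled to 8.2 μm/px so one reference pixel equals one OCT
fast-axis pixel, zero-padded because the mosaic extends past the photo.
Projections are resampled to isotropic 8.2 μm pixels (slow axis
upsampled by 25.2/8.2) before any correlation.

Pincushion correction uses `r_c = r_u (1 + k r_u²)` on radii normalized
by the half-diagonal about the image centre; the inverse radius map is
solved by Newton iteration (the cubic is monotone for relevant k). The
factor k is chosen from a grid by undistorting, running a shallow
pyramid and scoring the residual of an affine fit to the point pairs —
residual distortion an affine map cannot absorb; on synthetic captures
with k* = 0.15 the search lands on the true grid point and the score
curve is unimodal.

The pyramid correlates the whole (Hamming-windowed, zero-padded)
projection against the reference, stores the part-centre/peak pair,
splits into 4 quadrants and recurses with a Gaussian search mask per
quadrant centred where the parent peak predicts it, sized half the
quadrant with SD one sixth of that extent (±3 SD spans the mask).
Levels n yield `Σᵢ₌₀..ₙ 4ⁱ` pairs. Parts smaller than
`registration.min_part_px` (default 64 px at instrument scale; 16 px in
desk-scale experiments, the same fraction of image width) stop their
branch: small parts carry too few vessels for a reliable peak.

Pruning keeps `ceil(0.7 N)` pairs (round up, never starving the fit),
then fits two quadratics by ordinary least squares. Degradation ladder:
fewer than 9 survivors → affine terms only; fewer than 3 → pure
translation (which is also what a "no pyramid" single global
registration produces). The inverse map is fitted on swapped pairs and
refined by Newton iteration on the forward polynomial at query time, so
forward∘inverse round-trips to well under 0.25 px over the projection
support.

## Stitching

Warping is inverse mapping with bilinear interpolation (forward mapping
would leave holes). Each projection is multiplied by a separable 2D
Hamming weight window before accumulation; a divisor canvas accumulates
the same warped weights, and the mosaic is accumulator/divisor where
the divisor is positive. Because Hamming never reaches zero
(corners 0.08²), the divisor is strictly positive inside every
footprint. Identical interpolation of `I·H` and `H` makes the all-ones
conservation property exact to machine precision. The unweighted
variant (binary divisor) is kept behind a flag; on brightness-
mismatched inputs its seam metric is strictly larger, which is the
point of the weighting.

## Evaluation

Residual-motion statistics report SD and range over all B-scans and
over the best-k (default 150 of 250) ranked by match quality. Match
quality is the normalized peak of a **linear** (non-circular)
cross-correlation of each repeated B-scan row against a reference row:
rows displaced by residual motion lose overlap and score lower, so
saccadic spikes fall out of the best subset. The graded point-pair
error is the mean over points and graders of the Euclidean distance
`(1/n)(1/G) Σᵢ Σ_g ‖p_ig‖₂` (the name notwithstanding, the defining
expression is a mean of distances; a root-mean-square mode is available
behind a flag). The seam metric is the ratio of the 99th-percentile
gradient magnitude in thin bands around footprint boundaries to that of
footprint interiors, excluding the mosaic's outer edge (the step to the
empty canvas is not a seam).

## What the synthetic scenes do and do not show

The generator provides what the algorithms consume: dark connected
vessel trees with bifurcations (registration features), smooth layer
surfaces with strictly ordered depths, sharp dark-to-bright layer
onsets with an exponential tail (so gradient and DOPU segmentation
localize the surface itself), a bright outer-retina complex between
IS/OS and RPE (making IS/OS the dominant gradient, as in real scans), a
graded DOPU dip centred on the RPE, vessel shadows attenuating the
outer bands, lens/corneal reflection artifacts, and blinks that darken
frames over a 2-frame lid ramp. Gaze is a drift random walk plus
Poisson saccades and blinks; drift and saccade amplitudes are free
parameters of the simulator (defaults: 20 μm/s drift, 100 μm saccades),
not measured values.

Not emulated: OCT speckle statistics and wave-optics effects, intra-
B-scan shear during fast motion, optic nerve head anatomy, pathology,
eye rotation (the tracker estimates translation only), and illumination
falloff beyond a smooth background field. Passing tests therefore
demonstrate algorithmic correctness — oracle equivalence, parameter
recovery, conservation and ordering properties — not clinical-grade
robustness on real scans.

## Known limitations

* Rotation is not tracked; a log-polar extension would fit between
  preprocessing and correlation but is out of scope.
* Per-B-scan segmentation has no smoothness coupling across B-scans.
* The pyramid inherits errors of its level-0 registration; the Gaussian
  region limitation bounds but does not eliminate this, and a
  prior-knowledge initial mask (Gaussian at the nominal region centre)
  is available when the region label is known.
* Registration of the 7 regions is independent per region; a joint
  optimization over all transforms would reduce doubled vessels in
  heavily overlapped areas.
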