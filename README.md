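# octmosaic

Motion-compensated OCT acquisition simulation and large field-of-view
en-face mosaicking.

Volumetric retinal OCT trades field of view against acquisition time and
resolution: a single raster scan covers perhaps 28° × 21° and takes a few
seconds, during which the eye drifts, makes microsaccades and blinks.
`octmosaic` implements the two-stage strategy that works around both
limits at once, for researchers building or evaluating retinal scanners
and registration pipelines:

1. **Acquisition stage** — a retinal tracker estimates per-frame eye
   motion from SLO camera images by 2D phase correlation and steers the
   OCT scanner in closed loop; blinks and large motions trigger a retake
   phase that rewinds the slow-scan axis and overwrites corrupted
   B-scans, so each volume comes out motion-free and complete.
2. **Stitching stage** — per-region volumes are reduced to high-contrast
   en-face projections (axial sum over a 30 μm band at the retinal
   pigment epithelium), registered against a wide-field fundus photograph
   through a recursive pyramid of masked phase correlations, corrected
   for pincushion distortion plus a second-order polynomial warp, and
   blended seam-free with border-decaying weights into one wide-field
   map. Stored transforms can be reused to stitch secondary channels
   (e.g. retardation maps from polarization-sensitive OCT).

A synthetic scene generator (vessel-tree retina phantom, layered A-scans
with vessel shadows and a depolarizing RPE band, gaze traces with drift,
saccades and blinks, SLO reflection artifacts, known optical
distortions) makes every stage verifiable against ground truth at desk
scale.

## The core algorithms

**Tracking.** An SLO frame `I(x,y)` is cleaned by thresholding the
saturated reflection artifacts, `M = [I ≥ t]`, morphological closing and
growth `CM = ((M ⊕ S) ⊖ S) ⊕ T`, and apodization
`F = I · min(1 − CM_smooth, H)` with a 2D Hamming window `H`. The offset
to a reference frame is the argmax of
`r = F⁻¹[ FF · G* / (|FF · G*| + ε) ]`, where `FF` is the reference
spectrum high-pass filtered twice (gain `1 − Gaussian(ω; s)`), with a
3×3-smoothed, centroid-refined subpixel peak. Estimates are gated by a
scanner step limit and a dynamic threshold at half the mean of the last
60 valid peak heights; the reference is the average of the 10 most
artifact-free of 20 training frames.

**Layer segmentation.** Per B-scan: an adaptive per-A-scan threshold
(mean of the top half of each column) plus topmost-pixel smoothing gives
the ILM; a large-kernel dark-to-bright axial gradient, masked below the
ILM, traced by a maximum-weight path with |Δz| ≤ 1 per column gives the
IS/OS; inverse DOPU (the RPE depolarizes) masked below the IS/OS and the
same path search gives the RPE. Volumes are flattened at the RPE before
band projection.

**Registration.** The fundus photo's green channel is rescaled to
8.2 μm/px and zero-padded. Projections are pre-corrected with the radial
model `r_c = r_u (1 + k r_u²)` (k chosen by grid search), then localized
by the pyramid: correlate the whole projection, split into 4 quadrants,
correlate each inside a Gaussian search mask centred where the parent
predicts, recurse — `Σᵢ 4ⁱ` point pairs. After dismissing the weakest
30% by peak height, two quadratics
`f(x,y) = ax² + by² + cxy + dx + ey + f` (one per output axis) are fit
by least squares.

**Stitching.** Each projection is weighted by a 2D Hamming window `H`
before warping; accumulator and divisor canvases sum `I·H` and `H`
respectively, and the mosaic is their ratio — a per-pixel weighted
average that is exactly 1 on all-ones input and suppresses seams where
regions meet.

## Worked example

```python
import numpy as np
import octmosaic as om
from octmosaic import registration as reg, stitch as st

# 1. scene: a retina phantom viewed through the tracking SLO
phantom = om.make_phantom(seed=1, extent_deg=10.0, vessel_density=0.10)
frames = [om.render_slo_frame(phantom, noise_sd=0.01, seed=k)
          for k in range(20)]
state = om.train_tracker(frames)

# 2. closed-loop acquisition under sinusoidal fixation drift + a blink
geometry = om.AcquisitionGeometry.desk(samples=(128, 128))
t = np.arange(400) / 60.0
drift = np.stack([50 * np.sin(2 * np.pi * 0.5 * t),
                  np.zeros_like(t)], axis=1)
gaze = om.GazeTrace(offsets_um=drift, frame_rate=60.0,
                    blink_intervals=[(90, 96)])
result = om.run_acquisition(phantom, geometry, gaze, state, seed=2)
sd_px = (result.residual_um / phantom.pitch_um).std(axis=0)
print(f"residual motion SD: x = {sd_px[0]:.2f} px, y = {sd_px[1]:.2f} px; "
      f"retakes = {result.n_retakes}")

# 3. layers, flattening and the RPE-band en-face projection
surfaces = om.segment_volume(result.volume, smooth_window=13)
flat, _ = om.flatten_volume(result.volume, surfaces)
projection = om.project_band(flat, band_um=30.0)
print(f"surfaces ordered (ILM < IS/OS < RPE): {surfaces.ordered()}; "
      f"projection {projection.pixels.shape}")

# 4. register a projection against a wide-field reference
fundus = om.make_phantom(seed=11, extent_deg=14.0, vessel_density=0.10,
                         pitch_um=8.2)
reference = reg.prepare_fundus_reference(fundus.fundus_map, 8.2, pad_px=32)
part = fundus.fundus_map[150:406, 200:456]          # known placement
pairs = reg.pyramid_pointset(reference, part, levels_n=2, min_part_px=16)
transform = reg.prune_and_fit(pairs)
print(f"pyramid pairs: {len(pairs)}, fit residual "
      f"{transform.residual_px:.3f} px")

# 5. stitch two overlapping projections
part2 = fundus.fundus_map[100:356, 120:376]
tf2 = reg.prune_and_fit(reg.pyramid_pointset(reference, part2, levels_n=2,
                                             min_part_px=16))
mosaic, valid, canvas = st.stitch_projections([part, part2],
                                              [transform, tf2],
                                              reference.shape)
ratio = om.seam_metric(mosaic, canvas.footprints, valid=valid)
print(f"mosaic covers {valid.mean():.0%} of the canvas; "
      f"seam/interior gradient ratio {ratio:.2f}")
```

Output:

```
residual motion SD: x = 0.21 px, y = 0.05 px; retakes = 1
surfaces ordered (ILM < IS/OS < RPE): True; projection (128, 128)
pyramid pairs: 21, fit residual 0.160 px
mosaic covers 28% of the canvas; seam/interior gradient ratio 0.96
```

The tracker holds the residual motion of a ±50 μm, 0.5 Hz drifting
fixation to ~0.2 px SD despite a blink mid-scan (re-scanned
automatically); the 21 pyramid point pairs locate the projection to
sub-pixel residual; the blended two-region mosaic shows boundary
gradients no larger than its interior's (ratio ≈ 1, i.e. no seams).

A `octmosaic` console script exposes the stages as subcommands
(`phantom`, `track`, `segment`, `project`, `register`, `stitch`,
`evaluate`) operating on TIFF/CSV/JSON files; see `octmosaic --help`.

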