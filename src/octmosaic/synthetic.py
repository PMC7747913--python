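"""Synthetic retina, SLO and OCT scene generation with known ground truth.

Every downstream stage of the pipeline (tracking, segmentation, projection,
registration, stitching) is validated against scenes produced here: a
vessel-tree fundus phantom with smooth layer depth fields, gaze traces with
drift/saccades/blinks, SLO frames with reflection artifacts, and OCT
volumes with layered A-scans, vessel shadows and a depolarizing RPE band.

Conventions: 2D images are indexed ``(y, x)``; B-scans ``(z, x)``; volumes
``(b_scan, z, x)``.  Depth ``z`` increases away from the vitreous.  Angular
extent converts to retinal distance at 300 um per degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

UM_PER_DEGREE = 300.0

REGION_NAMES = (
    "central",
    "central_superior",
    "central_inferior",
    "temporal_superior",
    "temporal_inferior",
    "nasal_superior",
    "nasal_inferior",
)


@dataclass
class RetinaPhantom:
    """Ground-truth retina: fundus reflectance plus layer depth fields.

    ``fundus_map`` holds reflectance in arbitrary units on a square grid of
    ``pitch_um`` micron pixels; vessels are dark connected curves recorded
    in ``vessel_mask``.  The three depth fields (microns from an arbitrary
    reference plane) satisfy ``ilm < isos < rpe`` everywhere.
    """

    fundus_map: np.ndarray
    vessel_mask: np.ndarray
    ilm_depth: np.ndarray
    isos_depth: np.ndarray
    rpe_depth: np.ndarray
    pitch_um: float
    extent_deg: float
    seed: int
    dopu_low: float = 0.2
    dopu_high: float = 0.95
    rpe_band_halfwidth_um: float = 15.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.fundus_map.shape

    def dopu_profile(self, z_um: np.ndarray, rpe_um: np.ndarray) -> np.ndarray:
        """DOPU as a function of depth: a graded dip centred on the RPE
        (minimum ``dopu_low`` at the layer, ``dopu_high`` elsewhere)."""
        sigma = self.rpe_band_halfwidth_um / 2.0
        dip = np.exp(-0.5 * ((z_um - rpe_um) / sigma) ** 2)
        return self.dopu_high - (self.dopu_high - self.dopu_low) * dip


@dataclass
class GazeTrace:
    """Per-frame lateral eye position (dx, dy) in microns at ``frame_rate``."""

    offsets_um: np.ndarray  # (n_frames, 2) columns (dx, dy)
    frame_rate: float
    blink_intervals: list[tuple[int, int]] = field(default_factory=list)
    saccade_frames: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.offsets_um)

    def is_blink(self, frame: int) -> bool:
        return any(a <= frame < b for a, b in self.blink_intervals)

    def lid_factor(self, frame: int) -> float:
        """Light throughput of the eyelid: 0 inside a blink, ramping over
        2 frames on either side to emulate lid closure."""
        if self.is_blink(frame):
            return 0.0
        for a, b in self.blink_intervals:
            if frame == a - 1 or frame == b:
                return 0.5
        return 1.0


@dataclass
class AcquisitionGeometry:
    """Scan-pattern geometry for the 7-region wide-field protocol.

    Defaults follow the instrument protocol: 28 x 21 degree volumes of
    1024 A-scans x 250 B-scans at (8.2, 25.2) um lateral pitch, seven
    fixation regions whose neighbours overlap by roughly one third of a
    volume, three repeats per region.
    """

    oct_fov_deg: tuple[float, float] = (28.0, 21.0)
    samples: tuple[int, int] = (1024, 250)  # (a_scans, b_scans)
    pixel_pitch_um: tuple[float, float] = (8.2, 25.2)
    repeats_per_region: int = 3
    depth_samples: int = 128
    z_pitch_um: float = 3.0

    @classmethod
    def desk(cls, samples: tuple[int, int] = (256, 128),
             depth_samples: int = 128) -> "AcquisitionGeometry":
        """Proportionally scaled-down geometry for fast experiments."""
        pitch = (8.2, 25.2)
        fov = (samples[0] * pitch[0] / UM_PER_DEGREE,
               samples[1] * pitch[1] / UM_PER_DEGREE)
        return cls(oct_fov_deg=fov, samples=samples, pixel_pitch_um=pitch,
                   depth_samples=depth_samples)

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.samples[0] * self.pixel_pitch_um[0],
                self.samples[1] * self.pixel_pitch_um[1])

    @property
    def region_centers(self) -> dict[str, tuple[float, float]]:
        """Region centre (x_um, y_um) relative to the fovea.

        Spacing of two thirds of the volume extent leaves one third
        overlap between neighbours.  Superior is negative y (image-up).
        """
        wx, wy = self.fov_um
        dx, dy = 2.0 * wx / 3.0, 2.0 * wy / 3.0
        return {
            "central": (0.0, 0.0),
            "central_superior": (0.0, -dy),
            "central_inferior": (0.0, +dy),
            "temporal_superior": (-dx, -dy),
            "temporal_inferior": (-dx, +dy),
            "nasal_superior": (+dx, -dy),
            "nasal_inferior": (+dx, +dy),
        }


@dataclass
class ArtifactSpec:
    """Reflection artifacts added to SLO frames.

    Two fixed bright stripes emulate reflections inside the instrument
    optics; a saturated disk of ``patch_area_frac`` of the frame emulates
    the corneal reflection, whose position varies with the entry angle.
    """

    stripes: bool = True
    stripe_cols_frac: tuple[float, ...] = (0.18, 0.5)
    stripe_halfwidth_frac: float = 0.02
    corneal_patch: bool = True
    patch_center_frac: tuple[float, float] = (0.45, 0.75)
    patch_area_frac: float = 0.25
    level: float = 4.0


@dataclass
class OCTVolume:
    """B-scan stack: ``intensity[b, z, x]`` with optional DOPU channel."""

    intensity: np.ndarray
    dopu: np.ndarray | None
    pitch_um: tuple[float, float, float]  # (x, y, z)
    region: str
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.intensity.shape[2]


def _edge_band(z_um: np.ndarray, depth_um: np.ndarray, amplitude: float,
               decay_um: float, rise_um: float = 1.5) -> np.ndarray:
    """Layer reflectance profile: logistic rise at ``depth_um`` followed
    by an exponential decay of scale ``decay_um``."""
    d = z_um - depth_um
    return (amplitude / (1.0 + np.exp(-d / rise_um))
            * np.exp(-np.clip(d, 0.0, None) / decay_um))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Zero-mean unit-SD smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _draw_vessel_tree(mask: np.ndarray, rng: np.random.Generator,
                      width_scale: float) -> None:
    """Draw one branching vessel into ``mask`` (in place).

    A random smoothed polyline walks across the field, thinning and
    bifurcating with small probability — enough structure to provide the
    crossings and bifurcations that registration relies on.
    """
    n = mask.shape[0]
    stack = [(rng.uniform(0.2 * n, 0.8 * n), rng.uniform(0.2 * n, 0.8 * n),
              rng.uniform(0, 2 * math.pi), rng.uniform(1.5, 3.5) * width_scale)]
    yy, xx = np.mgrid[0:n, 0:n]
    while stack:
        y, x, ang, w = stack.pop()
        steps = int(rng.integers(n // 4, n))
        for _ in range(steps):
            ang += rng.normal(0.0, 0.15)
            y += math.sin(ang) * 2.0
            x += math.cos(ang) * 2.0
            if not (0 <= y < n and 0 <= x < n):
                break
            r = max(1.0, w)
            y0, y1 = int(max(0, y - r - 1)), int(min(n, y + r + 2))
            x0, x1 = int(max(0, x - r - 1)), int(min(n, x + r + 2))
            d2 = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2
            mask[y0:y1, x0:x1] |= d2 <= r * r
            w *= 0.999
            if rng.random() < 0.01 and w > 1.2:
                stack.append((y, x, ang + rng.choice([-1, 1])
                              * rng.uniform(0.4, 0.9), w * 0.7))


def make_phantom(seed: int, extent_deg: float = 45.0,
                 vessel_density: float = 0.08,
                 pitch_um: float = 10.0) -> RetinaPhantom:
    """Generate a deterministic retina phantom.

    ``vessel_density`` is the target fraction of vessel pixels; trees are
    added until the mask reaches it (so the realised fraction lands
    slightly above, never below).  Layer depth fields are smooth with
    strictly positive gaps, guaranteeing ILM < IS/OS < RPE.
    """
    if extent_deg <= 0:
        raise ValueError("extent_deg must be positive")
    if not 0 <= vessel_density < 1:
        raise ValueError("vessel_density must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(extent_deg * UM_PER_DEGREE / pitch_um))
    shape = (n, n)

    background = 0.5 + 0.1 * _smooth_field(rng, shape, sigma=n / 12)
    vessel_mask = np.zeros(shape, dtype=bool)
    width_scale = max(0.6, n / 512)
    guard = 0
    while vessel_density > 0 and vessel_mask.mean() < vessel_density:
        _draw_vessel_tree(vessel_mask, rng, width_scale)
        guard += 1
        if guard > 500:
            break
    vessel_soft = ndimage.gaussian_filter(vessel_mask.astype(float), 1.0)
    fundus = background * (1.0 - 0.55 * vessel_soft)

    ilm = 80.0 + 20.0 * _smooth_field(rng, shape, sigma=n / 8)
    isos = ilm + 120.0 + 10.0 * np.abs(_smooth_field(rng, shape, sigma=n / 8))
    rpe = isos + 25.0 + 5.0 * np.abs(_smooth_field(rng, shape, sigma=n / 8))
    return RetinaPhantom(fundus_map=fundus, vessel_mask=vessel_mask,
                         ilm_depth=ilm, isos_depth=isos, rpe_depth=rpe,
                         pitch_um=pitch_um, extent_deg=extent_deg, seed=seed)


def simulate_gaze(n_frames: int, drift_rate: float = 20.0,
                  saccade_rate: float = 0.5, blink_rate: float = 0.1,
                  frame_rate: float = 60.0, seed: int = 0,
                  saccade_amplitude_um: float = 100.0,
                  blink_duration_s: float = 0.110) -> GazeTrace:
    """Simulate fixational eye movement.

    Drift is a 2D random walk whose per-second step SD is ``drift_rate``
    um/s.  Saccades arrive as a Bernoulli process of ``saccade_rate`` per
    second and add an instantaneous jump.  Blinks arrive at ``blink_rate``
    per second and last ~110 ms — about 6 frames at 60 Hz.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    for name, v in (("drift_rate", drift_rate), ("saccade_rate", saccade_rate),
                    ("blink_rate", blink_rate)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    step_sd = drift_rate / frame_rate
    steps = rng.normal(0.0, step_sd, size=(n_frames, 2))
    steps[0] = 0.0

    saccade_frames: list[int] = []
    p_sac = saccade_rate / frame_rate
    if p_sac > 0:
        hits = rng.random(n_frames) < p_sac
        for k in np.nonzero(hits)[0]:
            jump = rng.normal(0.0, saccade_amplitude_um, size=2)
            steps[k] += jump
            saccade_frames.append(int(k))

    offsets = np.cumsum(steps, axis=0)

    blink_intervals: list[tuple[int, int]] = []
    p_blink = blink_rate / frame_rate
    if p_blink > 0:
        dur = max(1, int(blink_duration_s * frame_rate))
        starts = np.nonzero(rng.random(n_frames) < p_blink)[0]
        for s in starts:
            e = min(int(s) + dur, n_frames)
            if blink_intervals and s < blink_intervals[-1][1]:
                continue
            blink_intervals.append((int(s), e))

    return GazeTrace(offsets_um=offsets, frame_rate=frame_rate,
                     blink_intervals=blink_intervals,
                     saccade_frames=saccade_frames)


def render_slo_frame(phantom: RetinaPhantom,
                     gaze_um: tuple[float, float] = (0.0, 0.0),
                     frame_shape: tuple[int, int] = (128, 128),
                     artifact: ArtifactSpec | None = None,
                     noise_sd: float = 0.0, seed: int = 0,
                     lid_factor: float = 1.0) -> np.ndarray:
    """Render one SLO camera frame at a lateral gaze offset.

    The frame samples the central ``frame_shape`` window of the phantom
    displaced by ``gaze_um = (dx, dy)``; reflections and additive noise
    are layered on top.  ``lid_factor`` scales retinal signal during
    blinks (0 = lid closed); artifacts originate in the optics and remain.
    """
    h, w = frame_shape
    ph, pw = phantom.shape
    dy = gaze_um[1] / phantom.pitch_um
    dx = gaze_um[0] / phantom.pitch_um
    top = (ph - h) / 2.0 + dy
    left = (pw - w) / 2.0 + dx
    if top < 0 or left < 0 or top + h > ph or left + w > pw:
        raise ValueError("gaze offset places the frame outside the phantom")
    if abs(top - round(top)) < 1e-9 and abs(left - round(left)) < 1e-9:
        ti, li = int(round(top)), int(round(left))
        frame = phantom.fundus_map[ti:ti + h, li:li + w].copy()
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        frame = ndimage.map_coordinates(phantom.fundus_map,
                                        [yy + top, xx + left], order=1)
    frame *= lid_factor

    if artifact is not None:
        if artifact.stripes:
            hw = max(1, int(artifact.stripe_halfwidth_frac * w))
            for cf in artifact.stripe_cols_frac:
                c = int(cf * w)
                frame[:, max(0, c - hw):c + hw] = artifact.level
        if artifact.corneal_patch and artifact.patch_area_frac > 0:
            radius = math.sqrt(artifact.patch_area_frac * h * w / math.pi)
            cy = artifact.patch_center_frac[0] * h
            cx = artifact.patch_center_frac[1] * w
            yy, xx = np.mgrid[0:h, 0:w]
            frame[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = \
                artifact.level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
    return frame


def render_oct_volume(phantom: RetinaPhantom, geometry: AcquisitionGeometry,
                      region: str, residual_motion: np.ndarray | None = None,
                      distortion=None, seed: int = 0, noise_sd: float = 0.02,
                      shadow_factor: float = 0.4,
                      with_dopu: bool = True) -> OCTVolume:
    """Render an OCT volume of one fixation region.

    Each A-scan carries Gaussian bright bands at the phantom's ILM, IS/OS
    and RPE depths; vessel shadows attenuate the outer-retina bands by
    ``shadow_factor``; the DOPU channel is low inside the RPE band and
    high elsewhere.  ``residual_motion`` adds per-B-scan lateral offsets
    (um, shape ``(n_bscans, 2)``); ``distortion`` is an optional callable
    warping lateral sample positions ``(N, 2)`` (x_um, y_um, relative to
    the region centre) before phantom lookup.
    """
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region {region!r}; expected one of "
                         f"{REGION_NAMES}")
    nx, nb = geometry.samples
    nz = geometry.depth_samples
    px, py = geometry.pixel_pitch_um
    cx_um, cy_um = geometry.region_centers[region]
    rng = np.random.default_rng(seed)

    x_um = (np.arange(nx) - (nx - 1) / 2.0) * px
    z_um = np.arange(nz) * geometry.z_pitch_um
    ph_n = phantom.shape[0]
    center_px = (ph_n - 1) / 2.0

    intensity = np.empty((nb, nz, nx), dtype=np.float32)
    dopu = np.empty((nb, nz, nx), dtype=np.float32) if with_dopu else None

    for b in range(nb):
        y_um = (b - (nb - 1) / 2.0) * py
        lat = np.column_stack([x_um, np.full(nx, y_um)])
        if distortion is not None:
            lat = np.asarray(distortion(lat), dtype=float)
        if residual_motion is not None:
            lat = lat + residual_motion[b]
        sx = center_px + (lat[:, 0] + cx_um) / phantom.pitch_um
        sy = center_px + (lat[:, 1] + cy_um) / phantom.pitch_um
        coords = [np.clip(sy, 0, ph_n - 1), np.clip(sx, 0, ph_n - 1)]
        ilm = ndimage.map_coordinates(phantom.ilm_depth, coords, order=1)
        isos = ndimage.map_coordinates(phantom.isos_depth, coords, order=1)
        rpe = ndimage.map_coordinates(phantom.rpe_depth, coords, order=1)
        vessel = ndimage.map_coordinates(
            ndimage.gaussian_filter(phantom.vessel_mask.astype(float), 1.0),
            coords, order=1)
        # soft edges for anti-aliasing, full shadow depth at vessel cores
        atten = 1.0 - (1.0 - shadow_factor) * np.clip(1.6 * vessel, 0.0, 1.0)

        z = z_um[:, None]
        # each layer is a sharp dark-to-bright edge at the stated depth
        # with an exponential tail below, so gradient- and DOPU-based
        # segmentation both localize the surface itself.  The long IS/OS
        # tail keeps the outer retina bright down to the RPE, as in real
        # scans, making IS/OS the dominant dark-to-bright transition.
        band = (_edge_band(z, ilm[None, :], 0.75, 15.0)
                + atten[None, :] * _edge_band(z, isos[None, :], 0.85, 45.0)
                + atten[None, :] * _edge_band(z, rpe[None, :], 0.50, 18.0))
        bscan = 0.05 + band
        if noise_sd > 0:
            bscan = bscan + rng.normal(0.0, noise_sd, size=bscan.shape)
        intensity[b] = np.clip(bscan, 0.0, None)
        if with_dopu:
            dopu[b] = phantom.dopu_profile(np.broadcast_to(z, (nz, nx)),
                                           rpe[None, :])

    return OCTVolume(intensity=intensity, dopu=dopu,
                     pitch_um=(px, py, geometry.z_pitch_um), region=region,
                     seed=seed,
                     meta={"center_um": (cx_um, cy_um),
                           "phantom_seed": phantom.seed,
                           "shadow_factor": shadow_factor})
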