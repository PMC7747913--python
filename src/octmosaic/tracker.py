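"""Closed-loop retinal tracking and blink/retake acquisition simulation.

The tracker estimates per-frame retinal motion by phase-correlating each
preprocessed SLO frame against a doubly high-pass-filtered reference
spectrum.  Estimates are gated twice: a fixed cap on the step between
consecutive valid offsets (scanner safety), and a dynamic peak-height
threshold derived from the rolling mean of the last 60 valid peaks.  An
invalid frame (blink, large motion) triggers a retake phase: the slow-scan
index rewinds by a few B-scan positions, the system waits for valid
tracking, then resumes and overwrites the potentially corrupted B-scans.

``run_acquisition`` closes the loop on synthetic scenes: SLO frames are
rendered from a phantom at the simulated gaze, offsets are applied to the
virtual scanner with one-frame latency, and the final volume is rendered
with the residual (uncorrected) per-B-scan motion.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import phasecorr, slo
from .phasecorr import OffsetEstimate
from .synthetic import (AcquisitionGeometry, ArtifactSpec, GazeTrace,
                        OCTVolume, RetinaPhantom, render_oct_volume,
                        render_slo_frame)


class AcquisitionError(RuntimeError):
    """Raised when the closed-loop acquisition cannot complete."""


@dataclass
class TrackerState:
    reference_spectrum: np.ndarray
    peak_history: deque = field(default_factory=lambda: deque(maxlen=60))
    threshold_factor: float = 0.5
    max_step: float = 50.0
    rollback_bscans: int = 4
    absolute_floor: float = 0.02
    epsilon: float = 1e-9
    last_valid: OffsetEstimate | None = None

    def dynamic_threshold(self) -> float:
        if not self.peak_history:
            return self.absolute_floor
        return self.threshold_factor * float(np.mean(self.peak_history))


def train_tracker(frames: list[np.ndarray],
                  params: slo.SLOParams | None = None,
                  kernel_size_s: float | None = None,
                  **state_kwargs) -> TrackerState:
    """Training phase: build the averaged reference and pre-filter its
    spectrum twice so the per-frame loop needs no filtering."""
    ref = slo.build_reference_frame(frames, params)
    spec = np.fft.fft2(ref.filtered.pixels)
    hp = phasecorr.make_highpass(spec.shape, kernel_size_s, applications=2)
    return TrackerState(reference_spectrum=hp.apply(spec), **state_kwargs)


def track_frame(state: TrackerState, filtered_frame: np.ndarray,
                ) -> OffsetEstimate:
    """Raw (ungated) offset estimate for one preprocessed frame."""
    return phasecorr.estimate_offset(state.reference_spectrum,
                                     filtered_frame, state.epsilon)


def validate_offset(estimate: OffsetEstimate,
                    state: TrackerState) -> OffsetEstimate:
    """Gate an estimate and update the tracker's history on success.

    Rejection reasons: ``step_too_large`` when the change relative to the
    last valid offset exceeds ``max_step`` px; ``peak_too_low`` when the
    peak falls under ``threshold_factor`` times the rolling mean of the
    last 60 valid peaks (or an absolute floor while the history is empty).
    Invalid frames leave the history untouched.
    """
    if not estimate.valid:
        return estimate
    if state.last_valid is not None:
        step = np.hypot(estimate.dy - state.last_valid.dy,
                        estimate.dx - state.last_valid.dx)
        if step > state.max_step:
            return OffsetEstimate(estimate.dy, estimate.dx,
                                  estimate.peak_height, valid=False,
                                  reason="step_too_large")
    if estimate.peak_height < state.dynamic_threshold():
        return OffsetEstimate(estimate.dy, estimate.dx,
                              estimate.peak_height, valid=False,
                              reason="peak_too_low")
    state.peak_history.append(estimate.peak_height)
    state.last_valid = estimate
    return estimate


@dataclass
class AcquisitionResult:
    volume: OCTVolume
    residual_um: np.ndarray          # (n_bscans, 2) applied minus true gaze
    log: list[dict]
    n_retakes: int
    bscan_frame: np.ndarray          # frame index that acquired each B-scan
    estimated_gaze_um: np.ndarray    # (n_frames, 2) tracker output (nan invalid)


def run_acquisition(phantom: RetinaPhantom, geometry: AcquisitionGeometry,
                    gaze: GazeTrace, state: TrackerState,
                    params: slo.SLOParams | None = None,
                    region: str = "central",
                    frame_shape: tuple[int, int] = (128, 128),
                    bscans_per_frame: float = 1.14,
                    artifact: ArtifactSpec | None = None,
                    noise_sd: float = 0.01, seed: int = 0,
                    max_retakes: int = 100,
                    render_volume: bool = True) -> AcquisitionResult:
    """Simulate a tracked OCT volume acquisition with blink re-scanning.

    One SLO frame arrives per ~1.14 B-scans; valid offsets steer the
    virtual scanner starting with the next frame (one-frame latency).  An
    invalid frame rewinds the B-scan index by ``state.rollback_bscans``
    and pauses scanning until tracking recovers; re-scanned positions
    overwrite earlier data, so the final volume holds only B-scans taken
    during valid tracking.  The trajectory log records every scan event,
    including the overwritten ones (the raw-acquisition view).
    """
    params = params or slo.SLOParams()
    n_bscans = geometry.samples[1]
    pitch = phantom.pitch_um

    residual = np.zeros((n_bscans, 2))
    bscan_frame = np.full(n_bscans, -1, dtype=int)
    acquired_once = np.zeros(n_bscans, dtype=bool)
    est_gaze = np.full((len(gaze), 2), np.nan)
    log: list[dict] = []

    correction = np.zeros(2)          # um, applied to the scanner
    pending: np.ndarray | None = None  # estimate awaiting latency
    b_idx = 0
    b_budget = 0.0
    mode = "track"
    n_retakes = 0
    done = False

    for k in range(len(gaze)):
        if pending is not None:
            correction = pending
            pending = None
        g = gaze.offsets_um[k]
        frame = render_slo_frame(phantom, (g[0], g[1]),
                                 frame_shape=frame_shape, artifact=artifact,
                                 noise_sd=noise_sd, seed=seed + k,
                                 lid_factor=gaze.lid_factor(k))
        ff, _ = slo.preprocess_frame(frame, params)
        est = validate_offset(track_frame(state, ff.pixels), state)
        row = {"frame": k, "bscan_index": b_idx, "dx": est.dx, "dy": est.dy,
               "peak": est.peak_height, "valid": est.valid, "event": "track"}
        if est.valid:
            # frame content shifted by -gaze relative to the reference
            gaze_est = np.array([-est.dx, -est.dy]) * pitch
            est_gaze[k] = gaze_est
            pending = gaze_est
            if mode == "retake":
                mode = "track"
                row["event"] = "resume"
            b_budget += bscans_per_frame
            while b_budget >= 1.0 and not done:
                residual[b_idx] = g - correction
                bscan_frame[b_idx] = k
                log.append({**row, "bscan_index": b_idx,
                            "event": ("rescan" if acquired_once[b_idx]
                                      else row["event"])})
                row["event"] = "track"
                acquired_once[b_idx] = True
                b_idx += 1
                b_budget -= 1.0
                if b_idx >= n_bscans:
                    done = True
            if done:
                break
        else:
            if mode == "track":
                mode = "retake"
                n_retakes += 1
                if n_retakes > max_retakes:
                    raise AcquisitionError("retake budget exceeded")
                b_idx = max(0, b_idx - state.rollback_bscans)
                b_budget = 0.0
                row["event"] = "retake_start"
                row["bscan_index"] = b_idx
            log.append(row)

    if not done:
        raise AcquisitionError("gaze trace ended before the volume "
                               f"completed ({b_idx}/{n_bscans} B-scans)")

    volume = None
    if render_volume:
        volume = render_oct_volume(phantom, geometry, region,
                                   residual_motion=residual, seed=seed)
    return AcquisitionResult(volume=volume, residual_um=residual, log=log,
                             n_retakes=n_retakes, bscan_frame=bscan_frame,
                             estimated_gaze_um=est_gaze)
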