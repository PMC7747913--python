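"""SLO frame preprocessing for phase-correlation tracking.

Bright reflection artifacts (lens reflexes, the corneal reflex that can
cover up to a third of the frame) would otherwise dominate the edge content
the tracker correlates on.  They are removed by thresholding, morphological
cleanup and soft masking, and the frame is apodized with a Hamming window
so the FFT sees no artificial border edges:

    M  = I >= t
    CM = ((M (+) S) (-) S) (+) T        (closing with S, grow by T)
    F  = I * min(1 - smooth(CM), H)

The tracking reference is the average of the 10 most artifact-free of 20
training frames, mutually registered by phase correlation first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, dilation, disk

from . import phasecorr


@dataclass
class ArtifactMask:
    raw_mask: np.ndarray
    closed_mask: np.ndarray
    smoothed_mask: np.ndarray
    threshold_t: float
    disk_S_radius: int
    disk_T_radius: int


@dataclass
class FilteredFrame:
    pixels: np.ndarray
    window: np.ndarray


@dataclass
class ReferenceFrame:
    pixels: np.ndarray
    usable_pixel_counts: list[int]
    member_indices: list[int]
    filtered: FilteredFrame | None = None


@dataclass
class SLOParams:
    """Preprocessing defaults; the instrument values are not published, so
    these are declared package defaults exposed in the ``slo`` config
    section."""

    threshold_t: float | None = None      # None -> percentile rule
    threshold_percentile: float = 98.0
    disk_S_radius: int = 15
    disk_T_radius: int = 5
    smooth_window: int = 11


def hamming2d(shape: tuple[int, int]) -> np.ndarray:
    """Separable 2D Hamming window (outer product of 1D windows)."""
    return np.outer(np.hamming(shape[0]), np.hamming(shape[1]))


def detect_artifact_mask(frame: np.ndarray, threshold_t: float,
                         disk_S_radius: int = 15, disk_T_radius: int = 5,
                         smooth_window: int = 11) -> ArtifactMask:
    """Threshold saturated artifacts and clean the mask morphologically.

    ``raw_mask`` flags pixels at or above ``threshold_t``; closing with
    the larger disk S removes noise patches, dilation by the smaller disk
    T grows the mask so the subsequent soft transition stays clear of the
    artifact; a sliding-window box average produces the continuous mask.
    """
    if disk_S_radius < 1 or disk_T_radius < 1:
        raise ValueError("disk radii must be >= 1")
    if disk_S_radius < disk_T_radius:
        raise ValueError("disk S must not be smaller than disk T")
    raw = (frame >= threshold_t)
    closed = dilation(closing(raw, disk(disk_S_radius)),
                      disk(disk_T_radius))
    smoothed = ndimage.uniform_filter(closed.astype(float),
                                      size=smooth_window, mode="constant")
    smoothed = np.clip(smoothed, 0.0, 1.0)
    return ArtifactMask(raw_mask=raw.astype(np.uint8),
                        closed_mask=closed.astype(np.uint8),
                        smoothed_mask=smoothed,
                        threshold_t=float(threshold_t),
                        disk_S_radius=disk_S_radius,
                        disk_T_radius=disk_T_radius)


def default_threshold(frame: np.ndarray, percentile: float = 98.0) -> float:
    """Histogram-based artifact threshold: saturated reflections live in
    the extreme intensity tail."""
    return float(np.percentile(frame, percentile))


def preprocess_frame(frame: np.ndarray,
                     params: SLOParams | None = None) -> tuple[FilteredFrame,
                                                               ArtifactMask]:
    params = params or SLOParams()
    t = params.threshold_t
    if t is None:
        t = default_threshold(frame, params.threshold_percentile)
    mask = detect_artifact_mask(frame, t, params.disk_S_radius,
                                params.disk_T_radius, params.smooth_window)
    return apply_window_and_mask(frame, mask), mask


def apply_window_and_mask(frame: np.ndarray,
                          mask: ArtifactMask) -> FilteredFrame:
    """``F = I * min(1 - CM_smooth, H)`` — masked regions and borders go
    smoothly to zero before the FFT."""
    if mask.smoothed_mask.shape != frame.shape:
        raise ValueError("mask and frame dimensions differ")
    window = hamming2d(frame.shape)
    filtered = frame * np.minimum(1.0 - mask.smoothed_mask, window)
    return FilteredFrame(pixels=filtered, window=window)


def count_usable_pixels(mask: ArtifactMask) -> int:
    """PC = number of pixels not covered by the closed artifact mask."""
    return int(np.sum(1 - mask.closed_mask))


def build_reference_frame(frames: list[np.ndarray],
                          params: SLOParams | None = None,
                          n_train: int = 20,
                          n_members: int = 10) -> ReferenceFrame:
    """Average the 10 best of 20 training frames into a tracking reference.

    Frames are ranked by usable-pixel count PC; the best becomes the base,
    the next 9 are registered to it by phase correlation (integer offsets,
    circular), offset-corrected, and all 10 are averaged.  The average is
    re-preprocessed before use so its own borders are windowed.
    """
    params = params or SLOParams()
    if len(frames) != n_train:
        raise ValueError(f"expected exactly {n_train} training frames, "
                         f"got {len(frames)}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("training frames must share dimensions")

    pcs: list[int] = []
    filtered: list[FilteredFrame] = []
    for f in frames:
        ff, m = preprocess_frame(f, params)
        filtered.append(ff)
        pcs.append(count_usable_pixels(m))
    order = sorted(range(len(frames)), key=lambda i: pcs[i], reverse=True)
    members = order[:n_members]
    if sum(1 for i in members if pcs[i] > 0) < n_members:
        raise RuntimeError("training failed: fewer than "
                           f"{n_members} frames with usable pixels")

    base = members[0]
    ref_spec = np.fft.fft2(filtered[base].pixels)
    stack = [frames[base].astype(float)]
    for i in members[1:]:
        est = phasecorr.estimate_offset(ref_spec, filtered[i].pixels)
        dy, dx = int(round(est.dy)), int(round(est.dx))
        stack.append(np.roll(frames[i].astype(float), (-dy, -dx),
                             axis=(0, 1)))
    rf = np.mean(stack, axis=0)
    ff, _ = preprocess_frame(rf, params)
    return ReferenceFrame(pixels=rf, usable_pixel_counts=pcs,
                          member_indices=members, filtered=ff)
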