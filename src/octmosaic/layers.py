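"""Retinal layer segmentation on OCT B-scans.

Three surfaces are extracted per B-scan, each as a single-valued depth
profile over A-scan position x:

* ILM — per-A-scan adaptive thresholding, topmost foreground pixel,
  101-px moving-average smoothing;
* IS/OS — dark-to-bright axial gradient (large kernel), masked to below
  the ILM, traced by a shortest-path search;
* RPE — inverse DOPU as path weight (the RPE depolarizes, so DOPU is low
  there), masked to below the IS/OS, traced by the same search.

The path model is dynamic programming over columns with a |dz| <= 1 step
between neighbouring A-scans, maximizing accumulated weight — the usual
graph formulation for layer boundaries.  The volume is then flattened so
the RPE sits at a constant depth, which makes a fixed axial band
projection meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, remove_small_objects

from .synthetic import OCTVolume


class SegmentationError(RuntimeError):
    pass


@dataclass
class LayerSurfaces:
    """Per-(B-scan, A-scan) depth indices of the three surfaces (pixels,
    fractional values allowed)."""

    ilm: np.ndarray
    isos: np.ndarray
    rpe: np.ndarray

    def ordered(self) -> bool:
        return bool(np.all((self.ilm < self.isos) & (self.isos < self.rpe)))


def threshold_bscan(bscan: np.ndarray, top_fraction: float = 0.5,
                    close_radius: int = 1, min_area: int = 50) -> np.ndarray:
    """Adaptive per-A-scan threshold: t(x) is the mean of the top
    ``ceil(top_fraction * depth)`` values of column x; pixels >= t(x) are
    foreground.  Closing with a small disk and removal of small patches
    suppress noise blobs above the ILM.  Pass ``close_radius=0``/
    ``min_area=0`` to disable the cleanup.
    """
    nz = bscan.shape[0]
    if nz < 2:
        raise ValueError("need at least 2 depth samples")
    k = max(1, int(np.ceil(top_fraction * nz)))
    part = np.partition(bscan, nz - k, axis=0)[nz - k:, :]
    t = part.mean(axis=0)
    binary = bscan >= t[None, :]
    if close_radius > 0:
        binary = closing(binary, disk(close_radius))
    if min_area > 0:
        binary = remove_small_objects(binary, max_size=min_area - 1)
    return binary.astype(np.uint8)


def estimate_ilm(binary: np.ndarray, smooth_window: int = 101) -> np.ndarray:
    """Topmost foreground pixel per A-scan, gap-interpolated, then
    moving-average smoothed (window shrinks at the borders)."""
    nz, nx = binary.shape
    if not binary.any():
        raise SegmentationError("empty thresholded B-scan")
    has = binary.any(axis=0)
    top = np.where(has, binary.argmax(axis=0), np.nan).astype(float)
    if not has.all():
        idx = np.nonzero(has)[0]
        top = np.interp(np.arange(nx), idx, top[idx])
    kernel = np.ones(smooth_window)
    num = np.convolve(top, kernel, mode="same")
    den = np.convolve(np.ones(nx), kernel, mode="same")
    return num / den


def isos_weights(bscan: np.ndarray, ilm: np.ndarray,
                 gradient_kernel: int = 15) -> np.ndarray:
    """Dark-to-bright axial gradient, zeroed above the ILM and for half a
    kernel below it so the ILM's own edge cannot win."""
    if gradient_kernel % 2 == 0:
        raise ValueError("gradient_kernel must be odd")
    h = gradient_kernel // 2
    kernel = np.concatenate([-np.ones(h), [0.0], np.ones(h)]) / (2 * h)
    grad = ndimage.correlate1d(bscan, kernel, axis=0, mode="nearest")
    weights = np.clip(grad, 0.0, None)
    nz, nx = bscan.shape
    zz = np.arange(nz)[:, None]
    weights[zz < (ilm[None, :] + h)] = 0.0
    return weights


def shortest_path_layer(weights: np.ndarray) -> np.ndarray:
    """Maximum-weight left-to-right path with |dz| <= 1 per column step.

    Dynamic programming over A-scan columns; equivalent to a shortest
    path with cost ``max(weight) - weight``.  All-zero weights yield a
    flat mid-depth path and a warning (no structure to follow).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    nz, nx = w.shape
    if not w.any():
        warnings.warn("all-zero weight field: returning flat path",
                      stacklevel=2)
        return np.full(nx, nz // 2, dtype=float)
    if nz == 1:
        return np.zeros(nx, dtype=float)
    score = w[:, 0].copy()
    back = np.zeros((nz, nx), dtype=np.int8)
    for x in range(1, nx):
        up = np.empty(nz)
        down = np.empty(nz)
        up[0], down[-1] = -np.inf, -np.inf
        up[1:] = score[:-1]
        down[:-1] = score[1:]
        stacked = np.stack([up, score, down])
        choice = np.argmax(stacked, axis=0)
        score = stacked[choice, np.arange(nz)] + w[:, x]
        back[:, x] = choice - 1  # -1: from above, 0: straight, +1: below
    path = np.empty(nx, dtype=float)
    z = int(np.argmax(score))
    for x in range(nx - 1, -1, -1):
        path[x] = z
        z += int(back[z, x])
    return path


def rpe_from_dopu(bscan_intensity: np.ndarray, dopu: np.ndarray | None,
                  isos: np.ndarray,
                  gradient_kernel: int = 15) -> np.ndarray:
    """RPE path from inverse DOPU, restricted to below the IS/OS.

    Without a DOPU channel, falls back to the intensity gradient below
    the IS/OS (with a warning) — less specific, since other outer-retina
    edges also carry gradient energy.
    """
    nz, nx = bscan_intensity.shape
    zz = np.arange(nz)[:, None]
    if dopu is not None:
        weights = 1.0 - np.clip(dopu, 0.0, 1.0)
    else:
        warnings.warn("no DOPU channel: falling back to intensity-gradient "
                      "RPE", stacklevel=2)
        weights = isos_weights(bscan_intensity, isos, gradient_kernel)
    weights = weights.copy()
    weights[zz <= isos[None, :]] = 0.0
    return shortest_path_layer(weights)


def segment_bscan(intensity: np.ndarray, dopu: np.ndarray | None = None,
                  top_fraction: float = 0.5, close_radius: int = 1,
                  min_area: int = 50, smooth_window: int = 101,
                  gradient_kernel: int = 15
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full per-B-scan pipeline: ILM, IS/OS, RPE profiles."""
    binary = threshold_bscan(intensity, top_fraction, close_radius, min_area)
    ilm = estimate_ilm(binary, smooth_window)
    isos = shortest_path_layer(isos_weights(intensity, ilm, gradient_kernel))
    rpe = rpe_from_dopu(intensity, dopu, isos, gradient_kernel)
    return ilm, isos, rpe


def segment_volume(volume: OCTVolume, **kwargs) -> LayerSurfaces:
    nb = volume.n_bscans
    ilm = np.empty((nb, volume.n_ascans))
    isos = np.empty_like(ilm)
    rpe = np.empty_like(ilm)
    for b in range(nb):
        d = volume.dopu[b] if volume.dopu is not None else None
        ilm[b], isos[b], rpe[b] = segment_bscan(volume.intensity[b], d,
                                                **kwargs)
    return LayerSurfaces(ilm=ilm, isos=isos, rpe=rpe)


def flatten_volume(volume: OCTVolume, surfaces: LayerSurfaces,
                   target_depth: int | None = None
                   ) -> tuple[OCTVolume, np.ndarray]:
    """Shift each A-scan axially (integer samples) so the RPE sits at a
    constant depth.  Returns the flattened volume and the shift map
    (positive = column moved up), which ``unflatten_volume`` inverts.
    Out-of-range samples are zero-padded."""
    nb, nz, nx = volume.intensity.shape
    if target_depth is None:
        target_depth = int(round(np.median(surfaces.rpe)))
    shifts = np.round(surfaces.rpe - target_depth).astype(int)
    out = np.zeros_like(volume.intensity)
    out_dopu = np.zeros_like(volume.dopu) if volume.dopu is not None else None
    for b in range(nb):
        for x in range(nx):
            s = shifts[b, x]
            src = slice(max(0, s), min(nz, nz + s))
            dst = slice(max(0, -s), min(nz, nz - s))
            out[b, :, x][dst] = volume.intensity[b, :, x][src]
            if out_dopu is not None:
                out_dopu[b, :, x][dst] = volume.dopu[b, :, x][src]
    flat = OCTVolume(intensity=out, dopu=out_dopu, pitch_um=volume.pitch_um,
                     region=volume.region, seed=volume.seed,
                     meta={**volume.meta, "flattened_rpe_depth": target_depth})
    return flat, shifts


def unflatten_volume(volume: OCTVolume, shifts: np.ndarray) -> OCTVolume:
    """Invert ``flatten_volume`` (interior samples; zero-padded margins
    do not round-trip)."""
    nb, nz, nx = volume.intensity.shape
    out = np.zeros_like(volume.intensity)
    out_dopu = np.zeros_like(volume.dopu) if volume.dopu is not None else None
    for b in range(nb):
        for x in range(nx):
            s = -shifts[b, x]
            src = slice(max(0, s), min(nz, nz + s))
            dst = slice(max(0, -s), min(nz, nz - s))
            out[b, :, x][dst] = volume.intensity[b, :, x][src]
            if out_dopu is not None:
                out_dopu[b, :, x][dst] = volume.dopu[b, :, x][src]
    return OCTVolume(intensity=out, dopu=out_dopu, pitch_um=volume.pitch_um,
                     region=volume.region, seed=volume.seed,
                     meta=dict(volume.meta))
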