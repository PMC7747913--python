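"""Quantitative evaluation: residual motion, graded point error, seams.

* ``residual_motion_stats`` summarizes per-frame (or per-B-scan) lateral
  offsets by SD and range, over all frames and over the best-matching
  subset — the latter excludes microsaccadic spikes that no closed-loop
  tracker can follow.
* ``estimate_bscan_offsets`` recovers lateral offsets of a repeated
  line scan by 1D cross-correlation against a reference B-scan, searched
  within a window around an optional rough bias path.
* ``rmse_pointpairs`` implements the multi-grader feature-point error:
  the mean over points and graders of the Euclidean distance between a
  reference point and the position a grader marked on the mosaic (an
  alternative root-mean-square mode is available).
* ``seam_metric`` quantifies stitching seams as the ratio of boundary-
  band to interior gradient magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk, erosion


@dataclass
class MotionReport:
    sd_all: float
    range_all: float
    sd_best: float
    range_best: float
    k: int


@dataclass
class GradedPointSet:
    """n reference points and their positions as marked by G graders."""

    reference_points: np.ndarray   # (n, 2) (x, y)
    graded_points: np.ndarray      # (n, G, 2)

    def __post_init__(self):
        self.reference_points = np.asarray(self.reference_points, float)
        self.graded_points = np.asarray(self.graded_points, float)
        if self.graded_points.shape[0] != self.reference_points.shape[0]:
            raise ValueError("every reference point needs grader marks")


def residual_motion_stats(offsets: np.ndarray, match_scores: np.ndarray,
                          best_k: int) -> MotionReport:
    """SD and max-min range of a 1D offset trace, over all samples and
    over the ``best_k`` samples ranked by match score."""
    offsets = np.asarray(offsets, dtype=float)
    scores = np.asarray(match_scores, dtype=float)
    if offsets.shape[0] != scores.shape[0]:
        raise ValueError("offsets and match_scores lengths differ")
    if best_k <= 1:
        raise ValueError("best_k must exceed 1")
    if best_k > len(offsets):
        raise ValueError("best_k exceeds the number of samples")
    order = np.argsort(scores)[::-1]
    best = offsets[order[:best_k]]
    return MotionReport(sd_all=float(offsets.std()),
                        range_all=float(offsets.max() - offsets.min()),
                        sd_best=float(best.std()),
                        range_best=float(best.max() - best.min()),
                        k=best_k)


def estimate_bscan_offsets(rows: np.ndarray, reference_index: int = 0,
                           bias_path: np.ndarray | None = None,
                           search_halfwidth: int | None = None,
                           return_scores: bool = False):
    """Per-row lateral offset of a repeated line scan.

    Each row is cross-correlated (mean-subtracted, linear, i.e. without
    circular wrap) against the reference row; the admissible lag window
    is centred on ``bias_path`` when given, otherwise spans all lags.
    Flat rows yield NaN.  With ``return_scores`` the normalized peak
    correlation per row is returned as well — the match-quality measure
    used to rank B-scans for the best-k statistics.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need a 2D stack of at least 2 rows")
    n, width = rows.shape
    ref = rows[reference_index] - rows[reference_index].mean()
    if ref.std() == 0:
        raise ValueError("reference row is flat")
    norm_ref = np.linalg.norm(ref)
    lags = np.arange(-(width - 1), width)
    offsets = np.full(n, np.nan)
    scores = np.zeros(n)
    for i in range(n):
        r = rows[i] - rows[i].mean()
        if r.std() == 0:
            continue
        corr = np.correlate(r, ref, mode="full")  # index k -> lag k-(W-1)
        admissible = np.ones(corr.shape, dtype=bool)
        if bias_path is not None and search_halfwidth is not None:
            admissible = np.abs(lags - bias_path[i]) <= search_halfwidth
        corr = np.where(admissible, corr, -np.inf)
        k = int(np.argmax(corr))
        offsets[i] = lags[k]
        scores[i] = corr[k] / (norm_ref * np.linalg.norm(r))
    if return_scores:
        return offsets, scores
    return offsets


def rmse_pointpairs(points: GradedPointSet, pitch_um: float,
                    mode: str = "mean") -> tuple[float, float, float]:
    """Multi-grader registration error.

    Returns ``(err_px, err_um, sd_px)`` where ``err_px`` is the mean over
    all (point, grader) combinations of the Euclidean distance between
    the reference point and the graded mark (``mode='rms'`` takes the
    square root of the mean squared distance instead), and ``sd_px`` the
    SD of those distances.
    """
    ref = points.reference_points[:, None, :]
    d = np.linalg.norm(points.graded_points - ref, axis=-1).ravel()
    if mode == "mean":
        err = float(d.mean())
    elif mode == "rms":
        err = float(np.sqrt(np.mean(d ** 2)))
    else:
        raise ValueError("mode must be 'mean' or 'rms'")
    return err, err * pitch_um, float(d.std())


def seam_metric(mosaic: np.ndarray, footprints: list[np.ndarray],
                band_px: int = 2, percentile: float = 99.0,
                valid: np.ndarray | None = None) -> float:
    """Boundary-to-interior gradient ratio.

    Gradient magnitude is pooled (at ``percentile``) over a thin band
    around every footprint boundary and over footprint interiors; their
    ratio approaches 1 for seam-free blends and grows when stitching
    leaves intensity steps at footprint edges.
    """
    if not footprints:
        raise ValueError("need at least one footprint")
    gy, gx = np.gradient(mosaic.astype(float))
    gmag = np.hypot(gy, gx)
    if valid is None:
        valid = np.ones_like(mosaic, dtype=bool)
    boundary = np.zeros_like(valid)
    interior = np.zeros_like(valid)
    selem = disk(band_px)
    for fp in footprints:
        edge = dilation(fp, selem) & ~erosion(fp, selem)
        boundary |= edge
        interior |= erosion(fp, disk(2 * band_px + 1))
    # stay clear of the union's outer edge: the step to the empty canvas
    # is not a stitching seam
    covered_interior = erosion(valid, disk(band_px + 2))
    boundary &= covered_interior
    interior &= covered_interior & ~boundary
    if not boundary.any() or not interior.any():
        return 1.0
    b = float(np.percentile(gmag[boundary], percentile))
    i = float(np.percentile(gmag[interior], percentile))
    return b / i if i > 0 else np.inf
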