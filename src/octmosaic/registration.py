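"""Registration of en-face projections to a wide-field fundus reference.

The chain has four stages:

1. *Reference preparation* — the fundus photo's green channel (highest
   vessel contrast) is rescaled so 1 px = 8.2 um, matching the OCT x
   pitch, and zero-padded because the mosaic extends past the photo.
2. *Pincushion pre-correction* — radial distortion ``r_c = r_u (1 + k
   r_u^2)`` with the factor k chosen by grid search for the value that
   minimizes the residual mismatch between corrected projections and the
   reference.
3. *Recursive pyramid point-pair estimation* — the projection is
   phase-correlated against the reference as a whole, then split into 4
   quadrants, each correlated inside a Gaussian search mask centred at
   the location the parent level predicts, and so on: levels n yield
   ``sum_i 4^i`` point pairs, dense enough to observe spatially varying
   distortion while each part stays large enough for robust correlation.
4. *Pruning and polynomial fit* — the weakest 30% of pairs by peak
   height are dismissed; the rest determine two second-order polynomials
   ``x' = a x^2 + b y^2 + c xy + d x + e y + f`` (one per output axis) by
   least squares, plus the fitted inverse map.

Point coordinates are (x, y); images are indexed (y, x).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phasecorr
from .enface import EnFaceProjection
from .slo import hamming2d

TARGET_PITCH_UM = 8.2


@dataclass
class FundusReference:
    pixels: np.ndarray
    pitch_um: float = TARGET_PITCH_UM
    pad_px: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PincushionModel:
    """Radial distortion ``r_c = r_u (1 + k r_u^2)`` on normalized radii.

    Radii are normalized by ``scale`` (default: half the image diagonal)
    about ``center`` (x, y).  ``k = 0`` is the identity.
    """

    k: float
    center: tuple[float, float]
    scale: float

    @classmethod
    def for_shape(cls, shape: tuple[int, int], k: float) -> "PincushionModel":
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        return cls(k=float(k), center=(cx, cy),
                   scale=math.hypot(cy, cx))

    def correct_points(self, pts: np.ndarray) -> np.ndarray:
        """Uncorrected -> corrected coordinates (direct evaluation)."""
        pts = np.asarray(pts, dtype=float)
        rel = (pts - np.asarray(self.center)) / self.scale
        ru = np.hypot(rel[..., 0], rel[..., 1])
        factor = 1.0 + self.k * ru ** 2
        return np.asarray(self.center) + rel * factor[..., None] * self.scale

    def uncorrect_points(self, pts: np.ndarray) -> np.ndarray:
        """Corrected -> uncorrected: invert the cubic radius map by Newton
        iteration (the map is monotone for the small k in play)."""
        pts = np.asarray(pts, dtype=float)
        rel = (pts - np.asarray(self.center)) / self.scale
        rc = np.hypot(rel[..., 0], rel[..., 1])
        ru = rc.copy()
        for _ in range(25):
            f = ru * (1.0 + self.k * ru ** 2) - rc
            fp = 1.0 + 3.0 * self.k * ru ** 2
            ru = ru - f / fp
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(rc > 0, ru / rc, 1.0)
        return np.asarray(self.center) + rel * ratio[..., None] * self.scale


def undistort_image(image: np.ndarray, model: PincushionModel) -> np.ndarray:
    """Resample ``image`` onto the corrected grid (inverse mapping with
    bilinear interpolation)."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    src = model.uncorrect_points(np.stack([xx, yy], axis=-1))
    return ndimage.map_coordinates(image, [src[..., 1], src[..., 0]],
                                   order=1, mode="constant")


def distort_image(image: np.ndarray, model: PincushionModel) -> np.ndarray:
    """Apply the distortion to an undistorted image (synthesis direction,
    used to fabricate test inputs with known k)."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    src = model.correct_points(np.stack([xx, yy], axis=-1))
    return ndimage.map_coordinates(image, [src[..., 1], src[..., 0]],
                                   order=1, mode="constant")


@dataclass
class PointPair:
    source: tuple[float, float]   # (x, y) in projection coordinates
    target: tuple[float, float]   # (x, y) in fundus coordinates
    peak_height: float
    level: int


@dataclass
class RegionTransform:
    """Pincushion pre-correction followed by per-axis quadratic polynomials.

    ``poly_x``/``poly_y`` are coefficient vectors (a, b, c, d, e, f) of
    ``f(x, y) = a x^2 + b y^2 + c xy + d x + e y + f`` mapping corrected
    projection coordinates to fundus coordinates.  The stored inverse
    polynomials seed a Newton refinement, so round-tripping a point
    through forward and inverse maps reproduces it to well under a
    quarter pixel over the projection support.
    """

    poly_x: np.ndarray
    poly_y: np.ndarray
    inv_poly_x: np.ndarray
    inv_poly_y: np.ndarray
    pincushion: PincushionModel | None = None
    residual_px: float = 0.0
    meta: dict = field(default_factory=dict)

    @staticmethod
    def _design(pts: np.ndarray) -> np.ndarray:
        x, y = pts[..., 0], pts[..., 1]
        return np.stack([x * x, y * y, x * y, x, y, np.ones_like(x)],
                        axis=-1)

    def _poly_forward(self, pts: np.ndarray) -> np.ndarray:
        a = self._design(np.asarray(pts, dtype=float))
        return np.stack([a @ self.poly_x, a @ self.poly_y], axis=-1)

    def _poly_inverse_seed(self, pts: np.ndarray) -> np.ndarray:
        a = self._design(np.asarray(pts, dtype=float))
        return np.stack([a @ self.inv_poly_x, a @ self.inv_poly_y], axis=-1)

    def _poly_inverse(self, pts: np.ndarray, iters: int = 8) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        est = self._poly_inverse_seed(pts)
        for _ in range(iters):
            x, y = est[..., 0], est[..., 1]
            fx = self.poly_x
            fy = self.poly_y
            rx = (fx[0] * x * x + fx[1] * y * y + fx[2] * x * y
                  + fx[3] * x + fx[4] * y + fx[5]) - pts[..., 0]
            ry = (fy[0] * x * x + fy[1] * y * y + fy[2] * x * y
                  + fy[3] * x + fy[4] * y + fy[5]) - pts[..., 1]
            j00 = 2 * fx[0] * x + fx[2] * y + fx[3]
            j01 = 2 * fx[1] * y + fx[2] * x + fx[4]
            j10 = 2 * fy[0] * x + fy[2] * y + fy[3]
            j11 = 2 * fy[1] * y + fy[2] * x + fy[4]
            det = j00 * j11 - j01 * j10
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            est = est - np.stack([(j11 * rx - j01 * ry) / det,
                                  (-j10 * rx + j00 * ry) / det], axis=-1)
        return est

    def forward_points(self, pts: np.ndarray) -> np.ndarray:
        """Raw projection coordinates -> fundus coordinates."""
        pts = np.asarray(pts, dtype=float)
        if self.pincushion is not None:
            pts = self.pincushion.correct_points(pts)
        return self._poly_forward(pts)

    def inverse_points(self, pts: np.ndarray) -> np.ndarray:
        """Fundus coordinates -> raw projection coordinates."""
        est = self._poly_inverse(pts)
        if self.pincushion is not None:
            est = self.pincushion.uncorrect_points(est)
        return est

    def to_dict(self) -> dict:
        return {
            "k": self.pincushion.k if self.pincushion else 0.0,
            "poly_x": list(map(float, self.poly_x)),
            "poly_y": list(map(float, self.poly_y)),
            "inv_poly_x": list(map(float, self.inv_poly_x)),
            "inv_poly_y": list(map(float, self.inv_poly_y)),
            "residual_px": float(self.residual_px),
        }

    @classmethod
    def from_dict(cls, d: dict,
                  shape: tuple[int, int] | None = None) -> "RegionTransform":
        pin = None
        if d.get("k", 0.0) != 0.0 and shape is not None:
            pin = PincushionModel.for_shape(shape, d["k"])
        return cls(poly_x=np.asarray(d["poly_x"]),
                   poly_y=np.asarray(d["poly_y"]),
                   inv_poly_x=np.asarray(d["inv_poly_x"]),
                   inv_poly_y=np.asarray(d["inv_poly_y"]),
                   pincushion=pin, residual_px=d.get("residual_px", 0.0))


def prepare_fundus_reference(photo: np.ndarray, photo_pitch_um: float,
                             pad_px: int = 128) -> FundusReference:
    """Green channel, rescale to 8.2 um/px, zero-pad the borders."""
    if photo_pitch_um is None or photo_pitch_um <= 0:
        raise ValueError("photo_pitch_um must be a positive pixel pitch")
    if photo.ndim == 3:
        green = photo[..., 1].astype(float)
    elif photo.ndim == 2:
        green = photo.astype(float)
    else:
        raise ValueError("expected an RGB or grayscale photo")
    factor = photo_pitch_um / TARGET_PITCH_UM
    if abs(factor - 1.0) > 1e-9:
        green = ndimage.zoom(green, factor, order=1)
    padded = np.pad(green, pad_px, mode="constant")
    return FundusReference(pixels=padded, pad_px=pad_px)


def resample_isotropic(projection: EnFaceProjection,
                       target_pitch_um: float = TARGET_PITCH_UM
                       ) -> np.ndarray:
    """Resample a projection to square ``target_pitch_um`` pixels so
    pixel offsets against the reference are commensurate (the slow axis
    pitch of 25.2 um is ~3x the fast axis 8.2 um)."""
    fy = projection.pitch_um[1] / target_pitch_um
    fx = projection.pitch_um[0] / target_pitch_um
    return ndimage.zoom(projection.pixels.astype(float), (fy, fx), order=1)


def gaussian_mask(shape: tuple[int, int], center_xy: tuple[float, float],
                  sigma: tuple[float, float]) -> np.ndarray:
    """Unit-peak 2D Gaussian search mask over the reference grid."""
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    return np.exp(-0.5 * (((yy - center_xy[1]) / sigma[1]) ** 2
                          + ((xx - center_xy[0]) / sigma[0]) ** 2))


def masked_phase_correlate(reference: FundusReference, part: np.ndarray,
                           search_mask: np.ndarray | None = None,
                           epsilon: float = 1e-6
                           ) -> tuple[float, float, float]:
    """Locate a projection part inside the reference.

    The part is Hamming-windowed, zero-padded to reference size and
    phase-correlated; the surface is re-indexed so each bin corresponds
    to a candidate position of the *part centre* in reference
    coordinates, multiplied by the search mask, and the peak located
    with subpixel refinement.  Returns ``(center_x, center_y, peak)``.
    """
    rh, rw = reference.shape
    ph, pw = part.shape
    if ph > rh or pw > rw:
        raise ValueError("part must be smaller than the reference")
    canvas = np.zeros((rh, rw))
    canvas[:ph, :pw] = part * hamming2d(part.shape)
    surface = phasecorr.phase_correlate(np.fft.fft2(reference.pixels),
                                        canvas, epsilon).spatial
    # surface[d] peaks where canvas = roll(ref, d); the part's top-left
    # sits at -d, its centre at -d + half-extent.
    hc_y, hc_x = ph / 2.0, pw / 2.0
    idx_y = (int(round(hc_y)) - np.arange(rh)) % rh
    idx_x = (int(round(hc_x)) - np.arange(rw)) % rw
    centred = surface[np.ix_(idx_y, idx_x)]
    frac_y = hc_y - round(hc_y)
    frac_x = hc_x - round(hc_x)
    if search_mask is not None:
        if search_mask.shape != centred.shape:
            raise ValueError("search mask must match the reference shape")
        centred = centred * search_mask
    cy, cx, peak = phasecorr_peak_absolute(centred)
    return cx + frac_x, cy + frac_y, peak


def phasecorr_peak_absolute(surface: np.ndarray
                            ) -> tuple[float, float, float]:
    """Smooth, argmax and centroid-refine a surface whose indices are
    absolute positions (no circular wrap of the result)."""
    smoothed = ndimage.convolve(surface, phasecorr._KERNEL3, mode="wrap")
    py, px = np.unravel_index(int(np.argmax(smoothed)), smoothed.shape)
    ny, nx = smoothed.shape
    neigh = smoothed[np.ix_((py + np.arange(-1, 2)) % ny,
                            (px + np.arange(-1, 2)) % nx)]
    fy, fx = phasecorr._centroid_fraction(neigh)
    return py + fy, px + fx, float(smoothed[py, px])


def pyramid_pointset(reference: FundusReference, projection: np.ndarray,
                     init_mask: np.ndarray | None = None, levels_n: int = 3,
                     min_part_px: int = 64) -> list[PointPair]:
    """Recursive pyramid point-pair estimation.

    Level 0 correlates the whole projection; each further level splits
    every part into 4 quadrants and correlates them inside a Gaussian
    search mask (half the quadrant size, SD one sixth of the mask
    extent) centred where the parent peak predicts the quadrant to be.
    With no early termination the result holds ``sum_{i<=n} 4^i`` pairs;
    parts smaller than ``min_part_px`` stop their branch early because
    small parts make the correlation fragile.
    """
    if levels_n < 0:
        raise ValueError("levels_n must be >= 0")
    pairs: list[PointPair] = []

    def recurse(top: tuple[int, int], shape: tuple[int, int],
                mask: np.ndarray | None, remaining: int, depth: int) -> None:
        ty, tx = top
        h, w = shape
        part = projection[ty:ty + h, tx:tx + w]
        cx_src = tx + w / 2.0
        cy_src = ty + h / 2.0
        tgt_x, tgt_y, peak = masked_phase_correlate(reference, part, mask)
        pairs.append(PointPair(source=(cx_src, cy_src),
                               target=(tgt_x, tgt_y),
                               peak_height=peak, level=depth))
        if remaining <= 0:
            return
        h2, w2 = h // 2, w // 2
        if min(h2, w2) < min_part_px:
            warnings.warn("pyramid branch stopped early: part below the "
                          "minimum robust size", stacklevel=2)
            return
        for qy, qx in ((0, 0), (0, 1), (1, 0), (1, 1)):
            sub_top = (ty + qy * h2, tx + qx * w2)
            sub_shape = (h2 if qy == 0 else h - h2,
                         w2 if qx == 0 else w - w2)
            sub_cx = sub_top[1] + sub_shape[1] / 2.0
            sub_cy = sub_top[0] + sub_shape[0] / 2.0
            exp_x = tgt_x + (sub_cx - cx_src)
            exp_y = tgt_y + (sub_cy - cy_src)
            sigma = (sub_shape[1] / 12.0, sub_shape[0] / 12.0)
            sub_mask = gaussian_mask(reference.shape, (exp_x, exp_y), sigma)
            recurse(sub_top, sub_shape, sub_mask, remaining - 1, depth + 1)

    recurse((0, 0), projection.shape, init_mask, levels_n, 0)
    return pairs


def prune_and_fit(pairs: list[PointPair],
                  pincushion: PincushionModel | None = None,
                  keep_fraction: float = 0.7) -> RegionTransform:
    """Dismiss the weakest pairs and fit the quadratic transform.

    The kept count is rounded up (``ceil(0.7 N)``) so pruning can never
    push the sample below the fitting minimum on small sets.  With fewer
    than 9 survivors the quadratic system is barely determined, so the
    fit degrades to a similarity-like transform (linear terms only) with
    a warning.
    """
    if not pairs:
        raise ValueError("no point pairs to fit")
    n_keep = int(math.ceil(keep_fraction * len(pairs)))
    kept = sorted(pairs, key=lambda p: p.peak_height, reverse=True)[:n_keep]
    src = np.array([p.source for p in kept], dtype=float)
    dst = np.array([p.target for p in kept], dtype=float)

    if len(kept) >= 9:
        order = "quadratic"
    elif len(kept) >= 3:
        order = "affine"
        warnings.warn(f"only {len(kept)} pairs survive pruning: falling "
                      "back to an affine fit", stacklevel=2)
    else:
        order = "translation"
        if len(pairs) > 1:
            warnings.warn(f"only {len(kept)} pairs survive pruning: "
                          "translation-only fit", stacklevel=2)

    def fit(a_pts: np.ndarray, b_pts: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
        if order == "translation":
            shift = (b_pts - a_pts).mean(axis=0)
            cx = np.array([0.0, 0.0, 0.0, 1.0, 0.0, shift[0]])
            cy = np.array([0.0, 0.0, 0.0, 0.0, 1.0, shift[1]])
            pred = a_pts + shift
            rms = float(np.sqrt(np.mean(np.sum((pred - b_pts) ** 2,
                                               axis=1))))
            return cx, cy, rms
        a = RegionTransform._design(a_pts)
        if order == "affine":
            a = a.copy()
            a[:, :3] = 0.0
        cx, *_ = np.linalg.lstsq(a, b_pts[:, 0], rcond=None)
        cy, *_ = np.linalg.lstsq(a, b_pts[:, 1], rcond=None)
        res = np.stack([a @ cx - b_pts[:, 0], a @ cy - b_pts[:, 1]], axis=-1)
        rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
        if order == "affine":
            cx[:3] = 0.0
            cy[:3] = 0.0
        return cx, cy, rms

    fwd_x, fwd_y, rms = fit(src, dst)
    inv_x, inv_y, _ = fit(dst, src)
    return RegionTransform(poly_x=fwd_x, poly_y=fwd_y, inv_poly_x=inv_x,
                           inv_poly_y=inv_y, pincushion=pincushion,
                           residual_px=rms,
                           meta={"n_pairs": len(pairs), "n_kept": len(kept)})


def estimate_k(projections: list[np.ndarray], reference: FundusReference,
               k_grid: list[float], levels_n: int = 1,
               min_part_px: int = 32) -> PincushionModel:
    """Grid-search the pincushion factor k.

    For each candidate, projections are undistorted, registered by a
    shallow pyramid, and scored by the residual of an affine fit to the
    point pairs — residual distortion that an affine map cannot absorb.
    The k with the lowest mean residual wins.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    scores = []
    for k in k_grid:
        residuals = []
        for proj in projections:
            model = PincushionModel.for_shape(proj.shape, k)
            corrected = undistort_image(proj, model)
            pairs = pyramid_pointset(reference, corrected, levels_n=levels_n,
                                     min_part_px=min_part_px)
            src = np.array([p.source for p in pairs])
            dst = np.array([p.target for p in pairs])
            a = np.column_stack([src, np.ones(len(src))])
            res = 0.0
            for axis in range(2):
                coef, *_ = np.linalg.lstsq(a, dst[:, axis], rcond=None)
                res += float(np.mean((a @ coef - dst[:, axis]) ** 2))
            residuals.append(math.sqrt(res))
        scores.append(float(np.mean(residuals)))
    best = int(np.argmin(scores))
    model = PincushionModel.for_shape(projections[0].shape, k_grid[best])
    model_scores = dict(zip(map(float, k_grid), scores))
    # retain the score curve for diagnostics
    model.__dict__["score_curve"] = model_scores
    return model
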