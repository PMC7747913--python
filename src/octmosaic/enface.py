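"""En-face projection over the RPE band and averaging of repeated volumes.

Summing OCT intensity over a thin axial band at the retinal pigment
epithelium gives a fundus-like image in which vessel shadows have maximal
contrast — the moving image used for registration against the wide-field
fundus photo.  Repeated volumes of the same region are rigidly aligned by
phase correlation and averaged to raise SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import phasecorr
from .layers import LayerSurfaces
from .synthetic import OCTVolume


@dataclass
class EnFaceProjection:
    """2D projection image: rows are B-scans (y), columns A-scans (x)."""

    pixels: np.ndarray
    band_um: float
    region: str
    pitch_um: tuple[float, float]  # (x, y)
    n_averaged: int = 1
    meta: dict = field(default_factory=dict)


def project_band(volume: OCTVolume, surfaces: LayerSurfaces | None = None,
                 band_um: float = 30.0,
                 band_center: float | None = None) -> EnFaceProjection:
    """Sum intensity over an axial band of ``band_um`` microns centred at
    the flattened RPE depth.

    The volume must be RPE-flattened.  Band edges falling between depth
    samples are handled by fractional weighting of the boundary samples,
    so the projection is continuous in ``band_um``.  A band reaching
    outside the recorded depth range is clipped with a warning.
    """
    if band_um <= 0:
        raise ValueError("band_um must be positive")
    nz = volume.n_depth
    zp = volume.pitch_um[2]
    if band_center is None:
        band_center = volume.meta.get("flattened_rpe_depth")
        if band_center is None:
            raise ValueError("volume is not flattened; pass band_center "
                             "explicitly")
    half_px = band_um / (2.0 * zp)
    lo, hi = band_center - half_px, band_center + half_px
    if lo < -0.5 or hi > nz - 0.5:
        warnings.warn("projection band clipped to the recorded depth range",
                      stacklevel=2)
        lo, hi = max(lo, -0.5), min(hi, nz - 0.5)
    z = np.arange(nz)
    # overlap of [z-0.5, z+0.5] with [lo, hi]
    w = np.clip(np.minimum(z + 0.5, hi) - np.maximum(z - 0.5, lo), 0.0, 1.0)
    pixels = np.tensordot(volume.intensity, w, axes=([1], [0]))
    return EnFaceProjection(pixels=pixels.astype(np.float64), band_um=band_um,
                            region=volume.region,
                            pitch_um=(volume.pitch_um[0], volume.pitch_um[1]),
                            meta={"band_center_px": float(band_center)})


def register_and_average_repeats(projections: list[EnFaceProjection],
                                 peak_threshold: float = 0.03
                                 ) -> EnFaceProjection:
    """Align repeated projections of one region and average them.

    The first projection is the reference; the others are shifted by the
    integer phase-correlation offset and averaged with a per-pixel
    divisor over the overlapping support.  A member whose correlation
    peak falls below ``peak_threshold`` is dropped with a warning — the
    automated stand-in for visual rejection of motion-corrupted scans.
    """
    if not projections:
        raise ValueError("need at least one projection")
    ref = projections[0]
    ref_spec = np.fft.fft2(ref.pixels)
    acc = ref.pixels.astype(float).copy()
    div = np.ones_like(acc)
    used = 1
    for p in projections[1:]:
        if p.pixels.shape != ref.pixels.shape:
            raise ValueError("projections must share dimensions")
        est = phasecorr.estimate_offset(ref_spec, p.pixels)
        if est.peak_height < peak_threshold:
            warnings.warn(f"dropping repeat of region {p.region!r}: "
                          f"peak {est.peak_height:.3g} below threshold",
                          stacklevel=2)
            continue
        dy, dx = int(round(est.dy)), int(round(est.dx))
        shifted = np.zeros_like(acc)
        support = np.zeros_like(acc)
        h, w = acc.shape
        src_y = slice(max(0, dy), min(h, h + dy))
        dst_y = slice(max(0, -dy), min(h, h - dy))
        src_x = slice(max(0, dx), min(w, w + dx))
        dst_x = slice(max(0, -dx), min(w, w - dx))
        shifted[dst_y, dst_x] = p.pixels[src_y, src_x]
        support[dst_y, dst_x] = 1.0
        acc += shifted
        div += support
        used += 1
    out = acc / div
    return EnFaceProjection(pixels=out, band_um=ref.band_um,
                            region=ref.region, pitch_um=ref.pitch_um,
                            n_averaged=used, meta=dict(ref.meta))
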