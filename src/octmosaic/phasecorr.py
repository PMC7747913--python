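"""2D phase correlation with spectral high-pass filtering and subpixel peaks.

Phase correlation estimates the translation between two images from the
normalized cross-power spectrum: for ``g = roll(f, d)`` the inverse
transform of ``G(w) FF*(w) / (|G(w) FF*(w)| + eps)`` is a sharp peak at
``d``.  Because only the phase carries through, the peak is much narrower
than in plain cross-correlation and the estimate is robust to global
illumination changes.

All offsets follow the package convention: images are indexed ``(y, x)``,
offsets are ``(dy, dx)`` such that ``frame == roll(reference, (dy, dx))``,
and circular ambiguity is resolved to the interval ``(-N/2, N/2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class SpectralFilter:
    """High-pass gain map applied multiplicatively in frequency space.

    The gain is ``1 - G_s(w)`` with ``G_s`` a unit-peak Gaussian of width
    ``kernel_size_s`` (in FFT-bin units) centred at DC, so the mean
    intensity is suppressed and sharp edges pass unattenuated.
    """

    kernel_size_s: float
    gain_map: np.ndarray
    applications: int = 1

    def apply(self, spectrum: np.ndarray) -> np.ndarray:
        out = spectrum
        for _ in range(self.applications):
            out = out * self.gain_map
        return out


@dataclass
class CorrelationSurface:
    """Spatial-domain correlation surface and the spectrum it came from."""

    cross_spectrum: np.ndarray
    spatial: np.ndarray
    epsilon: float


@dataclass
class OffsetEstimate:
    dy: float
    dx: float
    peak_height: float
    valid: bool = True
    reason: str = "ok"


def make_highpass(shape: tuple[int, int], kernel_size_s: float | None = None,
                  applications: int = 1) -> SpectralFilter:
    """Build the spectral high-pass ``1 - Gaussian(w; s)`` for ``shape``.

    ``kernel_size_s`` defaults to ``shape[1] / 8``.  Applying the filter
    twice (``applications=2``) is used to pre-filter a reference spectrum
    once so per-frame work needs no filtering at all.
    """
    if kernel_size_s is None:
        kernel_size_s = shape[1] / 8.0
    if kernel_size_s <= 0:
        raise ValueError("kernel_size_s must be positive")
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    d2 = fy[:, None] ** 2 + fx[None, :] ** 2
    gain = 1.0 - np.exp(-d2 / (2.0 * kernel_size_s ** 2))
    return SpectralFilter(kernel_size_s=float(kernel_size_s), gain_map=gain,
                          applications=applications)


def phase_correlate(reference_spectrum: np.ndarray, frame: np.ndarray,
                    epsilon: float = 1e-9) -> CorrelationSurface:
    """Correlate a (pre-filtered) reference spectrum against a spatial frame.

    ``epsilon`` is scaled by the median cross-power magnitude so the
    stabiliser is dimensionless with respect to image intensity.
    """
    if reference_spectrum.shape != frame.shape:
        raise ValueError("reference spectrum and frame shapes differ: "
                         f"{reference_spectrum.shape} vs {frame.shape}")
    g = np.fft.fft2(frame)
    cross = g * np.conj(reference_spectrum)
    mag = np.abs(cross)
    scale = float(np.median(mag))
    if scale == 0.0:
        scale = 1.0
    r_spec = cross / (mag + epsilon * scale)
    spatial = np.real(np.fft.ifft2(r_spec))
    return CorrelationSurface(cross_spectrum=r_spec, spatial=spatial,
                              epsilon=epsilon)


_G1 = np.exp(-0.5 * np.array([1.0, 0.0, 1.0]))
_KERNEL3 = np.outer(_G1, _G1)
_KERNEL3 /= _KERNEL3.sum()


def _wrap(v: np.ndarray | float, n: int):
    """Map indices to the centred interval (-n/2, n/2]."""
    w = np.mod(np.asarray(v, dtype=float), n)
    w = np.where(w > n / 2, w - n, w)
    return w


def _centroid_fraction(neigh: np.ndarray) -> tuple[float, float]:
    """Fractional peak position from a 3x3 neighbourhood.

    Works on the row/column marginals with their minimum subtracted, so
    the flat correlation floor does not bias the centroid toward the
    integer bin; two equal adjacent bins land exactly on their midpoint.
    """
    d = np.arange(-1, 2, dtype=float)
    out = []
    for marginal in (np.clip(neigh, 0.0, None).sum(axis=1),
                     np.clip(neigh, 0.0, None).sum(axis=0)):
        w = marginal - marginal.min()
        total = w.sum()
        out.append(float((w * d).sum() / total) if total > 0 else 0.0)
    return out[0], out[1]


def locate_peak_subpixel(surface: CorrelationSurface) -> OffsetEstimate:
    """Locate the correlation peak with subpixel precision.

    The surface is smoothed with a 3x3 Gaussian to suppress pixel-to-pixel
    jitter; the integer argmax is then refined by the intensity-weighted
    centroid of its (circularly indexed) 3x3 neighbourhood.  When several
    bins tie for the maximum the one closest to zero offset wins: the
    smallest-motion hypothesis.
    """
    r = surface.spatial
    if not np.all(np.isfinite(r)):
        raise ValueError("correlation surface contains non-finite values")
    ny, nx = r.shape
    smoothed = ndimage.convolve(r, _KERNEL3, mode="wrap")
    peak = float(smoothed.max())
    if peak <= 0 or np.allclose(smoothed, smoothed.flat[0]):
        return OffsetEstimate(0.0, 0.0, peak_height=max(peak, 0.0),
                              valid=False, reason="peak_too_low")
    ys, xs = np.nonzero(smoothed >= peak * (1.0 - 1e-12))
    wy = _wrap(ys, ny)
    wx = _wrap(xs, nx)
    best = int(np.argmin(wy ** 2 + wx ** 2))
    py, px = int(ys[best]), int(xs[best])

    neigh = smoothed[np.ix_((py + np.arange(-1, 2)) % ny,
                            (px + np.arange(-1, 2)) % nx)]
    fy, fx = _centroid_fraction(neigh)
    dy = float(_wrap(py + fy, ny))
    dx = float(_wrap(px + fx, nx))
    return OffsetEstimate(dy=dy, dx=dx, peak_height=peak)


def estimate_offset(reference_spectrum: np.ndarray, frame: np.ndarray,
                    epsilon: float = 1e-9) -> OffsetEstimate:
    """Convenience wrapper: correlate and locate the peak in one call."""
    return locate_peak_subpixel(phase_correlate(reference_spectrum, frame,
                                                epsilon))


def brute_force_integer_offset(reference: np.ndarray,
                               frame: np.ndarray) -> tuple[int, int]:
    """Exhaustive argmax of the normalized cross-spectrum over all shifts.

    Independent oracle used in tests: evaluates the phase-only correlation
    at every integer circular shift by direct summation, without the
    smoothing or subpixel stages of the production path.
    """
    f = np.fft.fft2(reference)
    g = np.fft.fft2(frame)
    cross = g * np.conj(f)
    mag = np.abs(cross)
    cross = np.where(mag > 0, cross / np.where(mag == 0, 1, mag), 0)
    ny, nx = reference.shape
    best = (-np.inf, 0, 0)
    wy = np.exp(2j * np.pi * np.fft.fftfreq(ny)[:, None]
                * np.arange(ny)[None, :])
    wx = np.exp(2j * np.pi * np.fft.fftfreq(nx)[:, None]
                * np.arange(nx)[None, :])
    # r(d) = sum_w cross(w) exp(+i w.d) / N, evaluated densely
    r = np.real(np.einsum("ab,ac,bd->cd", cross, wy, wx)) / (ny * nx)
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    return int(_wrap(iy, ny)), int(_wrap(ix, nx))
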