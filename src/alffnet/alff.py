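"""Amplitude of low-frequency fluctuations (ALFF) from 4D BOLD series.

The ALFF of a voxel is the mean square-root spectral power of its
(detrended, band-passed) time series over the 0.01-0.08 Hz band.  The
spectral dialect follows the FFT-centric convention: no taper, transform
length equal to the series length, band edges inclusive, band-pass
realised by zeroing frequency bins outside the band.  Per-bin amplitude is
scaled as sqrt(2)*|X_k|/N so that the squared amplitudes of the one-sided
spectrum sum to the mean square of the (zero-mean) signal.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_BAND",
    "preprocess_series",
    "bandlimited_amplitude",
    "compute_alff_map",
    "smooth_volume",
    "estimate_fwhm",
]

#: Conversion from Gaussian FWHM to standard deviation: 1/sqrt(8 ln 2).
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

DEFAULT_BAND = (0.01, 0.08)

#: Motion-exclusion limits: maximum displacement (mm) and rotation (deg).
MAX_DISPLACEMENT_MM = 3.0
MAX_ROTATION_DEG = 3.0


def preprocess_series(
    data4d: np.ndarray,
    n_discard: int,
    motion_summary: tuple[float, float] | None = None,
    max_displacement_mm: float = MAX_DISPLACEMENT_MM,
    max_rotation_deg: float = MAX_ROTATION_DEG,
    detrend: bool = True,
) -> tuple[np.ndarray, bool]:
    """Drop initial volumes, remove per-voxel linear trends, and flag
    subjects whose motion summary exceeds the exclusion limits.

    ``motion_summary`` is (max displacement mm, max rotation deg), as
    produced upstream by realignment; realignment itself is out of scope.
    Returns (preprocessed 4D array, excluded flag).
    """
    data4d = np.asarray(data4d)
    if data4d.ndim != 4:
        raise ValueError("expected a 4D array (x, y, z, t)")
    if data4d.shape[-1] < n_discard + 2:
        raise ValueError(
            f"series of {data4d.shape[-1]} volumes too short to discard "
            f"{n_discard} and retain >=2"
        )
    excluded = False
    if motion_summary is not None:
        disp, rot = motion_summary
        excluded = disp > max_displacement_mm or rot > max_rotation_deg
    out = data4d[..., n_discard:].astype(np.float64)
    if detrend:
        # closed-form linear detrend: subtract the projection onto {1, t}
        t = np.arange(out.shape[-1], dtype=np.float64)
        t -= t.mean()
        out -= out.mean(axis=-1, keepdims=True)
        slope = (out @ t) / (t @ t)
        out -= slope[..., None] * t
    return out, excluded


def _band_mask(n: int, tr_s: float, band: Sequence[float]) -> np.ndarray:
    f_lo, f_hi = band
    nyquist = 0.5 / tr_s
    if not 0.0 < f_lo < f_hi:
        raise ValueError(f"band must satisfy 0 < f_lo < f_hi, got {band}")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {f_hi} Hz above Nyquist {nyquist:.4f} Hz")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    return (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)


def _band_amplitudes(x: np.ndarray, tr_s: float, band: Sequence[float]) -> np.ndarray:
    """One-sided per-bin amplitudes sqrt(2)|X_k|/N within the band.

    ``x`` has time on the last axis; returns (..., n_band_bins).
    """
    n = x.shape[-1]
    keep = _band_mask(n, tr_s, band)
    spec = np.fft.rfft(x, axis=-1)
    return np.sqrt(2.0) * np.abs(spec[..., keep]) / n


def bandlimited_amplitude(
    timeseries: Sequence[float], tr_s: float, band: Sequence[float] = DEFAULT_BAND
) -> float:
    """Mean square-root spectral power of one time series over the band."""
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1D series with at least 2 samples")
    amps = _band_amplitudes(x - x.mean(), tr_s, band)
    if amps.size == 0:
        return 0.0
    return float(amps.mean())


def compute_alff_map(
    data4d: np.ndarray,
    mask: np.ndarray,
    tr_s: float,
    band: Sequence[float] = DEFAULT_BAND,
) -> np.ndarray:
    """Voxelwise ALFF inside the brain mask; outside-mask voxels are 0."""
    data4d = np.asarray(data4d)
    mask = np.asarray(mask).astype(bool)
    if data4d.ndim != 4:
        raise ValueError("expected a 4D array (x, y, z, t)")
    if mask.shape != data4d.shape[:3]:
        raise ValueError("mask shape does not match the volume grid")
    if not mask.any():
        raise ValueError("empty brain mask")
    series = data4d[mask].astype(np.float64)
    series -= series.mean(axis=-1, keepdims=True)
    amps = _band_amplitudes(series, tr_s, band)
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask] = amps.mean(axis=-1) if amps.shape[-1] else 0.0
    return out


def smooth_volume(
    map3d: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Isotropic Gaussian smoothing; fwhm_mm = 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    map3d = np.asarray(map3d, dtype=np.float64)
    if fwhm_mm == 0:
        return map3d.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(map3d, sigma=sigma_vox)


def estimate_fwhm(
    map3d: np.ndarray, voxel_size_mm: float, mask: np.ndarray | None = None
) -> float:
    """Estimate the smoothness (FWHM, mm) of a field from its lag-1 spatial
    autocorrelation, assuming a Gaussian autocorrelation shape.

    For white noise smoothed with a Gaussian kernel of standard deviation
    sigma, the correlation of voxels at distance d is exp(-d^2/(4 sigma^2));
    inverting at d = 1 voxel gives sigma per axis.  Reported for diagnostic
    purposes; the cluster simulation uses the configured FWHM.
    """
    vol = np.asarray(map3d, dtype=np.float64)
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    fwhms = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        a = vol[tuple(sl_a)][pair_mask]
        b = vol[tuple(sl_b)][pair_mask]
        if a.size < 10:
            continue
        r = np.corrcoef(a, b)[0, 1]
        if not 0 < r < 1:
            continue
        sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(r)))
        fwhms.append(sigma_vox / FWHM_TO_SIGMA * voxel_size_mm)
    if not fwhms:
        return float("nan")
    return float(np.mean(fwhms))
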