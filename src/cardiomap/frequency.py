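"""Activation-frequency estimation via Welch's periodogram.

The activation (dominant) frequency of a signal is the location of the
maximum peak of its power spectral density, with only peaks inside the
0.1-12 Hz physiological band considered.  The PSD uses Welch's method with a
3 s window and 1 s overlap between consecutive windows (segment advance 2 s),
Hann-tapered.  The culture-level statistic is the mean of the per-pixel
dominant frequencies over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import scipy.signal

from .core import CalciumMovie

__all__ = [
    "SpectrumResult",
    "ActivationFrequencyResult",
    "welch_psd",
    "dominant_frequency",
    "mean_activation_frequency",
]

DEFAULT_BAND = (0.1, 12.0)
DEFAULT_WINDOW_S = 3.0
DEFAULT_OVERLAP_S = 1.0


@dataclass
class SpectrumResult:
    """Welch PSD of one signal with its in-band dominant frequency.

    ``dominant_freq`` is None when no in-band peak is defined (flat or
    zero-power spectrum).
    """

    freqs: np.ndarray
    power: np.ndarray
    dominant_freq: Optional[float]
    band: tuple[float, float]


@dataclass
class ActivationFrequencyResult:
    """Culture-level activation frequency.

    ``mean_hz`` is None (undefined) when fewer than ``min_defined_fraction``
    of masked pixels produce an in-band peak.
    """

    mean_hz: Optional[float]
    n_pixels_used: int
    n_pixels_total: int
    per_pixel_hz: Optional[np.ndarray] = None


def _welch(
    x: np.ndarray,
    frame_rate: float,
    window_s: float,
    overlap_s: float,
    axis: int = -1,
) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(window_s * frame_rate))
    noverlap = int(round(overlap_s * frame_rate))
    if x.shape[axis] < nperseg:
        raise ValueError(
            f"signal of {x.shape[axis]} samples shorter than one "
            f"{window_s} s window ({nperseg} samples)"
        )
    return scipy.signal.welch(
        x, fs=frame_rate, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density", axis=axis,
    )


def _band_peak(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]
) -> Optional[float]:
    """Frequency of the maximum in-band PSD bin, or None if undefined."""
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return None
    p = power[in_band]
    if not np.isfinite(p).all() or p.max() <= 0:
        return None
    return float(freqs[in_band][int(np.argmax(p))])


def welch_psd(
    signal: np.ndarray,
    frame_rate: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
    band: tuple[float, float] = DEFAULT_BAND,
) -> SpectrumResult:
    """Welch power spectral density of a 1-D trace with in-band peak pick.

    With density scaling the integral of the PSD matches the signal variance
    (to within window-normalization effects), so absolute power levels are
    comparable across recordings of different lengths.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("welch_psd expects a 1-D signal")
    freqs, power = _welch(signal, frame_rate, window_s, overlap_s)
    dom = None
    if np.ptp(signal) > 0:
        dom = _band_peak(freqs, power, band)
    return SpectrumResult(freqs=freqs, power=power, dominant_freq=dom, band=band)


def dominant_frequency(
    signal: np.ndarray,
    frame_rate: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
    band: tuple[float, float] = DEFAULT_BAND,
) -> Optional[float]:
    """Shortcut for ``welch_psd(...).dominant_freq``."""
    return welch_psd(signal, frame_rate, window_s, overlap_s, band).dominant_freq


def mean_activation_frequency(
    movie: CalciumMovie,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
    band: tuple[float, float] = DEFAULT_BAND,
    method: Literal["pixelwise", "pooled"] = "pixelwise",
    min_defined_fraction: float = 0.10,
    keep_map: bool = False,
) -> ActivationFrequencyResult:
    """Mean activation frequency of the entire culture.

    ``pixelwise`` (default) computes the dominant in-band frequency of every
    masked pixel trace and averages the defined ones; the result is flagged
    undefined when fewer than ``min_defined_fraction`` of masked pixels yield
    a peak.  ``pooled`` instead takes the dominant frequency of the spatially
    averaged trace.
    """
    mask = movie.get_mask()
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("empty mask")
    t = movie.n_frames
    traces = movie.frames.reshape(t, -1)[:, idx]

    if method == "pooled":
        pooled = traces.mean(axis=1)
        dom = dominant_frequency(pooled, movie.frame_rate, window_s, overlap_s, band)
        n_used = idx.size if dom is not None else 0
        return ActivationFrequencyResult(dom, n_used, idx.size)
    if method != "pixelwise":
        raise ValueError(f"unknown method {method!r}")

    freqs, power = _welch(traces, movie.frame_rate, window_s, overlap_s, axis=0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return ActivationFrequencyResult(None, 0, idx.size)
    band_power = power[in_band]  # (n_band_bins, n_pixels)
    band_freqs = freqs[in_band]
    active = (np.ptp(traces, axis=0) > 0) & (band_power.max(axis=0) > 0)
    per_pixel = np.full(idx.size, np.nan)
    if active.any():
        per_pixel[active] = band_freqs[np.argmax(band_power[:, active], axis=0)]
    n_used = int(active.sum())
    mean_hz = None
    if n_used >= min_defined_fraction * idx.size and n_used > 0:
        mean_hz = float(np.nanmean(per_pixel[active]))
    freq_map = None
    if keep_map:
        fm = np.full(mask.shape, np.nan)
        fm.ravel()[idx] = per_pixel
        freq_map = fm
    return ActivationFrequencyResult(mean_hz, n_used, idx.size, per_pixel_hz=freq_map)
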