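"""Phase mapping: per-pixel instantaneous phase of a calcium movie.

Preprocessing detrends and rescales every pixel trace, then the instantaneous
phase is taken as the argument of the temporal analytic signal (Hilbert
quadrature).  This is the parameter-free standard in optical mapping; a
time-delay embedding would introduce an arbitrary delay parameter.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import detrend, hilbert

from .core import CalciumMovie, PhaseMovie

__all__ = ["normalize_movie", "compute_phase"]


def normalize_movie(movie: CalciumMovie) -> CalciumMovie:
    """Linearly detrend each pixel trace and rescale to zero mean, unit SD.

    Pixels whose detrended trace has zero variance (dead or saturated) are
    removed from the mask.  Raises ``ValueError`` when no active pixel
    remains.
    """
    mask = movie.get_mask()
    t, h, w = movie.frames.shape
    flat = movie.frames.reshape(t, h * w)
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("no active pixels: empty mask")
    raw = flat[:, idx]
    traces = detrend(raw, axis=0, type="linear")
    sd = traces.std(axis=0)
    # relative threshold: a constant or purely linear trace leaves only
    # floating-point residue after detrending and counts as dead
    scale = raw.std(axis=0) + np.abs(raw.mean(axis=0))
    active = sd > 1e-8 * scale
    if not active.any():
        raise ValueError("no active pixels: all traces have zero variance")
    out = np.zeros_like(flat)
    out[:, idx[active]] = traces[:, active] / sd[active]
    new_mask = np.zeros(h * w, dtype=bool)
    new_mask[idx[active]] = True
    return CalciumMovie(
        out.reshape(t, h, w), movie.frame_rate, movie.cm_per_pixel,
        mask=new_mask.reshape(h, w),
    )


def compute_phase(movie: CalciumMovie, edge_s: float = 0.5) -> PhaseMovie:
    """Instantaneous phase map via the analytic signal of each pixel trace.

    The movie should already be normalized (`normalize_movie`); the phase of
    the analytic signal is invariant to per-pixel affine intensity rescaling
    of a detrended trace, so strictness here is unnecessary.  The first and
    last ``edge_s`` seconds are retained but flagged lower-confidence
    (``PhaseMovie.edge_frames``) because the Hilbert transform distorts phase
    near the record boundaries.

    Raises ``ValueError`` for movies shorter than 8 frames (analytic signal
    unstable).
    """
    t, h, w = movie.frames.shape
    if t < 8:
        raise ValueError(f"need at least 8 frames for a stable analytic signal, got {t}")
    mask = movie.get_mask()
    flat = movie.frames.reshape(t, h * w)
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("empty mask")
    # remove any residual mean so the analytic signal rotates about the origin
    traces = flat[:, idx] - flat[:, idx].mean(axis=0)
    analytic = hilbert(traces, axis=0)
    ang = np.angle(analytic)
    ang = np.where(ang == -np.pi, np.pi, ang)
    phase = np.full((t, h * w), np.nan)
    phase[:, idx] = ang
    edge_frames = int(round(edge_s * movie.frame_rate))
    return PhaseMovie(
        phase.reshape(t, h, w), movie.frame_rate, movie.cm_per_pixel,
        mask=mask, edge_frames=edge_frames,
    )
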