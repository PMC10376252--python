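"""Core calibrated containers for optical-mapping movies and phase maps.

A :class:`CalciumMovie` is a T x H x W fluorescence stack with the two pieces
of calibration metadata everything downstream depends on: the acquisition
frame rate (Hz) and the pixel pitch (cm/pixel).  A :class:`PhaseMovie` holds
the per-pixel instantaneous phase, in radians wrapped to (-pi, pi], with the
same calibration.  Pixels outside the culture mask are flagged invalid (NaN
for phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["CalciumMovie", "PhaseMovie"]


def _check_calibration(frame_rate: float, cm_per_pixel: float) -> None:
    if not frame_rate > 0:
        raise ValueError(f"frame_rate must be > 0 Hz, got {frame_rate}")
    if not cm_per_pixel > 0:
        raise ValueError(f"cm_per_pixel must be > 0, got {cm_per_pixel}")


def _check_mask(mask: Optional[np.ndarray], frame_shape: tuple[int, int]) -> Optional[np.ndarray]:
    if mask is None:
        return None
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame_shape}"
        )
    return mask


@dataclass
class CalciumMovie:
    """Calibrated fluorescence time series of a cardiac monolayer.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), arbitrary intensity units.
    frame_rate
        Acquisition rate in Hz.
    cm_per_pixel
        Physical pixel pitch in cm.
    mask
        Optional (H, W) boolean culture region; ``None`` means the whole
        field of view is culture.
    """

    frames: np.ndarray
    frame_rate: float
    cm_per_pixel: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (T,H,W), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.frames.shape[1] == 0 or self.frames.shape[2] == 0:
            raise ValueError("zero-area frame shape")
        _check_calibration(self.frame_rate, self.cm_per_pixel)
        self.mask = _check_mask(self.mask, self.frame_shape)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def get_mask(self) -> np.ndarray:
        """Boolean culture mask, materialized to (H, W) even when implicit."""
        if self.mask is None:
            return np.ones(self.frame_shape, dtype=bool)
        return self.mask

    @property
    def area_cm2(self) -> float:
        """Masked culture area in cm^2."""
        return float(self.get_mask().sum()) * self.cm_per_pixel**2

    def with_frames(self, frames: np.ndarray) -> "CalciumMovie":
        return replace(self, frames=frames)


@dataclass
class PhaseMovie:
    """Per-pixel instantaneous phase of a calcium movie.

    ``phase`` is (T, H, W) in radians, wrapped to (-pi, pi]; pixels outside
    ``mask`` are NaN.  ``edge_frames`` marks how many frames at each end of
    the recording carry lower-confidence phase (analytic-signal edge effects).
    """

    phase: np.ndarray
    frame_rate: float
    cm_per_pixel: float
    mask: Optional[np.ndarray] = None
    edge_frames: int = 0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 3:
            raise ValueError("phase must be 3-D (T,H,W)")
        _check_calibration(self.frame_rate, self.cm_per_pixel)
        self.mask = _check_mask(self.mask, self.phase.shape[1:])
        finite = self.phase[np.isfinite(self.phase)]
        if finite.size and (finite.min() <= -np.pi - 1e-9 or finite.max() > np.pi + 1e-9):
            raise ValueError("phase values must lie in (-pi, pi]")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    def get_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.phase.shape[1:], dtype=bool)
        return self.mask

    @property
    def area_cm2(self) -> float:
        return float(self.get_mask().sum()) * self.cm_per_pixel**2

    def interior_frames(self) -> range:
        """Frame indices outside the low-confidence edge windows."""
        lo, hi = self.edge_frames, self.n_frames - self.edge_frames
        if hi <= lo:  # degenerate short movie: fall back to all frames
            return range(self.n_frames)
        return range(lo, hi)
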