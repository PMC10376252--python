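"""Phase-singularity detection by topological charge, and PS/cm^2 density.

A phase singularity (the pivot of a re-entrant spiral wave) is a point around
which the instantaneous phase winds by a full +/-2*pi.  Detection sums the
four wrapped phase differences around every 2x2 pixel loop; a loop whose sum
reaches +/-2*pi (within a small tolerance) encloses a singularity, and the
sign of the sum is its chirality.  Arrhythmia complexity is reported as the
mean number of singularities per frame divided by the masked culture area in
cm^2 (PS/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import skimage.measure
import skimage.transform

from .core import CalciumMovie, PhaseMovie
from .phase import compute_phase, normalize_movie

__all__ = [
    "PhaseSingularity",
    "PSDensityResult",
    "detect_ps_frame",
    "detect_ps_movie",
    "standardize_movie",
    "ps_density",
    "winding_number",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhaseSingularity:
    """One detected rotor core: frame index, loop top-left pixel, chirality.

    Chirality +1 means the phase increases counterclockwise around the core
    (image rows pointing down, the loop traversed right / down / left / up).
    """

    frame: int
    row: int
    col: int
    chirality: int


@dataclass
class PSDensityResult:
    """Per-frame singularity counts and the PS/cm^2 complexity statistic."""

    ps_per_frame: list[int]
    mean_ps_count: float
    area_cm2: float
    ps_density: float
    singularities: list[PhaseSingularity]


def _wrap(d: np.ndarray) -> np.ndarray:
    return (d + np.pi) % TWO_PI - np.pi


def _loop_sums(phase_frame: np.ndarray) -> np.ndarray:
    """Sum of wrapped phase differences around every 2x2 loop, (H-1, W-1).

    Loop order right / down / left / up is counterclockwise in (x=col,
    y=row) coordinates, so a +1 winding means counterclockwise phase
    increase.
    """
    p = phase_frame
    d_top = _wrap(p[:-1, 1:] - p[:-1, :-1])
    d_right = _wrap(p[1:, 1:] - p[:-1, 1:])
    d_bottom = _wrap(p[1:, :-1] - p[1:, 1:])
    d_left = _wrap(p[:-1, :-1] - p[1:, :-1])
    return d_top + d_right + d_bottom + d_left


def detect_ps_frame(
    phase_frame: np.ndarray,
    mask: Optional[np.ndarray] = None,
    tol: float = 0.01,
    merge_radius: int = 1,
    frame: int = 0,
) -> list[PhaseSingularity]:
    """Detect phase singularities in one wrapped phase frame.

    Only 2x2 loops whose four corners all lie inside ``mask`` (and carry
    finite phase) are evaluated.  Adjacent loops reporting the same chirality
    within ``merge_radius`` pixels are merged to a single singularity, since
    discretization can double-report a core that sits on a loop boundary.

    Raises ``ValueError`` if the input is not wrapped to (-pi, pi].
    """
    p = np.asarray(phase_frame, dtype=float)
    finite = np.isfinite(p)
    vals = p[finite]
    if vals.size and (vals.min() <= -np.pi - 1e-9 or vals.max() > np.pi + 1e-9):
        raise ValueError("phase frame must be wrapped to (-pi, pi]")
    if mask is None:
        mask = finite
    else:
        mask = np.asarray(mask, dtype=bool) & finite
    sums = _loop_sums(np.where(mask, p, 0.0))
    valid = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
    hits = valid & (np.abs(sums) >= TWO_PI - tol)
    rows, cols = np.nonzero(hits)
    chis = np.sign(sums[rows, cols]).astype(int)
    detections = sorted(zip(rows.tolist(), cols.tolist(), chis.tolist()))
    kept: list[PhaseSingularity] = []
    for r, c, chi in detections:
        duplicate = any(
            ps.chirality == chi
            and abs(ps.row - r) <= merge_radius
            and abs(ps.col - c) <= merge_radius
            for ps in kept
        )
        if not duplicate:
            kept.append(PhaseSingularity(frame=frame, row=r, col=c, chirality=chi))
    return kept


def detect_ps_movie(
    phase_movie: PhaseMovie,
    tol: float = 0.01,
    merge_radius: int = 1,
    frames: Optional[Sequence[int]] = None,
) -> list[PhaseSingularity]:
    """Run frame-wise detection over a phase movie.

    By default only the interior frames (outside the analytic-signal edge
    windows) are analyzed.
    """
    if frames is None:
        frames = phase_movie.interior_frames()
    mask = phase_movie.get_mask()
    out: list[PhaseSingularity] = []
    for f in frames:
        out.extend(
            detect_ps_frame(
                phase_movie.phase[f], mask=mask, tol=tol,
                merge_radius=merge_radius, frame=f,
            )
        )
    return out


def winding_number(phase_frame: np.ndarray, top: int, left: int, bottom: int, right: int) -> int:
    """Topological charge around the rectangular loop [top:bottom, left:right].

    Sums wrapped phase differences along the border, traversed right / down /
    left / up (counterclockwise in x-y), and divides by 2*pi.
    """
    p = np.asarray(phase_frame, dtype=float)
    path = np.concatenate([
        p[top, left : right + 1],
        p[top : bottom + 1, right][1:],
        p[bottom, left : right + 1][::-1][1:],
        p[top : bottom + 1, left][::-1][1:],
    ])
    total = _wrap(np.diff(np.concatenate([path, path[:1]]))).sum()
    return int(np.round(total / TWO_PI))


def standardize_movie(movie: CalciumMovie, target_shape: tuple[int, int]) -> CalciumMovie:
    """Spatially resample to the standardized analysis format (block average).

    The physical field size is conserved: ``cm_per_pixel`` is rescaled by the
    downsampling factor, which must match between axes to within 0.1% so the
    pixel pitch stays isotropic.
    """
    th, tw = target_shape
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    t, h, w = movie.frames.shape
    if th > h or tw > w:
        raise ValueError(f"target shape {target_shape} exceeds native shape {(h, w)}")
    fy, fx = h / th, w / tw
    if abs(fy - fx) > 1e-3 * fx:
        raise ValueError(f"anisotropic resampling factors {fy:.4f} vs {fx:.4f}")
    if h % th == 0 and w % tw == 0:
        by, bx = h // th, w // tw
        frames = skimage.measure.block_reduce(
            movie.frames, block_size=(1, by, bx), func=np.mean
        )
        mask = movie.mask
        if mask is not None:
            mask = skimage.measure.block_reduce(
                mask.astype(float), block_size=(by, bx), func=np.mean
            ) >= 0.5
    else:
        frames = np.stack([
            skimage.transform.resize(
                fr, (th, tw), order=1, anti_aliasing=True, preserve_range=True
            )
            for fr in movie.frames
        ])
        mask = movie.mask
        if mask is not None:
            mask = skimage.transform.resize(
                mask.astype(float), (th, tw), order=1, preserve_range=True
            ) >= 0.5
    return CalciumMovie(frames, movie.frame_rate, movie.cm_per_pixel * fx, mask=mask)


def ps_density(
    movie: CalciumMovie,
    tol: float = 0.01,
    merge_radius: int = 1,
    aggregate: Literal["mean", "max"] = "mean",
    normalized: bool = False,
) -> PSDensityResult:
    """Arrhythmia complexity of a movie as phase singularities per cm^2.

    The movie is normalized, phase-mapped, and singularities are detected on
    every interior frame; the per-frame counts are aggregated (time average
    by default, per-frame maximum as an alternative) and divided by the
    masked culture area.
    """
    if not normalized:
        movie = normalize_movie(movie)
    pm = compute_phase(movie)
    area = pm.area_cm2
    if area <= 0:
        raise ValueError("zero masked area")
    frames = list(pm.interior_frames())
    singularities = detect_ps_movie(pm, tol=tol, merge_radius=merge_radius, frames=frames)
    counts = {f: 0 for f in frames}
    for ps in singularities:
        counts[ps.frame] += 1
    per_frame = [counts[f] for f in frames]
    if aggregate == "mean":
        agg = float(np.mean(per_frame))
    elif aggregate == "max":
        agg = float(np.max(per_frame))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return PSDensityResult(
        ps_per_frame=per_frame,
        mean_ps_count=agg,
        area_cm2=area,
        ps_density=agg / area,
        singularities=singularities,
    )
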