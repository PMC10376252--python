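"""File formats: calibrated TIFF movies with plain-text sidecar metadata,
phase movies quantized to 16-bit, manifests and metric tables as CSV.

A movie is stored as a multi-page TIFF (one page per frame) next to a JSON
sidecar ``<name>.meta.json`` holding ``frame_rate`` (Hz) and
``cm_per_pixel``; an optional mask lives in ``<name>.mask.tif``.  Missing
calibration is a hard error — downstream statistics are physical quantities
and silent defaults would corrupt them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import CalciumMovie, PhaseMovie

__all__ = [
    "write_movie",
    "read_movie",
    "write_phase",
    "read_phase",
    "read_image",
    "write_image",
    "read_manifest",
    "write_manifest",
]

_REQUIRED_KEYS = ("frame_rate", "cm_per_pixel")


def _sidecar_path(path: Path, metadata_path: Optional[Path]) -> Path:
    return Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")


def _mask_path(path: Path) -> Path:
    return path.with_suffix(".mask.tif")


def write_movie(
    movie: CalciumMovie, path: str | Path, metadata_path: Optional[str | Path] = None
) -> Path:
    """Write a movie as multi-page float32 TIFF + JSON sidecar (+ mask TIFF)."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {"frame_rate": movie.frame_rate, "cm_per_pixel": movie.cm_per_pixel}
    _sidecar_path(path, metadata_path).write_text(json.dumps(meta, indent=2) + "\n")
    if movie.mask is not None:
        tifffile.imwrite(_mask_path(path), movie.mask.astype(np.uint8))
    return path


def read_movie(
    path: str | Path,
    metadata_path: Optional[str | Path] = None,
    mask_path: Optional[str | Path] = None,
) -> CalciumMovie:
    """Read a calibrated movie; raises naming any missing metadata key."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path, metadata_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise KeyError(f"metadata file {sidecar} is missing required key '{key}'")
    mask = None
    mpath = Path(mask_path) if mask_path else _mask_path(path)
    if mpath.exists():
        mask = tifffile.imread(mpath).astype(bool)
    return CalciumMovie(
        np.asarray(frames, dtype=np.float64),
        frame_rate=float(meta["frame_rate"]),
        cm_per_pixel=float(meta["cm_per_pixel"]),
        mask=mask,
    )


_PHASE_SCALE = 65535 / (2 * np.pi)


def write_phase(pm: PhaseMovie, path: str | Path) -> Path:
    """Write a phase movie as 16-bit TIFF, phase linearly mapped from
    (-pi, pi] onto 1..65535 (0 reserved for invalid pixels)."""
    path = Path(path)
    scaled = np.where(
        np.isfinite(pm.phase),
        np.clip(np.round((pm.phase + np.pi) * _PHASE_SCALE), 1, 65535),
        0,
    ).astype(np.uint16)
    tifffile.imwrite(path, scaled)
    meta = {
        "frame_rate": pm.frame_rate,
        "cm_per_pixel": pm.cm_per_pixel,
        "edge_frames": pm.edge_frames,
        "encoding": "phase = value / 65535 * 2*pi - pi; 0 = invalid",
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    if pm.mask is not None:
        tifffile.imwrite(_mask_path(path), pm.mask.astype(np.uint8))
    return path


def read_phase(path: str | Path) -> PhaseMovie:
    path = Path(path)
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    phase = raw.astype(np.float64) / _PHASE_SCALE - np.pi
    phase[raw == 0] = np.nan
    phase = np.clip(phase, -np.pi + 1e-12, np.pi)
    mask = None
    if _mask_path(path).exists():
        mask = tifffile.imread(_mask_path(path)).astype(bool)
    return PhaseMovie(
        phase, float(meta["frame_rate"]), float(meta["cm_per_pixel"]),
        mask=mask, edge_frames=int(meta.get("edge_frames", 0)),
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG image as a 2-D float array."""
    img = iio.imread(Path(path))
    img = np.asarray(img)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    return img.astype(np.float64)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, np.asarray(image))
    return path


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"line", "condition", "n_videos", "n_batches"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df
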