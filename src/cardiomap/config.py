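"""Pipeline configuration: every analysis constant surfaced as a default.

The config is a plain-text YAML key-value file so sensitivity analyses are
scriptable; nothing downstream hard-codes a threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Analysis parameters for the optical-mapping pipeline.

    standardized_shape : target (H, W) for spatial standardization; movies
        already at or below this size are analyzed natively.
    welch_window_s / welch_overlap_s : Welch segmentation (3 s windows,
        1 s overlap between consecutive windows).
    freq_band_hz : candidate band for the activation frequency (0.1-12 Hz).
    ps_tol_rad : tolerance on |winding sum| vs 2*pi in PS detection.
    oa_gate / ta_gate : ((min_area, max_area) um^2, (min_circ, max_circ))
        particle gates for organized and total sarcomeric area.
    """

    standardized_shape: tuple[int, int] = (512, 512)
    welch_window_s: float = 3.0
    welch_overlap_s: float = 1.0
    freq_band_hz: tuple[float, float] = (0.1, 12.0)
    ps_tol_rad: float = 0.01
    ps_aggregate: str = "mean"
    oa_gate: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 40.0), (0.0, 0.80))
    ta_gate: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 40.0), (0.0, 1.00))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.welch_overlap_s < self.welch_window_s:
            raise ValueError("welch_overlap_s must be smaller than welch_window_s")
        lo, hi = self.freq_band_hz
        if not lo < hi:
            raise ValueError("freq_band_hz must satisfy min < max")
        for gate in (self.oa_gate, self.ta_gate):
            (amin, amax), (cmin, cmax) = gate
            if amin > amax or cmin > cmax:
                raise ValueError(f"invalid particle gate {gate}")
        h, w = self.standardized_shape
        if h <= 0 or w <= 0:
            raise ValueError("standardized_shape must be positive")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("standardized_shape", "freq_band_hz"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("oa_gate", "ta_gate"):
            if key in data:
                data[key] = tuple(tuple(part) for part in data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Short stable digest identifying the parameter set in outputs."""
        blob = yaml.safe_dump(_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
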