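"""Ground-truth-known synthetic inputs for every pipeline stage.

Three generators:

* spiral-wave ("rotor") calcium movies with a controlled number of stable
  phase singularities, controlled chirality and rotation frequency;
* paced planar-wave movies with zero rotors and a known activation frequency;
* striated alpha-actinin-like images whose fraction of disordered area is
  known exactly, by pixel bookkeeping, at generation time.

The rotor phase model is kinematic (Archimedean-spiral phase), not a
reaction-diffusion simulation: the analytic phase field is written down in
closed form, so the true singularity positions and chiralities are exact in
every frame.  The instantaneous phase of pixel (r, c) at time t is

    phi(r, c, t) = 2*pi*f*t + sum_k chi_k * atan2(r - r_k, c - c_k)
                   - 2*pi * d_min / wavelength

where chi_k = +/-1 is rotor chirality, (r_k, c_k) the rotor core, and d_min
the distance to the nearest core (the radial term shapes the spiral arms and
contributes no winding).  The recorded signal is a positive-offset cosine of
this phase plus optional i.i.d. Gaussian noise; the analytic signal of each
pixel trace therefore recovers phi up to edge effects, and the winding
number of phi around core k equals chi_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CalciumMovie

__all__ = [
    "SpiralSpec",
    "SarcomereImageSpec",
    "SyntheticSarcomereImage",
    "make_spiral_movie",
    "make_paced_movie",
    "analytic_phase_field",
    "make_sarcomere_image",
    "make_manifest_fixture",
    "make_cohort",
]

#: Default fixture calibration: a 128 x 128 field covering exactly 1 cm^2 at
#: 50 Hz, so PS/cm^2 equals the raw PS count.
DEFAULT_SHAPE = (128, 128)
DEFAULT_CM_PER_PIXEL = 1.0 / 128.0
DEFAULT_FRAME_RATE = 50.0

_SIGNAL_OFFSET = 500.0
_SIGNAL_AMPLITUDE = 400.0


@dataclass
class SpiralSpec:
    """Ground-truth description of a spiral-wave movie.

    ``n_rotors = 0`` selects the planar-wave fallback (zero singularities).
    ``noise_sd`` is expressed as a fraction of the signal amplitude.
    """

    n_rotors: int
    chiralities: Sequence[int] = ()
    core_positions: Sequence[tuple[float, float]] = ()
    rotation_freq: float = 2.0
    wavelength: float = 32.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.chiralities = tuple(int(c) for c in self.chiralities)
        self.core_positions = tuple((float(r), float(c)) for r, c in self.core_positions)
        if self.n_rotors < 0:
            raise ValueError("n_rotors must be >= 0")
        if len(self.chiralities) != self.n_rotors or len(self.core_positions) != self.n_rotors:
            raise ValueError(
                "chiralities and core_positions must each have n_rotors entries"
            )
        if any(c not in (-1, 1) for c in self.chiralities):
            raise ValueError("chiralities must be +1 or -1")
        if not self.rotation_freq > 0:
            raise ValueError("rotation_freq must be > 0 Hz")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _spiral_spatial_phase(spec: SpiralSpec, shape: tuple[int, int]) -> np.ndarray:
    """Time-independent part of the spiral phase field (unwrapped, H x W)."""
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("zero-area shape")
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    if spec.n_rotors == 0:
        # planar wave travelling along +col: no winding anywhere
        return -2.0 * np.pi * cc / spec.wavelength
    for r0, c0 in spec.core_positions:
        if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
            raise ValueError(f"rotor core ({r0}, {c0}) outside image of shape {shape}")
    spatial = np.zeros((h, w))
    d_min = np.full((h, w), np.inf)
    for chi, (r0, c0) in zip(spec.chiralities, spec.core_positions):
        spatial += chi * np.arctan2(rr - r0, cc - c0)
        d_min = np.minimum(d_min, np.hypot(rr - r0, cc - c0))
    spatial -= 2.0 * np.pi * d_min / spec.wavelength
    return spatial


def analytic_phase_field(
    spec: SpiralSpec, shape: tuple[int, int], times: np.ndarray
) -> np.ndarray:
    """Exact wrapped phase (T, H, W) of the generated movie, noise-free.

    This is the construction's ground truth: winding the returned field
    around rotor core k gives exactly ``spec.chiralities[k]`` in every frame.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    spatial = _spiral_spatial_phase(spec, shape)
    phi = 2.0 * np.pi * spec.rotation_freq * times[:, None, None] + spatial[None]
    return wrap_phase(phi)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = (phi + np.pi) % (2.0 * np.pi) - np.pi
    # map the half-open boundary -pi back to +pi
    return np.where(out == -np.pi, np.pi, out)


def make_spiral_movie(
    spec: SpiralSpec,
    duration_s: float = 8.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    cm_per_pixel: float = DEFAULT_CM_PER_PIXEL,
) -> CalciumMovie:
    """Render a fibrillation-like calcium movie with ``spec.n_rotors`` rotors.

    Deterministic given ``spec.seed``.  The noiseless per-pixel signal is a
    positive-offset cosine of the analytic spiral phase; Gaussian noise with
    sd = ``noise_sd * amplitude`` is added per pixel-frame.
    """
    n_frames = int(round(duration_s * frame_rate))
    if n_frames < 2:
        raise ValueError("duration_s * frame_rate must give at least 2 frames")
    times = np.arange(n_frames) / frame_rate
    spatial = _spiral_spatial_phase(spec, shape)
    phi = 2.0 * np.pi * spec.rotation_freq * times[:, None, None] + spatial[None]
    frames = _SIGNAL_OFFSET + _SIGNAL_AMPLITUDE * np.cos(phi)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(
            0.0, spec.noise_sd * _SIGNAL_AMPLITUDE, size=frames.shape
        )
    return CalciumMovie(frames, frame_rate, cm_per_pixel)


def make_paced_movie(
    f0: float,
    duration_s: float = 30.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    cm_per_pixel: float = DEFAULT_CM_PER_PIXEL,
    wavelength: Optional[float] = None,
    noise_sd: float = 0.0,
    drift_freq: Optional[float] = None,
    drift_amplitude: float = 0.0,
    seed: int = 0,
) -> CalciumMovie:
    """Planar traveling wave paced at ``f0`` Hz: every pixel periodic, zero rotors.

    ``drift_freq``/``drift_amplitude`` add a slow sinusoidal baseline
    component (e.g. 0.05 Hz) used to exercise the 0.1-12 Hz band rule.
    """
    if not (0.0 < f0 < frame_rate / 2.0):
        raise ValueError(f"f0 = {f0} Hz outside (0, frame_rate/2)")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("zero-area shape")
    if wavelength is None:
        wavelength = float(w)
    n_frames = int(round(duration_s * frame_rate))
    if n_frames < 2:
        raise ValueError("duration_s * frame_rate must give at least 2 frames")
    times = np.arange(n_frames) / frame_rate
    cc = np.arange(w, dtype=float)
    phi = (
        2.0 * np.pi * f0 * times[:, None, None]
        - 2.0 * np.pi * cc[None, None, :] / wavelength
    )
    frames = _SIGNAL_OFFSET + _SIGNAL_AMPLITUDE * np.cos(np.broadcast_to(phi, (n_frames, h, w)).copy())
    if drift_freq is not None and drift_amplitude > 0:
        drift = drift_amplitude * _SIGNAL_AMPLITUDE * np.cos(
            2.0 * np.pi * drift_freq * times
        )
        frames = frames + drift[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd * _SIGNAL_AMPLITUDE, size=frames.shape)
    return CalciumMovie(frames, frame_rate, cm_per_pixel)


# ---------------------------------------------------------------------------
# sarcomere images
# ---------------------------------------------------------------------------


@dataclass
class SarcomereImageSpec:
    """Geometry (in micrometres) of a synthetic striation image.

    Defaults place single Z-disc footprints (1 x 6 um = 6 um^2 at
    0.2 um/pixel) inside the 5-40 um^2 organized-area particle gate, and
    disordered blobs (discs, circularity ~1) inside the total-area gate but
    outside the organized one.
    """

    z_disc_spacing: float = 2.0
    z_disc_width: float = 1.0
    z_disc_length: float = 6.0
    disordered_fraction: float = 0.0
    um_per_pixel: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.z_disc_spacing > self.z_disc_width > 0:
            raise ValueError("need z_disc_spacing > z_disc_width > 0")
        if not 0.0 <= self.disordered_fraction <= 1.0:
            raise ValueError("disordered_fraction must lie in [0, 1]")
        if not self.um_per_pixel > 0:
            raise ValueError("um_per_pixel must be > 0")


@dataclass
class SyntheticSarcomereImage:
    """A generated striation image plus its exact area bookkeeping.

    ``expected_score_pct`` is the disorganization percentage implied by the
    generator's own pixel counts: drawn disordered area over total drawn
    area, times 100 (NaN when nothing was drawn).
    """

    image: np.ndarray
    um_per_pixel: float
    organized_area_um2: float
    disordered_area_um2: float
    band_mask: np.ndarray

    @property
    def expected_score_pct(self) -> float:
        total = self.organized_area_um2 + self.disordered_area_um2
        if total == 0:
            return float("nan")
        return 100.0 * self.disordered_area_um2 / total


def _rect_gate_check(spec: SarcomereImageSpec) -> None:
    """Fail fast if a single Z-disc footprint falls outside the OA gate."""
    area_um2 = spec.z_disc_width * spec.z_disc_length
    if not 5.0 <= area_um2 <= 40.0:
        raise ValueError(
            f"Z-disc footprint {area_um2:.2f} um^2 outside the 5-40 um^2 organized gate"
        )
    perimeter = 2.0 * (spec.z_disc_width + spec.z_disc_length)
    circularity = 4.0 * np.pi * area_um2 / perimeter**2
    if circularity > 0.80:
        raise ValueError(
            f"Z-disc circularity {circularity:.2f} exceeds the 0.80 organized gate"
        )


def make_sarcomere_image(
    spec: SarcomereImageSpec, shape: tuple[int, int] = (512, 512)
) -> SyntheticSarcomereImage:
    """Draw a striated image with a known disordered-area fraction.

    The field is divided into square tiles.  An ordered tile carries parallel
    elongated Z-disc bands at ``z_disc_spacing``; a disordered tile carries
    three well-separated near-circular blobs whose total area roughly matches
    one ordered tile, so the downstream (1 - OA/TA)*100 score tracks
    ``disordered_fraction``.  Exactly round(fraction * n_tiles) tiles are
    disordered, chosen by the seeded RNG; output is deterministic given seed.
    """
    _rect_gate_check(spec)
    h, w = shape
    upp = spec.um_per_pixel
    band_w = max(1, int(round(spec.z_disc_width / upp)))
    band_l = max(1, int(round(spec.z_disc_length / upp)))
    pitch = max(band_w + 2, int(round(spec.z_disc_spacing / upp)))
    tile = 4 * pitch  # four bands per ordered tile
    if h < tile or w < tile:
        raise ValueError(f"shape {shape} too small for tile size {tile}")
    blob_r = max(2, int(round(1.6 / upp * 1.0)))  # 1.6 um radius blobs

    rng = np.random.default_rng(spec.seed)
    n_ty, n_tx = h // tile, w // tile
    n_tiles = n_ty * n_tx
    n_dis = int(round(spec.disordered_fraction * n_tiles))
    disordered_tiles = set(
        rng.choice(n_tiles, size=n_dis, replace=False).tolist()
    )

    canvas = np.zeros((h, w), dtype=bool)
    band_mask = np.zeros((h, w), dtype=bool)
    organized_px = 0
    disordered_px = 0

    y0_band = (tile - band_l) // 2
    for ti in range(n_tiles):
        ty, tx = divmod(ti, n_tx)
        oy, ox = ty * tile, tx * tile
        if ti in disordered_tiles:
            # three blobs on a fixed triangle, jittered by at most 1 px so
            # they can never merge (centre spacing >= 2r + 1)
            centres = np.array([[tile // 4, tile // 4],
                                [tile // 4, 3 * tile // 4],
                                [3 * tile // 4, tile // 2]], dtype=float)
            centres += rng.integers(-1, 2, size=centres.shape)
            yy, xx = np.mgrid[0:tile, 0:tile]
            for cy, cx in centres:
                blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_r**2
                canvas[oy : oy + tile, ox : ox + tile] |= blob
            disordered_px += int(canvas[oy : oy + tile, ox : ox + tile].sum())
        else:
            for b in range(4):
                x0 = ox + b * pitch + (pitch - band_w) // 2
                sl = np.s_[oy + y0_band : oy + y0_band + band_l, x0 : x0 + band_w]
                canvas[sl] = True
                band_mask[sl] = True
                organized_px += band_l * band_w

    background = 100.0
    foreground = 800.0
    img = np.where(canvas, foreground, background)
    img = img + rng.normal(0.0, 15.0, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    return SyntheticSarcomereImage(
        image=img,
        um_per_pixel=upp,
        organized_area_um2=organized_px * upp**2,
        disordered_area_um2=disordered_px * upp**2,
        band_mask=band_mask,
    )


# ---------------------------------------------------------------------------
# recording manifest and synthetic cohort
# ---------------------------------------------------------------------------

LINES = ("CTRL1", "CTRL2", "CTX1", "CTX2")
CONDITIONS = ("No DOX", "DOX")

# Per-cell video counts reconciled against every published marginal: row
# totals 42 (basal) and 36 (DOX), per-line totals 14/15/23/26, grand total 78
# videos from 30 differentiation batches (2.6 videos per batch).
_VIDEO_COUNTS = {"No DOX": (9, 8, 12, 13), "DOX": (5, 7, 11, 13)}
_BATCH_COUNTS = {"No DOX": (3, 4, 4, 5), "DOX": (3, 3, 3, 5)}


def make_manifest_fixture() -> pd.DataFrame:
    """Recording manifest of the study cohort: videos and differentiation
    batches per cell line (two control, two cardiotoxicity) and condition
    (basal vs doxorubicin)."""
    rows = []
    for cond in CONDITIONS:
        for line, n_vid, n_batch in zip(LINES, _VIDEO_COUNTS[cond], _BATCH_COUNTS[cond]):
            rows.append(
                {"line": line, "condition": cond, "n_videos": n_vid, "n_batches": n_batch}
            )
    return pd.DataFrame(rows, columns=["line", "condition", "n_videos", "n_batches"])


def video_id(line: str, condition: str, index: int) -> str:
    cond_token = "noDOX" if condition == "No DOX" else "DOX"
    return f"{line}_{cond_token}_{index:02d}"


def _cohort_rotor_spec(
    line: str, condition: str, n_rotors: int, shape: tuple[int, int], rng: np.random.Generator
) -> SpiralSpec:
    h, w = shape
    anchors = [(0.3, 0.3), (0.3, 0.7), (0.7, 0.35), (0.7, 0.75)]
    cores = []
    chis = []
    for k in range(n_rotors):
        ar, ac = anchors[k % len(anchors)]
        jitter = rng.uniform(-0.05, 0.05, size=2)
        cores.append(((ar + jitter[0]) * (h - 1), (ac + jitter[1]) * (w - 1)))
        chis.append(1 if k % 2 == 0 else -1)
    return SpiralSpec(
        n_rotors=n_rotors,
        chiralities=chis,
        core_positions=cores,
        rotation_freq=float(rng.uniform(1.8, 2.2)),
        wavelength=20.0,
        noise_sd=0.05,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_cohort(
    manifest: pd.DataFrame,
    out_dir: str | Path,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    duration_s: float = 7.0,
    frame_rate: float = 40.0,
    ctx_dox_rotors: int = 4,
) -> pd.DataFrame:
    """Write a synthetic optical-mapping cohort matching a manifest.

    Control lines carry one rotor under both conditions; cardiotoxicity (CTX)
    lines carry one rotor at baseline and ``ctx_dox_rotors`` rotors under
    doxorubicin — a constructed DOX effect restricted to the CTX lines.
    Returns a table (video_id, line, condition, path) of the movies written.
    """
    from . import io as cio  # local import: io imports core only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cm_per_pixel = 1.0 / shape[1]  # 1 cm wide field
    rows = []
    for _, mrow in manifest.iterrows():
        line, cond = mrow["line"], mrow["condition"]
        n_rotors = ctx_dox_rotors if (line.startswith("CTX") and cond == "DOX") else 1
        for i in range(int(mrow["n_videos"])):
            spec = _cohort_rotor_spec(line, cond, n_rotors, shape, rng)
            movie = make_spiral_movie(
                spec, duration_s=duration_s, frame_rate=frame_rate,
                shape=shape, cm_per_pixel=cm_per_pixel,
            )
            vid = video_id(line, cond, i)
            path = out_dir / f"{vid}.tif"
            cio.write_movie(movie, path)
            rows.append({"video_id": vid, "line": line, "condition": cond, "path": str(path)})
    return pd.DataFrame(rows)
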