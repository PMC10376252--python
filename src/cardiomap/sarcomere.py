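"""Sarcomere disorganization scoring from alpha-actinin immunofluorescence.

Z-discs of organized myofibrils show up as regularly spaced elongated bands
in sarcomeric alpha-actinin staining.  The image is binarized with an
automatic histogram threshold, connected particles are measured (area in
um^2 and circularity 4*pi*area/perimeter^2), and two gated areas are
accumulated:

* OA (organized area): particles of 5-40 um^2 with circularity 0.00-0.80,
  i.e. elongated band-like footprints of regularly spaced Z-discs;
* TA (total area): particles of 0-40 um^2 with circularity 0.00-1.00.

The disorganization percentage is (1 - OA/TA) * 100; higher means more of
the stained area is made of irregular, rounded or fragmented material.
Pixel calibration (um/pixel) is mandatory: the gates are physical areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import skimage.filters
import skimage.measure
import skimage.segmentation

__all__ = [
    "BinaryImage",
    "Particle",
    "ParticleSet",
    "DisorganizationResult",
    "binarize",
    "analyze_particles",
    "disorganization_score",
    "OA_GATE",
    "TA_GATE",
]

#: (size range um^2, circularity range) of the organized-area particle gate
OA_GATE = ((5.0, 40.0), (0.0, 0.80))
#: gate of the total sarcomeric area
TA_GATE = ((0.0, 40.0), (0.0, 1.00))


@dataclass
class BinaryImage:
    """Binarized staining image; foreground pixels are particles."""

    pixels: np.ndarray
    um_per_pixel: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("binary image must be 2-D")
        if not self.um_per_pixel > 0:
            raise ValueError("um_per_pixel must be > 0")


@dataclass(frozen=True)
class Particle:
    label: int
    area_um2: float
    perimeter_um: float
    circularity: float


@dataclass
class ParticleSet:
    particles: list[Particle]

    @property
    def total_area_um2(self) -> float:
        return float(sum(p.area_um2 for p in self.particles))

    def __len__(self) -> int:
        return len(self.particles)


@dataclass
class DisorganizationResult:
    """OA/TA areas and the disorganization percentage.

    ``score_pct`` is None when TA = 0 (no particles: score undefined).
    """

    OA_um2: float
    TA_um2: float
    score_pct: Optional[float]
    n_particles_OA: int
    n_particles_TA: int


def binarize(image: np.ndarray, um_per_pixel: float, invert: bool = False) -> BinaryImage:
    """Threshold a grayscale staining image into particles vs background.

    Uses the IsoData automatic histogram threshold; foreground is the bright
    side unless ``invert`` is set (for stains rendered dark on light).
    Raises ``ValueError`` on a constant image (no threshold exists).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.ptp(img) == 0:
        raise ValueError("no threshold: image is constant")
    thr = skimage.filters.threshold_isodata(img)
    fg = img <= thr if invert else img > thr
    return BinaryImage(fg, um_per_pixel)


def analyze_particles(
    binary: BinaryImage,
    size_range: tuple[float, float],
    circ_range: tuple[float, float],
    connectivity: int = 2,
    exclude_edges: bool = False,
) -> ParticleSet:
    """Measure connected particles and keep those inside both gates.

    Particles are 8-connected components by default (``connectivity=2``);
    area and perimeter are converted to um using the image calibration, and
    circularity is 4*pi*area/perimeter^2 with a Crofton perimeter estimate,
    clipped to 1 (single-pixel particles score 1).  An empty binary image
    yields an empty set, not an error.
    """
    if size_range[0] > size_range[1] or circ_range[0] > circ_range[1]:
        raise ValueError("gate ranges must satisfy min <= max")
    labels = skimage.measure.label(binary.pixels, connectivity=connectivity)
    if exclude_edges:
        labels = skimage.segmentation.clear_border(labels)
    upp = binary.um_per_pixel
    kept: list[Particle] = []
    for rp in skimage.measure.regionprops(labels):
        area = rp.area * upp**2
        perim = rp.perimeter_crofton * upp
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        if size_range[0] <= area <= size_range[1] and circ_range[0] <= circ <= circ_range[1]:
            kept.append(Particle(rp.label, float(area), float(perim), float(circ)))
    return ParticleSet(kept)


def disorganization_score(
    image: np.ndarray,
    um_per_pixel: float,
    oa_gate: tuple[tuple[float, float], tuple[float, float]] = OA_GATE,
    ta_gate: tuple[tuple[float, float], tuple[float, float]] = TA_GATE,
    invert: bool = False,
    connectivity: int = 2,
    exclude_edges: bool = False,
) -> DisorganizationResult:
    """Sarcomere disorganization percentage (1 - OA/TA) * 100 of one image."""
    binary = binarize(image, um_per_pixel, invert=invert)
    oa = analyze_particles(binary, *oa_gate, connectivity=connectivity,
                           exclude_edges=exclude_edges)
    ta = analyze_particles(binary, *ta_gate, connectivity=connectivity,
                           exclude_edges=exclude_edges)
    oa_area, ta_area = oa.total_area_um2, ta.total_area_um2
    if oa_area > ta_area + 1e-9:
        # cannot happen with the default gates (OA gate is a subset of TA's)
        raise ValueError("OA gate is not contained in TA gate")
    if ta_area == 0:
        return DisorganizationResult(0.0, 0.0, None, 0, 0)
    score = (1.0 - oa_area / ta_area) * 100.0
    score = float(min(100.0, max(0.0, score)))
    return DisorganizationResult(oa_area, ta_area, score, len(oa), len(ta))
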