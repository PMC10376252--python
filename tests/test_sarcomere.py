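"""Binarization, gated particle morphometry, disorganization score."""

import numpy as np
import pytest
import skimage.transform

from cardiomap.sarcomere import (
    OA_GATE,
    TA_GATE,
    BinaryImage,
    analyze_particles,
    binarize,
    disorganization_score,
)
from cardiomap.synthetic import SarcomereImageSpec, make_sarcomere_image

UPP = 0.2  # um per pixel


def _two_level(bands_value=200.0, background=10.0):
    img = np.full((64, 64), background)
    img[10:40, 10:15] = bands_value
    img[10:40, 25:30] = bands_value
    return img


def test_binarize_recovers_bands_exactly():
    img = _two_level()
    binary = binarize(img, UPP)
    np.testing.assert_array_equal(binary.pixels, img > 10.0)


def test_binarize_polarity_flag():
    img = _two_level()
    inverted = img.max() + img.min() - img
    np.testing.assert_array_equal(
        binarize(img, UPP).pixels, binarize(inverted, UPP, invert=True).pixels
    )


def test_binarize_rejects_constant_image():
    with pytest.raises(ValueError, match="no threshold"):
        binarize(np.full((16, 16), 3.0), UPP)


def test_binarize_noisy_fixture_jaccard():
    gen = make_sarcomere_image(SarcomereImageSpec(disordered_fraction=0.0, seed=5))
    fg = binarize(gen.image, gen.um_per_pixel).pixels
    truth = gen.band_mask
    jaccard = (fg & truth).sum() / (fg | truth).sum()
    assert jaccard >= 0.9


def _single_particle_image(mask):
    return BinaryImage(mask, UPP)


def test_elongated_band_passes_oa_gate():
    # 5 x 50 px at 0.2 um/px -> 10 um^2, circularity ~0.3
    mask = np.zeros((80, 80), dtype=bool)
    mask[10:60, 10:15] = True
    ps = analyze_particles(_single_particle_image(mask), *OA_GATE)
    assert len(ps) == 1
    assert ps.particles[0].area_um2 == pytest.approx(10.0)
    assert ps.particles[0].circularity <= 0.80


def test_disc_rejected_by_oa_kept_by_ta():
    # ~10 um^2 disc: circularity close to 1
    yy, xx = np.mgrid[0:80, 0:80]
    mask = (yy - 40) ** 2 + (xx - 40) ** 2 <= 9**2  # r=1.8um -> ~10.2 um^2
    assert len(analyze_particles(_single_particle_image(mask), *OA_GATE)) == 0
    ta = analyze_particles(_single_particle_image(mask), *TA_GATE)
    assert len(ta) == 1
    assert ta.particles[0].circularity > 0.80


def test_oversized_particle_rejected_by_both_gates():
    mask = np.zeros((120, 120), dtype=bool)
    mask[10:110, 10:23] = True  # 100 x 13 px = 52 um^2
    assert len(analyze_particles(_single_particle_image(mask), *OA_GATE)) == 0
    assert len(analyze_particles(_single_particle_image(mask), *TA_GATE)) == 0


def test_empty_binary_image_gives_empty_set():
    ps = analyze_particles(_single_particle_image(np.zeros((8, 8), dtype=bool)), *TA_GATE)
    assert len(ps) == 0 and ps.total_area_um2 == 0.0


def test_score_endpoints():
    ordered = make_sarcomere_image(SarcomereImageSpec(disordered_fraction=0.0, seed=1))
    disordered = make_sarcomere_image(SarcomereImageSpec(disordered_fraction=1.0, seed=1))
    s0 = disorganization_score(ordered.image, ordered.um_per_pixel)
    s1 = disorganization_score(disordered.image, disordered.um_per_pixel)
    assert s0.score_pct < 5.0
    assert s1.score_pct > 95.0


def test_score_midpoint_matches_generator_bookkeeping(sarcomere_half):
    res = disorganization_score(sarcomere_half.image, sarcomere_half.um_per_pixel)
    assert res.score_pct == pytest.approx(sarcomere_half.expected_score_pct, abs=10.0)
    assert res.OA_um2 <= res.TA_um2


def test_score_monotone_in_disorder():
    scores = []
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        gen = make_sarcomere_image(SarcomereImageSpec(disordered_fraction=frac, seed=2))
        scores.append(disorganization_score(gen.image, gen.um_per_pixel).score_pct)
    assert all(a <= b for a, b in zip(scores, scores[1:]))


def test_score_invariant_under_rotation_and_intensity_scaling(sarcomere_half):
    img = sarcomere_half.image.astype(float)
    base = disorganization_score(img, UPP).score_pct
    rotated = disorganization_score(np.rot90(img), UPP).score_pct
    scaled = disorganization_score(0.5 * img, UPP).score_pct
    assert rotated == pytest.approx(base, abs=1e-9)
    assert scaled == pytest.approx(base, abs=1.0)


def test_no_particles_flagged_undefined():
    # a faint gradient binarizes, but every particle is a giant slab
    img = np.zeros((64, 64))
    img[:32] = 100.0
    res = disorganization_score(img, 1.0)  # 32x64 px = 2048 um^2 >> gates
    assert res.score_pct is None
    assert res.n_particles_TA == 0
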