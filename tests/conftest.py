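import numpy as np
import pytest

from cardiomap.synthetic import (
    SarcomereImageSpec,
    SpiralSpec,
    make_paced_movie,
    make_spiral_movie,
)


@pytest.fixture(scope="session")
def one_rotor_spec():
    return SpiralSpec(n_rotors=1, chiralities=[1], core_positions=[(64.0, 64.0)],
                      rotation_freq=2.0, wavelength=32.0)


@pytest.fixture(scope="session")
def one_rotor_movie(one_rotor_spec):
    """Noiseless single counterclockwise rotor, 1 cm^2 field, 8 s @ 50 Hz."""
    return make_spiral_movie(one_rotor_spec, duration_s=8.0)


@pytest.fixture(scope="session")
def two_rotor_spec():
    return SpiralSpec(n_rotors=2, chiralities=[1, -1],
                      core_positions=[(40.0, 40.0), (88.0, 88.0)],
                      rotation_freq=2.0, wavelength=32.0)


@pytest.fixture(scope="session")
def two_rotor_movie(two_rotor_spec):
    return make_spiral_movie(two_rotor_spec, duration_s=8.0)


@pytest.fixture(scope="session")
def paced_movie():
    """Planar wave paced at 1.5 Hz, 30 s @ 50 Hz on a small 1 cm wide field."""
    return make_paced_movie(1.5, duration_s=30.0, shape=(48, 48), cm_per_pixel=1 / 48)


@pytest.fixture(scope="session")
def sarcomere_half():
    from cardiomap.synthetic import make_sarcomere_image

    return make_sarcomere_image(SarcomereImageSpec(disordered_fraction=0.5, seed=7))


def brute_force_windings(phase_frame):
    """Independent oracle: winding number of every 2x2 loop by explicit
    per-loop summation of wrapped phase differences."""
    p = np.asarray(phase_frame, dtype=float)
    h, w = p.shape
    out = np.zeros((h - 1, w - 1), dtype=int)
    for r in range(h - 1):
        for c in range(w - 1):
            loop = [p[r, c], p[r, c + 1], p[r + 1, c + 1], p[r + 1, c], p[r, c]]
            total = 0.0
            for a, b in zip(loop[:-1], loop[1:]):
                d = b - a
                while d <= -np.pi:
                    d += 2 * np.pi
                while d > np.pi:
                    d -= 2 * np.pi
                total += d
            out[r, c] = int(round(total / (2 * np.pi)))
    return out


def border_winding(phase_frame):
    """Independent oracle: winding along the outer border of a frame."""
    p = np.asarray(phase_frame, dtype=float)
    path = np.concatenate([
        p[0, :], p[1:, -1], p[-1, :-1][::-1], p[1:-1, 0][::-1], p[:1, 0],
    ])
    d = np.diff(path)
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return int(round(d.sum() / (2 * np.pi)))
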