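"""Welch PSD, band-limited dominant frequency, culture-level mean."""

import numpy as np
import pytest

from cardiomap.core import CalciumMovie
from cardiomap.frequency import (
    dominant_frequency,
    mean_activation_frequency,
    welch_psd,
)
from cardiomap.synthetic import make_paced_movie, make_spiral_movie, SpiralSpec

FS = 50.0
BIN_HZ = 1.0 / 3.0  # 3 s Welch windows


def _sine(f0, duration_s=30.0, amp=1.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * f0 * t)


def fft_peak_oracle(signal, fs, band=(0.1, 12.0)):
    """Independent oracle: argmax of the full-length raw periodogram."""
    freqs = np.fft.rfftfreq(len(signal), 1 / fs)
    power = np.abs(np.fft.rfft(signal - signal.mean())) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return freqs[sel][np.argmax(power[sel])]


@pytest.mark.parametrize("f0", [0.5, 1.0, 2.0, 4.0, 8.0])
def test_peak_within_one_bin_of_truth(f0):
    res = welch_psd(_sine(f0), FS)
    assert res.dominant_freq is not None
    assert abs(res.dominant_freq - f0) <= BIN_HZ + 1e-9
    # and agrees with a full-length periodogram oracle to within one bin
    assert abs(res.dominant_freq - fft_peak_oracle(_sine(f0), FS)) <= BIN_HZ + 1e-9


def test_total_power_matches_variance():
    x = _sine(2.0) + 0.3 * _sine(5.0)
    res = welch_psd(x, FS)
    total = np.trapezoid(res.power, res.freqs)
    assert total == pytest.approx(np.var(x), rel=0.10)


def test_out_of_band_component_never_wins():
    """A 0.05 Hz drift of equal amplitude cannot displace the in-band peak."""
    x = _sine(2.0) + _sine(0.05)
    res = welch_psd(x, FS)
    assert res.dominant_freq == pytest.approx(2.0, abs=BIN_HZ)
    strong_drift = _sine(2.0) + 5.0 * _sine(0.05)
    assert welch_psd(strong_drift, FS).dominant_freq >= 0.1


def test_amplitude_scaling_invariance():
    x = _sine(3.0) + 0.2 * _sine(7.0)
    assert dominant_frequency(x, FS) == dominant_frequency(100.0 * x, FS)


def test_flat_signal_has_no_peak():
    assert welch_psd(np.zeros(500), FS).dominant_freq is None


def test_white_noise_handled_gracefully():
    """Noise spectra are flat: no bin dominates, but a peak is still picked."""
    rng = np.random.default_rng(123)
    for _ in range(20):
        res = welch_psd(rng.normal(size=int(30 * FS)), FS)
        assert res.dominant_freq is not None  # graceful, not a crash
        in_band = (res.freqs >= 0.1) & (res.freqs <= 12.0)
        assert res.power[in_band].max() < 5.0 * np.median(res.power[in_band])


def test_short_signal_rejected():
    with pytest.raises(ValueError):
        welch_psd(np.ones(int(2 * FS)), FS)


def test_mean_activation_frequency_paced(paced_movie):
    res = mean_activation_frequency(paced_movie)
    assert res.mean_hz == pytest.approx(1.5, abs=BIN_HZ)
    assert res.n_pixels_used == res.n_pixels_total


def test_mean_activation_frequency_spiral_uniform():
    spec = SpiralSpec(1, [1], [(24.0, 24.0)], rotation_freq=2.0, wavelength=24.0)
    mv = make_spiral_movie(spec, duration_s=10.0, shape=(48, 48), cm_per_pixel=1 / 48)
    res = mean_activation_frequency(mv)
    assert res.mean_hz == pytest.approx(2.0, abs=BIN_HZ)


def test_mixed_frequency_mask_averages():
    """Half the culture at 1 Hz and half at 3 Hz averages to 2 Hz."""
    t = np.arange(int(30 * FS)) / FS
    frames = np.empty((len(t), 2, 4))
    frames[:, :, :2] = np.sin(2 * np.pi * 1.0 * t)[:, None, None]
    frames[:, :, 2:] = np.sin(2 * np.pi * 3.0 * t)[:, None, None]
    mv = CalciumMovie(frames, FS, 0.01)
    res = mean_activation_frequency(mv)
    assert res.mean_hz == pytest.approx(2.0, abs=BIN_HZ)


def test_undefined_when_no_pixel_has_a_peak():
    frames = np.zeros((400, 4, 4)) + 5.0
    res = mean_activation_frequency(CalciumMovie(frames, FS, 0.01))
    assert res.mean_hz is None
    assert res.n_pixels_used == 0


def test_pooled_method_agrees_on_homogeneous_movie():
    # wavelength longer than the field so the spatial average keeps a beat
    mv = make_paced_movie(1.5, duration_s=30.0, shape=(32, 32),
                          cm_per_pixel=1 / 32, wavelength=96.0)
    pixelwise = mean_activation_frequency(mv)
    pooled = mean_activation_frequency(mv, method="pooled")
    assert pooled.mean_hz == pytest.approx(pixelwise.mean_hz, abs=BIN_HZ)
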