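"""Estimate the activation frequency of a paced monolayer.

Builds a planar-wave movie paced at 1.5 Hz, estimates each pixel's dominant
frequency with Welch's periodogram (3 s windows, 1 s overlap, 0.1-12 Hz
band) and averages over the culture.  A 0.05 Hz baseline drift is added to
show the band rule at work: it cannot displace the in-band peak.
"""

from cardiomap import make_paced_movie, mean_activation_frequency

movie = make_paced_movie(1.5, duration_s=30.0, shape=(64, 64), cm_per_pixel=1 / 64)
res = mean_activation_frequency(movie)
print(f"paced at 1.5 Hz -> mean activation frequency {res.mean_hz:.3f} Hz "
      f"({res.n_pixels_used}/{res.n_pixels_total} pixels with a defined peak)")

clean = make_paced_movie(3.0, duration_s=30.0, shape=(64, 64), cm_per_pixel=1 / 64)
drifting = make_paced_movie(3.0, duration_s=30.0, shape=(64, 64), cm_per_pixel=1 / 64,
                            drift_freq=0.05, drift_amplitude=1.0)
f_clean = mean_activation_frequency(clean).mean_hz
f_drift = mean_activation_frequency(drifting).mean_hz
print(f"paced at 3.0 Hz:   {f_clean:.3f} Hz clean, {f_drift:.3f} Hz with an "
      f"equal-amplitude 0.05 Hz drift (out-of-band power ignored)")

# The Welch frequency grid for 3 s windows has 1/3 Hz bins, so 1.5 Hz is
# recovered at the nearest bin; the 0.05 Hz drift lies below the 0.1 Hz band
# edge and never becomes the dominant peak, leaving the 3 Hz estimate intact.
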