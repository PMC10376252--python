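# Methods

`cardiomap` quantifies two image-derived phenotypes of anthracycline
cardiotoxicity in hiPSC-derived cardiomyocyte (hiPSC-CM) monolayers:
arrhythmia complexity from calcium optical-mapping movies, and sarcomere
disorganization from sarcomeric α-actinin immunofluorescence. This note
describes the models, the tunable parameters, the synthetic ground truth the
package is validated against, and the numerical choices made where the
design was open.

## Phase mapping

A calcium movie is a calibrated T×H×W stack (`frame_rate` in Hz,
`cm_per_pixel`). Preprocessing (`normalize_movie`) removes a per-pixel
linear trend and rescales each trace to zero mean and unit SD; a trace whose
detrended residual is below 10⁻⁸ of its raw scale (SD + |mean|) is treated
as dead and dropped from the mask. The instantaneous phase
(`compute_phase`) is the argument of the temporal analytic signal (Hilbert
quadrature) of each pixel trace, wrapped to (−π, π]. The analytic-signal
route was chosen over time-delay embedding because it is parameter-free and
standard for optical mapping; an embedding would add an unstated delay
parameter. The analytic signal distorts phase near the record boundaries,
so the first and last 0.5 s are flagged lower-confidence
(`PhaseMovie.edge_frames`) and excluded from singularity counting; they are
retained in the array for inspection.

Phase is invariant to per-pixel affine intensity rescaling, so the same
phase maps result from 8-bit and 16-bit renderings of one recording.

## Phase-singularity detection and PS/cm²

A phase singularity (PS) — the pivot of a re-entrant spiral wave — is a
point around which phase winds by ±2π. Detection evaluates the topological
charge of every 2×2 pixel loop: the four phase differences around the loop,
each wrapped into (−π, π], are summed; the sum is analytically an exact
multiple of 2π, and a loop with |sum| ≥ 2π − `tol` (default `tol` =
0.01 rad) reports a singularity with chirality = sign(sum). The 2×2 loop is
the smallest closed loop and gives the tightest localization. Chirality +1
means counterclockwise phase increase with the loop traversed
right/down/left/up (x = column, y = row). Adjacent loops reporting the same
chirality within 1 pixel are merged, since a core sitting on a loop boundary
can be double-reported under discretization. Only loops whose four corners
carry valid masked phase are evaluated, so net detected chirality equals the
winding number along the mask border (charge conservation) on every frame.

Arrhythmia complexity is the number of PS per square centimetre: PS are
counted per interior frame, the counts are averaged over time, and the
average is divided by the masked culture area in cm². Whether the original
statistic is a time average, a per-frame maximum or a unique-rotor count is
not derivable from its description; the time average is the default and a
per-frame maximum is available via `aggregate="max"`, without any claim
that it reproduces the original software's aggregation. Movies larger than
the configured standardized analysis format (default 512×512) are first
block-averaged down to it, with `cm_per_pixel` rescaled so the physical
field size is conserved; non-integer factors fall back to bilinear
resampling with anti-aliasing.

## Activation frequency

The activation (dominant) frequency of a trace is the location of the
maximum of its Welch power spectral density, considering only peaks in the
0.1–12 Hz physiological band. Welch segmentation uses 3 s windows with 1 s
overlap between consecutive windows (i.e. a 2 s advance — the stated overlap
is taken literally rather than the more common 50%), Hann-tapered, density
scaling; the frequency resolution is therefore ≈ 1/3 Hz, which is the
recovery tolerance quoted in the tests. No prominence threshold is applied:
the estimate is the maximum in-band bin, undefined only when the signal is
flat or carries no in-band power.

The culture-level statistic is the mean over masked pixels of the per-pixel
dominant frequency; it is flagged undefined when fewer than 10% of masked
pixels yield a peak. Whether the original analysis averaged per-pixel
estimates or analysed a pooled trace is not stated; both are implemented
(`method="pixelwise"` default, `method="pooled"` alternative).

## Sarcomere disorganization

α-actinin images are binarized with the IsoData automatic histogram
threshold (the default of the common interactive tool for this analysis; a
`invert` flag handles stains rendered dark-on-light). Connected particles
(8-connected by default) are measured in physical units — calibration
(µm/pixel) is mandatory input — with area in µm², Crofton-estimated
perimeter, and circularity 4π·area/perimeter² clipped to 1 (single-pixel
particles score 1, matching the reference tool's convention). Two gates are
accumulated:

* organized area OA: particle area 5–40 µm² and circularity 0.00–0.80
  (elongated Z-disc bands of regularly spaced sarcomeres);
* total area TA: particle area 0–40 µm² and circularity 0.00–1.00.

The disorganization score is (1 − OA/TA)·100, in percent; OA ⊆ TA by gate
containment, so the score lies in [0, 100]. TA = 0 yields an explicitly
flagged undefined score. Edge-touching particles are included by default
(`exclude_edges` optional).

## Cohort statistics

Per-video PS density and activation frequency are aggregated by cell line
and condition. Group contrasts use the two-sided Mann–Whitney U test with
p < 0.05 considered significant; summaries are mean ± SD with the n−1
denominator. The exact null distribution is used whenever the pooled sample
is tie-free and has at most 25 observations — enumeration is cheap there and
exactness matters at the study's group sizes (5–14 videos per cell) — with
the normal approximation plus tie and continuity corrections beyond that.
Videos are treated as the statistical unit (matching the reported group
sizes); treating differentiation batches as units would require batch
means, which the manifest supports but the pipeline does not default to.

The recording manifest mirrors the published experiment accounting: 78
videos (42 basal, 36 doxorubicin) from 30 differentiation batches, 2.6
videos per batch, with per-line totals 14/15/23/26. The per-cell counts are
stored so that every one of those published marginals is reproduced exactly.

## Synthetic ground truth

The generators define the study conditions for validation:

* **Rotor movies** use a kinematic Archimedean-spiral phase, not a
  reaction–diffusion model: φ(r, c, t) = 2πft + Σₖ χₖ·atan2(r−rₖ, c−cₖ) −
  2π·d_min/λ, rendered as a positive-offset cosine plus i.i.d. Gaussian
  noise (sd expressed as a fraction of the signal amplitude). The kinematic
  model trades electrophysiological realism for an exact analytic truth:
  the phase field winds by exactly χₖ around core k in every frame, and the
  temporal analytic signal recovers φ, so detector output can be checked
  frame by frame. The sign convention makes the Hilbert-recovered phase
  wind with +χₖ, so constructed and detected chirality coincide. Defaults:
  128×128 pixels at 1/128 cm/pixel (a 1 cm² field, making PS/cm² equal the
  raw count), 50 Hz, rotation 2 Hz, wavelength 32 px. `n_rotors=0` produces
  a planar travelling wave (zero winding everywhere), also used by
  `make_paced_movie` for frequency fixtures, optionally with a 0.05 Hz
  baseline drift to exercise the band rule.
* **Striation images** tile the field with 40×40-px (8×8 µm at the default
  0.2 µm/pixel) tiles. Ordered tiles carry four 1×6 µm bands at 2 µm
  spacing — inside the OA gate; the generator refuses geometries whose band
  footprint would leave the gate. Disordered tiles carry three
  1.6-µm-radius discs (circularity ≈ 1, inside TA, outside OA) whose summed
  area ≈ one ordered tile's band area, so the expected score tracks the
  disordered tile fraction. The generator returns its exact pixel
  bookkeeping (`expected_score_pct`) as the oracle.
* **The synthetic cohort** writes one movie per manifest video: one rotor
  everywhere except the cardiotoxicity lines under doxorubicin, which get
  four — a constructed effect that should yield significant basal-vs-DOX
  contrasts only in those lines.

What the generators deliberately do not emulate: realistic calcium-transient
kinetics (the signal is sinusoidal), rotor meander/break-up, motion
artefacts, spatially correlated noise, out-of-focus light, and real
myofibril texture. Passing tests therefore demonstrate correctness of the
quantifications on controlled inputs — winding detection, band-limited
spectral peaks, gated morphometry, rank statistics — not robustness to every
property of laboratory recordings.

## Problem sizes and numerical choices

Validation fixtures are sized for exactness rather than scale: rotor
fixtures 128×128 × 8 s at 50 Hz (400 frames; 350 interior frames scored per
fixture), frequency fixtures 48×48 × 24 s, the end-to-end cohort 78 videos
of 48×48 × 6.5 s at 40 Hz. Detection tolerance 0.01 rad is exact on
analytic fixtures because loop sums are quantized to multiples of 2π.
Degenerate inputs fail loudly and specifically: missing calibration names
the missing key, empty masks and constant images raise, undefined
frequencies and scores are flagged rather than returned as numbers.

## Known limitations

* The rotor model is stationary; drifting or meandering cores, wavebreak
  and figure-of-eight re-entry are out of scope.
* PS trajectories are not tracked over time; only counts enter the density.
* The mask for real recordings (whole well vs confluent region) is the
  caller's responsibility; statistics are per masked area.
* The score's "organized" semantics follow the gate definitions at face
  value: elongated in-gate particles count as organized regardless of their
  spatial arrangement or periodicity.
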