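# Methods

## Spectral estimation

Power spectra are multitaper estimates: each equal-length segment is
multiplied by K = 3 DPSS (Slepian) tapers with time–bandwidth product
NW = 2 (K = 2NW − 1), the squared rFFT magnitudes are averaged over tapers
and then over trials **in the power domain**, and logarithms are taken only
afterwards. Tapers are normalized to unit energy so the estimate is a
density: `sum(P)·Δf` equals the mean segment variance for a mean-subtracted
white input (verified to 5% on 200 × 500 ms segments). No zero-padding is
used; the frequency grid is the natural Rayleigh resolution of the analysis
window, which avoids any interpolation ambiguity in band sums. Segments are
not detrended — the knee'd background (below) makes detrending unnecessary,
and leaving the data untouched keeps the estimator linear in power.

Spectrograms use a 250 ms window sliding in 25 ms steps; windows are indexed
by their center time (first center at `t_min + 0.125 s`), and only windows
fully inside the trial span are evaluated.

### Baseline normalization

The time–frequency difference map is
`D(t,w) = 10·(log10 E(t,w) − log10 B(w))` dB, with `B(w)` estimated from the
pre-stimulus window pooled over trials of **every** stimulus condition of
the session (conditions are exchangeable before onset). Band-power change
per condition is `ΔPower_i = 10·(log10 ST_i − BL_ave)` with
`BL_ave = mean_i log10 BL_i`; `ST_i`/`BL_i` are sums of power over the
in-band bins after removing line-noise bins (line frequency and all
harmonics, ±2 Hz — the width is a configurable choice; the exclusion itself
is standard). The same mask is applied to stimulus and baseline sums, so the
metric is invariant to an overall gain and to the density-vs-integrated
power convention. Cross-site averages of `D`, change spectra and `ΔPower`
are taken on the dB values (log-scale averaging).

Stimulus and baseline windows per design: (−200, 0) / (200, 400) ms for the
non-simultaneous size design, (−500, 0) / (250, 750) ms for the simultaneous
designs. Because the two windows of a design have equal length, stimulus and
baseline spectra share one frequency grid and band sums are directly
comparable. Gamma bands: 30–65 Hz (size), 45–70 Hz (orientation, SF, to
avoid slow gamma), 20–75 Hz (contrast, to accommodate the large peak shift);
high-gamma 150–250 Hz (above the gamma harmonic). All are configurable.

## Circular orientation statistics

Orientation is axial (180°-periodic), so statistics are computed on doubled
angles: preferred orientation is `½·atan2(ΣR sin2θ, ΣR cos2θ)` mapped to
[0, 180), selectivity is the normalized resultant `|ΣR e^{j2θ}|/ΣR`. The ½
factor and four-quadrant arctangent are required for values to live on the
axial range; a perfectly balanced profile (zero resultant) has no preferred
orientation and is reported as NaN rather than an arbitrary angle.
`R_i` is the linear (not dB) stimulus-window power summed over the gamma
band per orientation. An additive untuned offset (e.g. the 1/f background
inside the band) leaves the preferred orientation unbiased and only
compresses selectivity toward 0, which is the behavior one wants from a
descriptive index.

Gamma peak frequency is the argmax of the baseline-corrected change
spectrum within the band, ties broken toward the lower frequency
(conservative given the 1/f background); maxima on a band edge are flagged.
Tuning curves are compared with the sample Pearson correlation and a
two-sided t-based p-value. Bootstrap SEs of medians resample with
replacement using `numpy.random.default_rng(seed)`.

## High-gamma PSD slope

`log10 P = c − m·log10 f` is fitted by unweighted OLS over the included
150–250 Hz bins (the 200 Hz harmonic of a 50 Hz line is excluded); `m` is
reported as the positive decay exponent. The model is a pure power law with
`c` as the intercept/noise-floor constant; no additive noise-floor term is
fitted. Stimulus-window and baseline-window exponents from the same
electrodes are compared with a paired t test (an unpaired option exists
behind a flag). The slope stimulus window defaults to 250–500 ms for the
simultaneous designs — shorter than the band-power window — with the longer
250–750 ms window available as a config value.

## Electrode selection and referencing

A site enters the size-study analyses only if its minimum-over-sizes firing
rate is ≥ 1 spike/s, its spike-waveform SNR is strictly > 1.5, its RF-center
estimates are stable across sessions (SD < 0.1°), and its RF lies within
0.2° of the stimulus center; full-screen designs apply only the RF-stability
filter. SNR is peak-to-peak of the mean waveform over twice the SD of the
residuals after subtracting the mean waveform (a pluggable convention). RF
stability is the RMS radial deviation of the 2-D session estimates from
their mean — the per-axis-vs-radial convention is not standardized, and the
radial form is rotation-invariant. Decisions are deterministic, idempotent
and carry machine-readable exclusion reasons.

Bipolar referencing is the elementwise difference of two equal-length
traces; components common to both electrodes cancel while independent
components add in power (+3 dB), so a fully shared gamma peak is attenuated
by well over 10 dB while private broadband survives.

## Synthetic data generator

Each trial is a sum of independent Gaussian processes, synthesized by
spectral shaping in the rFFT domain and normalized by their *expected*
standard deviation (so components are exact Gaussian processes with known
variance):

- **Background**: PSD ∝ `(f² + knee²)^(−bg_slope/2)` with a 10 Hz knee.
  Field potentials flatten at low frequencies, and the knee is also what
  makes steep exponents measurable: a kneeless f⁻³ process puts essentially
  all variance near DC, and taper sidelobe leakage then floors the
  150–250 Hz estimate on 500 ms windows. Defaults: slope 1.25 (LFP),
  1.9 (ECoG); variance 1 (the unit of all gains).
- **Narrowband gamma**: Gaussian noise band-passed with a Gaussian envelope
  (±5 Hz) around the stimulus-dependent peak frequency — a stochastic
  oscillation with a realistic spectral bump, not a sinusoid. Its variance
  follows a separable tuning map: saturating growth with radius
  `1 − exp(−r/6°)` (still visibly rising at 9.6°, as the recordings this
  emulates show), axial von Mises orientation tuning (κ = 2, preferred 90°),
  log-Gaussian SF tuning (center 4 cpd, 1.5 octaves), and a Naka–Rushton
  contrast response (c50 = 10%, n = 2); overall gain 4 background-variance
  units. Peak frequency starts at 62 Hz for a 0.3° grating, falls
  1.2 Hz/octave of radius (capped at 5 octaves) and rises 4 Hz/octave of
  contrast — trends and ranges chosen so defaults stay inside the analysis
  bands and clear of the line-frequency exclusion. A **harmonic** at twice
  the peak carries 25% of the gamma variance; a **slow gamma** component
  (~30 Hz, ±3 Hz) engages for radii above 2.4°.
- **Broadband high-gamma**: noise shaped like the background above 80 Hz
  with a smooth order-8 high cut at 400 Hz (LFP) or 250 Hz (ECoG), variance
  0.02 per spike/s of driven rate. Because the LFP cut lies at the Nyquist
  edge, LFP stimulus and baseline slopes over 150–250 Hz agree; the ECoG cut
  falls inside the band and steepens the stimulus-window slope — this is the
  mechanism by which the generator reproduces the LFP/ECoG slope contrast.
- **Firing rate**: ratio-of-Gaussians center/surround
  (σ_center = 0.2°, σ_surround = 1°, surround gain 2, max driven 80 sp/s,
  spontaneous 5 sp/s), maximal at the smallest radius. Spikes are drawn by
  per-sample Bernoulli thinning at 2 kHz (exact inhomogeneous Poisson in the
  dt→0 limit; bin probabilities stay ≤ 0.1), with a 1.5× onset boost in the
  first 150 ms.
- **Onset transient**: Hann-windowed white noise over the first 150 ms
  (excluded by every analysis window, so its shape is non-critical), and
  continuous sinusoidal **line noise** (50 or 60 Hz, amplitude 0.3, random
  phase per trial).

Stimulus-driven components are gated to [0, 0.8] s (hard gate); trials span
[−0.5, 0.8) s at 2 kHz. Sessions present the `grid × repeats` conditions in
a seeded pseudo-random order shared by all channels. A configurable fraction
of each channel's gamma variance derives from a white-noise latent common to
all channels (each channel band-passes the same latent around its own peak),
emulating spatially coherent gamma: fraction 0 gives independent channels,
fraction 1 identical gamma for identically tuned channels. Per-session
RF-center estimates are jittered with SD 0.02°, and biphasic spike snippets
(peak-to-peak 6, noise SD 1) are attached for SNR filtering. Everything is
driven by `numpy.random.SeedSequence` spawning, so fixed seeds reproduce
sessions bit-exactly.

### What the generator does and does not emulate

It reproduces the statistical structure the analyses consume: stimulus-gated
narrowband/broadband components with parametric tuning, 1/f background with
class-specific slope and broadband extent, rate-coupled high-gamma, line
noise, shared gamma across channels, and Poisson spiking. It does **not**
model volume conduction, laminar structure, eye movements, cross-frequency
phase coupling, non-Gaussian burst statistics of real gamma, or EEG-class
signals. Passing tests therefore demonstrate that the analysis chain
recovers known parametric structure from realistic spectra — not that it
would be robust to every artifact of real recordings.

## Numerical and design choices

- Problem sizes in the test suite and acceptance script (e.g. 8 orientations
  × 30 repeats; 6 radii × 20 repeats × 6 sites per class; 300 × 500 ms
  segments for slope recovery) are chosen so each property is resolved
  with comfortable statistical margin at desk scale.
- Band edges are inclusive; exclusion intervals are closed (`|f−c| ≤ h`
  removed). A band whose bins are all excluded is an error, as is a
  nonpositive power inside a dB difference or slope fit.
- `ΔPower` and `D` are invariant to trace rescaling by construction; tests
  assert it numerically.
- The degenerate cases are explicit: zero-resultant orientation profiles
  give NaN preferred orientation; zero-variance tuning curves give NaN
  Pearson r; zero-variance slope differences are flagged rather than given
  an infinite t; identical spike snippets give infinite SNR.
- The pipeline seeds every stochastic stage from one `SeedSequence`, records
  the seed and a config hash in the output manifest, and hashes every
  written table.

## Known limitations

- The multitaper estimator has the usual NW = 2 smoothing bias near sharp
  spectral features; slope recovery is validated to ±0.1 for exponents 1–3,
  and steeper spectra would need longer windows or more conservative tapers.
- Selection metrics for simulated sessions assume the stimulus is centered
  at the RF origin; real data must supply actual stimulus centers.
- The contrast peak-frequency analysis reports peaks only where they are
  salient (≥ 1 dB above the band median by default); very low contrasts
  rarely qualify, mirroring practice with real recordings.
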