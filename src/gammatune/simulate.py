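"""Synthetic trial-structured LFP/ECoG/spike generator with known tuning.

Each simulated trace is a sum of:

- a stationary Gaussian background with a 1/f**bg_slope power spectrum,
- stimulus-gated components, present only while the grating is on
  ([0, 0.8] s by default):

  * a narrowband stochastic gamma oscillation (Gaussian noise band-passed
    around a stimulus-dependent peak frequency) whose variance follows a
    separable tuning map: saturating growth with radius, axial von Mises
    orientation tuning, log-Gaussian spatial-frequency tuning and a
    Naka-Rushton contrast response; the peak frequency falls with radius and
    rises with log contrast,
  * a gamma harmonic at twice the peak frequency,
  * a 'slow gamma' (~30 Hz) component engaged for large stimuli,
  * broadband high-gamma noise band-limited to [80 Hz, hg_cutoff] whose
    variance is proportional to the surround-suppressed firing rate,
  * a broadband onset transient in the first 150 ms,

- continuous sinusoidal line noise (50 or 60 Hz).

Spikes are drawn from an inhomogeneous Poisson process (per-sample Bernoulli
thinning at the trace sampling rate) whose driven rate is a
ratio-of-Gaussians center/surround function of stimulus radius, so firing is
maximal for small stimuli -- the opposite of the gamma-amplitude trend.

Sessions generate multiple channels over a shared pseudo-random condition
order; a configurable fraction of each channel's gamma variance is drawn
from a latent source common to all channels, emulating the spatially
coherent gamma that bipolar referencing cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from gammatune.conditions import FULLSCREEN, StimulusCondition


@dataclass(frozen=True)
class TuningMapParams:
    """Ground-truth tuning maps and spectral shape parameters for one channel.

    All gains are variances in units of the background variance
    (``bg_sigma**2``).  Signal-class defaults differ: LFP keeps its
    stimulus-driven broadband up to ~400 Hz with a shallower background
    slope, ECoG's broadband is confined below ~250 Hz with a steeper slope.
    """

    # orientation tuning (axial von Mises)
    theta_pref_deg: float = 90.0
    kappa: float = 2.0
    # gamma amplitude vs radius: saturating growth 1 - exp(-r / size_sat)
    gamma_gain: float = 4.0
    size_sat_deg: float = 6.0
    # gamma peak frequency: linear decrement per octave of radius, capped
    peak_hz_ref: float = 62.0
    size_ref_deg: float = 0.3
    freq_per_octave_size: float = 1.2
    max_freq_octaves: float = 5.0
    # spatial-frequency tuning: log-Gaussian
    sf_center_cpd: float = 4.0
    sf_bw_oct: float = 1.5
    # contrast: Naka-Rushton response, peak frequency rises with log contrast
    c50_pct: float = 10.0
    n_naka: float = 2.0
    freq_per_octave_contrast: float = 4.0
    # firing rate: ratio-of-Gaussians center/surround (spikes/s)
    spont_rate: float = 5.0
    max_driven_rate: float = 80.0
    center_sigma_deg: float = 0.2
    surround_sigma_deg: float = 1.0
    surround_gain: float = 2.0
    # broadband high-gamma: variance per spike/s of driven rate
    hg_gain: float = 0.02
    hg_lo_hz: float = 80.0
    hg_cutoff_hz: float = 400.0
    hg_cut_order: int = 8
    # background 1/f with a low-frequency knee (P ~ (f^2 + knee^2)^(-slope/2))
    bg_slope: float = 1.25
    bg_knee_hz: float = 10.0
    bg_sigma: float = 1.0
    # narrowband structure
    gamma_bw_hz: float = 5.0
    harmonic_frac: float = 0.25
    slowgamma_gain: float = 1.0
    slowgamma_hz: float = 30.0
    slowgamma_bw_hz: float = 3.0
    slowgamma_radius_min_deg: float = 2.4
    # line noise
    line_hz: float = 50.0
    line_amp: float = 0.3
    # onset transient
    onset_dur_s: float = 0.15
    onset_gain: float = 2.0
    # effective radius of a full-screen grating for the tuning maps
    fullscreen_radius_deg: float = 30.0

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_gain", "hg_gain", "harmonic_frac",
                     "slowgamma_gain", "line_amp", "onset_gain", "bg_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bg_slope <= 0:
            raise ValueError("bg_slope must be > 0")


_CLASS_DEFAULTS = {
    "LFP": dict(bg_slope=1.25, hg_cutoff_hz=400.0),
    "ECoG": dict(bg_slope=1.9, hg_cutoff_hz=250.0),
}


def default_params(signal_class: str = "LFP", **overrides) -> TuningMapParams:
    """Default tuning-map parameters for a signal class ("LFP" or "ECoG")."""
    if signal_class not in _CLASS_DEFAULTS:
        raise ValueError(f"unknown signal class {signal_class!r}")
    kwargs = dict(_CLASS_DEFAULTS[signal_class])
    kwargs.update(overrides)
    return TuningMapParams(**kwargs)


@dataclass(frozen=True)
class ChannelSpec:
    """One simulated channel: class, ground-truth params, RF center (deg)."""

    signal_class: str
    params: TuningMapParams
    rf_center_deg: tuple[float, float] = (0.0, 0.0)
    channel_id: str | None = None


@dataclass
class TrialSet:
    """Trial-aligned traces, spikes and condition labels for one channel."""

    channel_id: str
    signal_class: str
    fs_hz: float
    t_axis: NDArray[np.float64]
    traces: NDArray[np.float64]  # (n_trials, n_samples)
    spikes: list[NDArray[np.float64]]
    conditions: list[StimulusCondition]
    rf_center_deg: tuple[float, float] = (0.0, 0.0)
    rf_center_per_session: NDArray[np.float64] | None = None
    snippets: NDArray[np.float64] | None = None

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    def trials_where(self, predicate) -> NDArray[np.intp]:
        """Indices of trials whose condition satisfies a predicate."""
        return np.array(
            [i for i, c in enumerate(self.conditions) if predicate(c)],
            dtype=np.intp,
        )


def _effective_radius(stim: StimulusCondition, p: TuningMapParams) -> float:
    return p.fullscreen_radius_deg if stim.is_fullscreen else stim.radius_deg


def _axial_von_mises(delta_deg: float, kappa: float) -> float:
    """Unnormalized axial von Mises weight, 1 at the preferred orientation."""
    return math.exp(kappa * (math.cos(2.0 * math.radians(delta_deg)) - 1.0))


def gamma_params_for(
    stim: StimulusCondition, p: TuningMapParams
) -> tuple[float, float]:
    """Ground-truth gamma variance and peak frequency for a stimulus.

    amp (variance, background units) is separable:
      size:        1 - exp(-radius / size_sat)         (saturating growth)
      orientation: exp(kappa * (cos 2(theta - theta_pref) - 1))
      SF:          exp(-(log2(sf / sf_center))^2 / (2 sf_bw^2))
      contrast:    c^n / (c^n + c50^n)                 (Naka-Rushton)
    scaled by ``gamma_gain``.  amp = 0 for a blank (contrast 0) stimulus.

    peak_hz falls linearly with log2 radius (capped at ``max_freq_octaves``
    octaves above the reference radius) and rises with log2 contrast.
    """
    r = _effective_radius(stim, p)
    c = stim.contrast_pct
    size_oct = min(max(math.log2(r / p.size_ref_deg), 0.0), p.max_freq_octaves)
    contrast_oct = math.log2(c / 100.0) if c > 0 else 0.0
    peak_hz = (
        p.peak_hz_ref
        - p.freq_per_octave_size * size_oct
        + p.freq_per_octave_contrast * contrast_oct
    )
    if c == 0:
        return 0.0, peak_hz
    amp = (
        p.gamma_gain
        * (1.0 - math.exp(-r / p.size_sat_deg))
        * _axial_von_mises(stim.orientation_deg - p.theta_pref_deg, p.kappa)
        * math.exp(
            -(math.log2(stim.sf_cpd / p.sf_center_cpd) ** 2)
            / (2.0 * p.sf_bw_oct**2)
        )
        * c**p.n_naka / (c**p.n_naka + p.c50_pct**p.n_naka)
    )
    return amp, peak_hz


def rate_for(stim: StimulusCondition, p: TuningMapParams) -> float:
    """Ground-truth mean firing rate (spikes/s) during the stimulus.

    Ratio-of-Gaussians center/surround: the center drive saturates quickly
    with radius while the divisive surround keeps growing, so the rate is
    maximal for small stimuli and falls monotonically beyond the center
    scale.  A blank stimulus yields the spontaneous rate.
    """
    if stim.is_blank:
        return p.spont_rate
    r = _effective_radius(stim, p)
    center = 1.0 - math.exp(-((r / p.center_sigma_deg) ** 2))
    surround = 1.0 - math.exp(-((r / p.surround_sigma_deg) ** 2))
    nr = (
        stim.contrast_pct**p.n_naka
        / (stim.contrast_pct**p.n_naka + p.c50_pct**p.n_naka)
    )
    driven = p.max_driven_rate * nr * center / (1.0 + p.surround_gain * surround)
    return p.spont_rate + driven


# ---------------------------------------------------------------------------
# noise synthesis helpers (FFT-domain spectral shaping)
# ---------------------------------------------------------------------------


def _shaped_noise(
    white: NDArray[np.float64],
    fs: float,
    shape: NDArray[np.float64],
) -> NDArray[np.float64]:
    """Filter white noise to a given one-sided amplitude shape, unit variance.

    ``shape`` is the desired spectral amplitude on the rfft grid (arbitrary
    scale).  The output is rescaled by the *expected* (not realized) standard
    deviation, so the result is an exact Gaussian process with unit expected
    variance.
    """
    n = white.shape[-1]
    X = np.fft.rfft(white)
    X = X * shape
    # expected variance per sample of irfft(shape * rfft(white)):
    # sum over full spectrum of shape^2 / n
    full = 2.0 * np.sum(shape**2) - shape[0] ** 2
    if n % 2 == 0:
        full -= shape[-1] ** 2
    ev = full / n
    if ev <= 0:
        return np.zeros(n)
    return np.fft.irfft(X, n) / math.sqrt(ev)


def powerlaw_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float,
    sigma: float = 1.0, knee_hz: float = 10.0,
) -> NDArray[np.float64]:
    """Gaussian noise with PSD proportional to (f^2 + knee^2)**(-exponent/2).

    Above the knee the spectrum decays as 1/f**exponent; below it the
    spectrum flattens, as neural field potentials do at low frequencies.
    (A kneeless pure power law concentrates almost all variance near DC for
    steep exponents, which no finite-window estimate can contain.)  SD of
    the process is ``sigma``.
    """
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = (f**2 + knee_hz**2) ** (-exponent / 4.0)
    shape[0] = 0.0
    return sigma * _shaped_noise(rng.standard_normal(n), fs, shape)


def _bandpass_gauss(
    white: NDArray[np.float64], fs: float, center_hz: float, bw_hz: float
) -> NDArray[np.float64]:
    """Gaussian-envelope band-pass of white noise, unit expected variance."""
    n = white.shape[-1]
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.exp(-((f - center_hz) ** 2) / (2.0 * bw_hz**2))
    return _shaped_noise(white, fs, shape)


def _highgamma_shape(
    f: NDArray[np.float64], p: TuningMapParams
) -> NDArray[np.float64]:
    """Amplitude shape of the stimulus-driven broadband component.

    Follows the background 1/f decay between ``hg_lo_hz`` and the Nyquist,
    with a smooth high cut at ``hg_cutoff_hz`` (order ``hg_cut_order``): for
    LFP the cut sits at 400 Hz, for ECoG at 250 Hz, so the ECoG broadband
    rolls off inside the 150-250 Hz slope-fit band.
    """
    shape = np.zeros_like(f)
    band = f >= p.hg_lo_hz
    shape[band] = f[band] ** (-p.bg_slope / 2.0) / np.sqrt(
        1.0 + (f[band] / p.hg_cutoff_hz) ** p.hg_cut_order
    )
    return shape


def simulate_trial(
    stim: StimulusCondition,
    p: TuningMapParams,
    seed: int,
    fs: float = 2000.0,
    t_start: float = -0.5,
    t_end: float = 0.8,
    stim_dur_s: float = 0.8,
    shared_white: NDArray[np.float64] | None = None,
    shared_fraction: float = 0.0,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Simulate one trial trace and its spike times.

    Deterministic: identical (stim, p, seed) give bit-identical output.
    ``shared_white`` is an optional pre-drawn white-noise latent (length =
    trace length) from which a ``shared_fraction`` of the narrowband gamma
    variance is derived; sessions use it to impose cross-channel coherence.

    Returns (trace, spike_times); times are seconds relative to stimulus
    onset (t = 0), with stimulus-driven components confined to
    [0, stim_dur_s].
    """
    if t_end - t_start < stim_dur_s:
        raise ValueError("trial must cover the stimulus duration")
    n = int(round((t_end - t_start) * fs))
    t = t_start + np.arange(n) / fs
    nyq = fs / 2.0
    amp, peak_hz = gamma_params_for(stim, p)
    if 2.0 * peak_hz >= nyq:
        raise ValueError(
            f"gamma harmonic at {2 * peak_hz:.0f} Hz exceeds Nyquist ({nyq:.0f} Hz)"
        )
    if p.hg_cutoff_hz > nyq:
        raise ValueError("hg_cutoff_hz exceeds Nyquist")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if shared_white is not None and shared_white.shape[-1] != n:
        raise ValueError("shared_white length must match the trace length")

    rng = np.random.default_rng(seed)
    gate = ((t >= 0.0) & (t < stim_dur_s)).astype(float)

    trace = powerlaw_noise(rng, n, fs, p.bg_slope, p.bg_sigma, p.bg_knee_hz)

    def mixed_band(center: float, bw: float) -> NDArray[np.float64]:
        own = _bandpass_gauss(rng.standard_normal(n), fs, center, bw)
        if shared_fraction > 0.0 and shared_white is not None:
            sh = _bandpass_gauss(shared_white, fs, center, bw)
            return (
                math.sqrt(1.0 - shared_fraction) * own
                + math.sqrt(shared_fraction) * sh
            )
        return own

    if amp > 0:
        trace += math.sqrt(amp) * mixed_band(peak_hz, p.gamma_bw_hz) * gate
        if p.harmonic_frac > 0:
            trace += (
                math.sqrt(amp * p.harmonic_frac)
                * mixed_band(2.0 * peak_hz, p.gamma_bw_hz)
                * gate
            )

    slow_on = (
        not stim.is_blank
        and p.slowgamma_gain > 0
        and _effective_radius(stim, p) > p.slowgamma_radius_min_deg
    )
    if slow_on:
        nr = (
            stim.contrast_pct**p.n_naka
            / (stim.contrast_pct**p.n_naka + p.c50_pct**p.n_naka)
        )
        trace += (
            math.sqrt(p.slowgamma_gain * nr)
            * mixed_band(p.slowgamma_hz, p.slowgamma_bw_hz)
            * gate
        )

    rate = rate_for(stim, p)
    driven = rate - p.spont_rate
    if not stim.is_blank and p.hg_gain > 0 and driven > 0:
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        hg = _shaped_noise(rng.standard_normal(n), fs, _highgamma_shape(f, p))
        trace += math.sqrt(p.hg_gain * driven) * hg * gate

    if not stim.is_blank and p.onset_gain > 0:
        onset_n = int(round(p.onset_dur_s * fs))
        onset_env = np.zeros(n)
        i0 = int(np.searchsorted(t, 0.0))
        env = np.hanning(onset_n)
        onset_env[i0 : i0 + onset_n] = env[: max(0, min(onset_n, n - i0))]
        trace += math.sqrt(p.onset_gain) * rng.standard_normal(n) * onset_env

    if p.line_amp > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        trace += p.line_amp * np.sin(2.0 * math.pi * p.line_hz * t + phase)

    # spikes: inhomogeneous Poisson via per-sample Bernoulli thinning
    rate_t = np.full(n, p.spont_rate)
    in_stim = gate > 0
    onset_boost = np.where(
        (t >= 0.0) & (t < p.onset_dur_s), 1.5, 1.0
    )
    rate_t[in_stim] = p.spont_rate + driven * onset_boost[in_stim]
    spikes = t[rng.random(n) < rate_t / fs]
    return trace, spikes


def _spike_snippet_template(length: int) -> NDArray[np.float64]:
    """Biphasic extracellular spike template, peak-to-peak normalized to 1."""
    x = np.arange(length, dtype=float)
    w = -np.exp(-((x - 0.3 * length) ** 2) / (2.0 * (0.06 * length) ** 2))
    w += 0.45 * np.exp(-((x - 0.55 * length) ** 2) / (2.0 * (0.12 * length) ** 2))
    return w / (w.max() - w.min())


def simulate_session(
    grid: Sequence[StimulusCondition],
    n_repeats_per_condition: int,
    channels: Sequence[ChannelSpec],
    shared_gamma_fraction: float = 0.0,
    seed: int = 0,
    fs: float = 2000.0,
    t_start: float = -0.5,
    t_end: float = 0.8,
    n_sessions: int = 5,
    rf_jitter_sd_deg: float = 0.02,
    n_snippets: int = 200,
    snippet_len: int = 48,
    snippet_amp: float = 6.0,
    snippet_noise_sd: float = 1.0,
) -> list[TrialSet]:
    """Simulate a multichannel recording session.

    All channels see the same pseudo-random trial order over
    ``grid x n_repeats_per_condition`` trials.  ``shared_gamma_fraction`` of
    each channel's narrowband gamma variance is drawn from a latent source
    common to all channels; 0 makes channels' gamma independent, 1 makes it
    identical (for channels with identical tuning parameters), so a bipolar
    difference removes the gamma peak.

    Per-session RF-center estimates are jittered around each channel's true
    center with SD ``rf_jitter_sd_deg``; spike-waveform snippets with
    peak-to-peak amplitude ``snippet_amp`` and additive noise SD
    ``snippet_noise_sd`` are attached for SNR-based selection.
    """
    if n_repeats_per_condition < 1:
        raise ValueError("n_repeats_per_condition must be >= 1")
    if len(grid) == 0:
        raise ValueError("empty condition grid")
    if len(channels) == 0:
        raise ValueError("no channels specified")

    ss = np.random.SeedSequence(seed)
    order_ss, shared_ss, aux_ss, *chan_ss = ss.spawn(3 + len(channels))
    order_rng = np.random.default_rng(order_ss)
    shared_rng = np.random.default_rng(shared_ss)
    aux_rng = np.random.default_rng(aux_ss)

    condition_list = [c for c in grid for _ in range(n_repeats_per_condition)]
    order = order_rng.permutation(len(condition_list))
    conditions = [condition_list[i] for i in order]
    n_trials = len(conditions)
    n_samp = int(round((t_end - t_start) * fs))

    shared_whites = (
        shared_rng.standard_normal((n_trials, n_samp))
        if shared_gamma_fraction > 0
        else None
    )

    template = _spike_snippet_template(snippet_len) * snippet_amp
    out: list[TrialSet] = []
    class_counts: dict[str, int] = {}
    for spec, css in zip(channels, chan_ss):
        crng = np.random.default_rng(css)
        trial_seeds = crng.integers(0, 2**31 - 1, size=n_trials)
        traces = np.empty((n_trials, n_samp))
        spikes: list[NDArray[np.float64]] = []
        for k, cond in enumerate(conditions):
            tr, sp = simulate_trial(
                cond,
                spec.params,
                int(trial_seeds[k]),
                fs=fs,
                t_start=t_start,
                t_end=t_end,
                shared_white=(
                    shared_whites[k] if shared_whites is not None else None
                ),
                shared_fraction=shared_gamma_fraction,
            )
            traces[k] = tr
            spikes.append(sp)
        rf = np.asarray(spec.rf_center_deg, dtype=float)
        rf_sessions = rf[None, :] + aux_rng.normal(
            0.0, rf_jitter_sd_deg, size=(n_sessions, 2)
        )
        snippets = template[None, :] + aux_rng.normal(
            0.0, snippet_noise_sd, size=(n_snippets, snippet_len)
        )
        idx = class_counts.get(spec.signal_class, 0)
        class_counts[spec.signal_class] = idx + 1
        channel_id = spec.channel_id or f"{spec.signal_class}{idx}"
        out.append(
            TrialSet(
                channel_id=channel_id,
                signal_class=spec.signal_class,
                fs_hz=fs,
                t_axis=t_start + np.arange(n_samp) / fs,
                traces=traces,
                spikes=spikes,
                conditions=conditions,
                rf_center_deg=(float(rf[0]), float(rf[1])),
                rf_center_per_session=rf_sessions,
                snippets=snippets,
            )
        )
    return out
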