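"""Multitaper spectral estimation and baseline-dB normalization.

Power spectra and spectrograms are estimated with the multitaper method
(DPSS/Slepian tapers, time-bandwidth product NW = 2, K = 3 tapers by
default).  Per-taper eigenspectra are averaged over tapers and then over
trials in the power domain; logarithms are taken only afterwards.

Baseline normalization follows the standard decibel convention

    D(t, w) = 10 * (log10 E(t, w) - log10 B(w))

where E is the trial-mean energy at time t and frequency w and B is the
baseline energy pooled over trials of every stimulus condition.  Band-power
change for condition i is

    dPower_i = 10 * (log10 ST_i - BL_ave),   BL_ave = mean_i log10 BL_i

with ST_i and BL_i the power summed over the in-band, non-excluded frequency
bins of the stimulus-window and baseline-window spectra.  Line-noise bins
(the line frequency and its harmonics, +/- a half-width) are excluded from
band sums identically in the stimulus and baseline windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.signal.windows import dpss


@dataclass(frozen=True)
class PowerSpectrum:
    """A one-sided power spectral density estimate.

    ``P`` is scaled as a density: the sum of ``P`` over the frequency grid
    times the bin width equals the (taper-weighted) mean segment variance.
    """

    f: NDArray[np.float64]
    P: NDArray[np.float64]
    n_trials: int
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if f.shape != P.shape:
            raise ValueError("f and P must have the same shape")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(P < 0):
            raise ValueError("power must be nonnegative")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "P", P)

    @property
    def df(self) -> float:
        return float(self.f[1] - self.f[0])


@dataclass(frozen=True)
class TimeFrequencyMap:
    """Trial-mean energy E(t, w), baseline B(w) and difference D(t, w) in dB."""

    t: NDArray[np.float64]
    w: NDArray[np.float64]
    E: NDArray[np.float64]
    B: NDArray[np.float64]
    D: NDArray[np.float64]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band with line-noise exclusions.

    ``exclusions`` is a sequence of (center_hz, half_width_hz) pairs; bins
    with |f - center| <= half_width are excluded from band sums and fits.
    """

    lo_hz: float
    hi_hz: float
    exclusions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band requires lo_hz < hi_hz")
        object.__setattr__(
            self,
            "exclusions",
            tuple((float(c), float(h)) for c, h in self.exclusions),
        )

    def mask(self, f: NDArray[np.float64]) -> NDArray[np.bool_]:
        """Boolean mask of included frequency bins on grid ``f``."""
        f = np.asarray(f, dtype=float)
        m = (f >= self.lo_hz) & (f <= self.hi_hz)
        for center, half in self.exclusions:
            m &= np.abs(f - center) > half
        return m


def line_exclusions(
    line_hz: float, fmax: float, half_width_hz: float = 2.0
) -> tuple[tuple[float, float], ...]:
    """Exclusion intervals at the line frequency and all harmonics up to fmax."""
    if line_hz <= 0:
        raise ValueError("line_hz must be positive")
    n = int(fmax // line_hz)
    return tuple((line_hz * k, half_width_hz) for k in range(1, n + 1))


@dataclass(frozen=True)
class BandPowerResult:
    """Baseline-normalized band-power change for one stimulus condition.

    ``st`` and ``bl`` are log10 of the band-summed stimulus-window and
    baseline-window power for this condition; ``bl_ave`` is the across-
    condition mean of the log10 baseline sums; ``delta_db`` is
    10 * (st - bl_ave).
    """

    condition_id: object
    st: float
    bl: float
    bl_ave: float
    delta_db: float


def _dpss_tapers(n: int, n_tapers: int, nw: float) -> NDArray[np.float64]:
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    tapers = dpss(n, nw, Kmax=n_tapers)
    tapers = np.atleast_2d(tapers)
    # unit energy so the eigenspectrum is an unbiased variance estimate
    tapers /= np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
    return tapers


def _eigenspectra(
    segments: NDArray[np.float64], fs: float, n_tapers: int, nw: float
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Mean-over-tapers power density per segment. Returns (f, P[seg, f])."""
    n = segments.shape[-1]
    tapers = _dpss_tapers(n, n_tapers, nw)
    # (K, n_seg, n_freq)
    spec = np.fft.rfft(tapers[:, None, :] * segments[None, :, :], axis=-1)
    power = (spec.real**2 + spec.imag**2) / fs
    # one-sided: double all bins except DC and (for even n) Nyquist
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return f, power.mean(axis=0)


def multitaper_psd(
    segments: Sequence[NDArray[np.float64]] | NDArray[np.float64],
    fs: float,
    n_tapers: int = 3,
    nw: float = 2.0,
    window: tuple[float, float] | None = None,
) -> PowerSpectrum:
    """Multitaper PSD averaged over equal-length segments.

    Parameters
    ----------
    segments:
        Iterable of equal-length 1-D arrays (e.g. one per trial), or a 2-D
        array (segments x samples).
    fs:
        Sampling rate in Hz.
    n_tapers:
        Number of DPSS tapers (K); default 3.
    nw:
        Time-bandwidth product; default 2 (so K = 2*NW - 1 with the default
        taper count).

    Returns
    -------
    PowerSpectrum
        Density on the one-sided rfft grid [0, Nyquist]; sum(P) * df equals
        the mean segment variance for a mean-subtracted white input, within
        estimator error.
    """
    seg_list = [np.asarray(s, dtype=float) for s in segments]
    if len(seg_list) == 0:
        raise ValueError("at least one segment is required")
    n = seg_list[0].shape[-1]
    if any(s.ndim != 1 or s.shape[0] != n for s in seg_list):
        raise ValueError("all segments must be 1-D and of equal length")
    arr = np.stack(seg_list)
    f, per_seg = _eigenspectra(arr, fs, n_tapers, nw)
    return PowerSpectrum(f=f, P=per_seg.mean(axis=0), n_trials=len(seg_list),
                         window=window)


def _window_slice(t_axis: NDArray[np.float64], window: tuple[float, float],
                  fs: float) -> slice:
    """Sample slice for a half-open time window [start, stop)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy start < stop")
    if t0 < t_axis[0] - 0.5 / fs or t1 > t_axis[-1] + 1.5 / fs:
        raise ValueError(
            f"window {window} outside trial span "
            f"({t_axis[0]:.3f}, {t_axis[-1]:.3f})"
        )
    i0 = int(np.searchsorted(t_axis, t0 - 0.5 / fs))
    n = int(round((t1 - t0) * fs))
    return slice(i0, i0 + n)


def psd_in_window(
    traces: NDArray[np.float64],
    t_axis: NDArray[np.float64],
    window: tuple[float, float],
    fs: float,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> PowerSpectrum:
    """Multitaper PSD of trial traces restricted to a time window."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    sl = _window_slice(np.asarray(t_axis, dtype=float), window, fs)
    return multitaper_psd(traces[:, sl], fs, n_tapers=n_tapers, nw=nw,
                          window=window)


def spectrogram(
    trials: NDArray[np.float64],
    fs: float,
    t_axis: NDArray[np.float64],
    window_s: float = 0.250,
    step_s: float = 0.025,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Trial-mean multitaper spectrogram with a sliding window.

    Windows are indexed by their center time; the first window starts at the
    first sample and successive windows advance by ``step_s``.  Only windows
    fully inside the trial span are evaluated.

    Returns ``(t_centers, w, E)`` with ``E`` of shape (n_windows, n_freqs).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    t_axis = np.asarray(t_axis, dtype=float)
    n_samp = trials.shape[1]
    if t_axis.shape[0] != n_samp:
        raise ValueError("t_axis length must match trial length")
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if win > n_samp:
        raise ValueError("window longer than trial")
    if step < 1:
        raise ValueError("step too small for sampling rate")
    starts = np.arange(0, n_samp - win + 1, step)
    tapers = _dpss_tapers(win, n_tapers, nw)
    f = np.fft.rfftfreq(win, d=1.0 / fs)
    E = np.empty((len(starts), f.shape[0]))
    for k, s in enumerate(starts):
        seg = trials[:, s : s + win]
        spec = np.fft.rfft(tapers[:, None, :] * seg[None, :, :], axis=-1)
        power = (spec.real**2 + spec.imag**2) / fs
        power[..., 1:] *= 2.0
        if win % 2 == 0:
            power[..., -1] /= 2.0
        E[k] = power.mean(axis=(0, 1))
    t_centers = t_axis[starts] + win / (2.0 * fs)
    return t_centers, f, E


def baseline_spectrum(
    traces_all_conditions: NDArray[np.float64],
    t_axis: NDArray[np.float64],
    fs: float,
    window: tuple[float, float] = (-0.5, 0.0),
    n_tapers: int = 3,
    nw: float = 2.0,
) -> PowerSpectrum:
    """Condition-pooled baseline PSD B(w).

    All trials of every stimulus condition are pooled into a single baseline
    estimate for the recording site, evaluated in the pre-stimulus window
    (default -500 to 0 ms; the non-simultaneous designs use -200 to 0 ms).
    """
    traces = np.atleast_2d(np.asarray(traces_all_conditions, dtype=float))
    if traces.shape[0] == 0:
        raise ValueError("empty trial set")
    return psd_in_window(traces, t_axis, window, fs, n_tapers=n_tapers, nw=nw)


def tf_difference(
    E: NDArray[np.float64], B: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Baseline-difference map D(t, w) = 10 * (log10 E - log10 B) in dB.

    Population maps are formed by averaging D across sites (on the dB scale).
    """
    E = np.asarray(E, dtype=float)
    B = np.asarray(B, dtype=float)
    if E.ndim != 2 or B.ndim != 1 or E.shape[1] != B.shape[0]:
        raise ValueError("E must be (n_times, n_freqs) and B (n_freqs,)")
    if np.any(E <= 0) or np.any(B <= 0):
        raise ValueError("energies must be strictly positive for dB difference")
    return 10.0 * (np.log10(E) - np.log10(B)[None, :])


def band_power_change(
    stim_psd_by_condition: Mapping[object, PowerSpectrum],
    baseline_psd_by_condition: Mapping[object, PowerSpectrum],
    band: BandDefinition,
) -> list[BandPowerResult]:
    """Per-condition band-power change relative to the condition-mean baseline.

    For each condition i, ST_i = log10 of the stimulus-window power summed
    over the in-band, non-excluded bins; BL_ave is the across-condition mean
    of the analogous log10 baseline sums; delta_db = 10 * (ST_i - BL_ave).
    The exclusion mask is applied identically to both windows.
    """
    keys = list(stim_psd_by_condition.keys())
    if set(keys) != set(baseline_psd_by_condition.keys()):
        raise ValueError("stimulus and baseline conditions must match")
    if not keys:
        raise ValueError("no conditions supplied")
    f = stim_psd_by_condition[keys[0]].f
    mask = band.mask(f)
    if not mask.any():
        raise ValueError(
            f"band {band.lo_hz}-{band.hi_hz} Hz has no included bins"
        )
    st = {}
    bl = {}
    for k in keys:
        ps, pb = stim_psd_by_condition[k], baseline_psd_by_condition[k]
        if not (np.array_equal(ps.f, f) and np.array_equal(pb.f, f)):
            raise ValueError("all spectra must share one frequency grid")
        s_sum = float(np.sum(ps.P[mask]))
        b_sum = float(np.sum(pb.P[mask]))
        if s_sum <= 0 or b_sum <= 0:
            raise ValueError(f"nonpositive band power for condition {k!r}")
        st[k] = np.log10(s_sum)
        bl[k] = np.log10(b_sum)
    bl_ave = float(np.mean([bl[k] for k in keys]))
    return [
        BandPowerResult(
            condition_id=k,
            st=st[k],
            bl=bl[k],
            bl_ave=bl_ave,
            delta_db=10.0 * (st[k] - bl_ave),
        )
        for k in keys
    ]


def change_spectrum(
    stim_psd: PowerSpectrum, baseline_psd: PowerSpectrum
) -> NDArray[np.float64]:
    """Per-frequency change 10 * (log10 P_stim - log10 B) in dB.

    Cross-site averages of change spectra are taken on the dB values
    (i.e. averaged on a log scale).
    """
    if not np.array_equal(stim_psd.f, baseline_psd.f):
        raise ValueError("frequency grids differ")
    if np.any(stim_psd.P <= 0) or np.any(baseline_psd.P <= 0):
        raise ValueError("spectra must be strictly positive for dB change")
    return 10.0 * (np.log10(stim_psd.P) - np.log10(baseline_psd.P))


def time_frequency_map(
    trials: NDArray[np.float64],
    fs: float,
    t_axis: NDArray[np.float64],
    baseline_window: tuple[float, float],
    window_s: float = 0.250,
    step_s: float = 0.025,
    n_tapers: int = 3,
) -> TimeFrequencyMap:
    """Convenience: spectrogram + condition-pooled baseline + dB difference.

    The baseline B(w) is estimated on the spectrogram's own frequency grid by
    averaging spectrogram windows whose extent lies inside the baseline
    window, so E and B are directly comparable.
    """
    t, w, E = spectrogram(trials, fs, t_axis, window_s, step_s, n_tapers)
    half = window_s / 2.0
    in_base = (t - half >= baseline_window[0] - 1e-9) & (
        t + half <= baseline_window[1] + 1e-9
    )
    if not in_base.any():
        raise ValueError("no spectrogram window fits inside the baseline window")
    B = E[in_base].mean(axis=0)
    D = tf_difference(E, B)
    return TimeFrequencyMap(t=t, w=w, E=E, B=B, D=D)
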