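"""High-gamma PSD slope fitting and stimulus-vs-baseline comparison.

The spectrum in the high-gamma range (default 150-250 Hz) is modeled as a
power law, fitted by ordinary least squares on log-log axes:

    log10 P(f) = c - m * log10 f

``m`` is reported as the positive decay exponent (P ~ f^-m gives m > 0).
Line-noise bins are excluded from the fit (for a 50 Hz line the 200 Hz
harmonic falls inside the default band).  Stimulus-window and baseline-window
slopes from the same electrodes are compared with a paired t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from gammatune.spectral import BandDefinition, PowerSpectrum


@dataclass(frozen=True)
class SlopeFit:
    """OLS power-law fit of a PSD over a band.

    m is the decay exponent (positive when power falls with frequency);
    c the intercept in log10 power units; residual_rms the RMS of the
    log10-domain residuals over the included bins.
    """

    m: float
    c: float
    band: tuple[float, float]
    window_label: str
    residual_rms: float
    n_bins: int


@dataclass(frozen=True)
class SlopeComparison:
    """Paired (default) or two-sample comparison of per-site slopes."""

    t: float
    p: float
    mean_stim: float
    mean_base: float
    paired: bool
    degenerate: bool  # zero-variance differences: t/p undefined


def fit_slope(
    psd: PowerSpectrum,
    band: BandDefinition | tuple[float, float] = (150.0, 250.0),
    window_label: str = "stimulus",
    min_bins: int = 5,
) -> SlopeFit:
    """Fit log10 P = c - m log10 f over the included bins of a band.

    Raises if fewer than ``min_bins`` bins are included or if any included
    power is nonpositive.
    """
    if not isinstance(band, BandDefinition):
        band = BandDefinition(*band)
    mask = band.mask(psd.f) & (psd.f > 0)
    if mask.sum() < min_bins:
        raise ValueError(
            f"only {int(mask.sum())} included bins in "
            f"{band.lo_hz}-{band.hi_hz} Hz; need >= {min_bins}"
        )
    P = psd.P[mask]
    if np.any(P <= 0):
        raise ValueError("nonpositive power inside the fit band")
    x = np.log10(psd.f[mask])
    y = np.log10(P)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return SlopeFit(
        m=float(-slope),
        c=float(intercept),
        band=(band.lo_hz, band.hi_hz),
        window_label=window_label,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_bins=int(mask.sum()),
    )


def compare_slopes(
    stim_slopes: Sequence[float],
    base_slopes: Sequence[float],
    paired: bool = True,
) -> SlopeComparison:
    """Compare per-site stimulus and baseline decay exponents.

    Default is a paired t test on per-site differences (the two windows come
    from the same electrodes); ``paired=False`` gives Welch's two-sample
    test.  Zero-variance differences (or zero-variance groups, unpaired) are
    flagged degenerate with NaN statistics.
    """
    s = np.asarray(stim_slopes, dtype=float)
    b = np.asarray(base_slopes, dtype=float)
    if paired and s.shape != b.shape:
        raise ValueError("paired comparison needs equal-length arrays")
    if min(s.size, b.size) < 2:
        raise ValueError("need at least 2 sites per group")
    mean_stim = float(s.mean())
    mean_base = float(b.mean())
    if paired:
        diffs = s - b
        scale = max(1.0, float(np.max(np.abs(diffs))))
        if np.std(diffs, ddof=1) <= 1e-12 * scale:
            return SlopeComparison(math.nan, math.nan, mean_stim, mean_base,
                                   True, True)
        t, p = stats.ttest_rel(s, b)
    else:
        if np.std(s, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            return SlopeComparison(math.nan, math.nan, mean_stim, mean_base,
                                   False, True)
        t, p = stats.ttest_ind(s, b, equal_var=False)
    return SlopeComparison(float(t), float(p), mean_stim, mean_base, paired,
                           False)
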