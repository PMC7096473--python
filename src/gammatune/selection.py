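"""Electrode inclusion filters and bipolar re-referencing.

Sites enter the analyses only if (a) their receptive-field (RF) center
estimates are stable across sessions (SD of the radial deviations < 0.1 deg);
and, for the size study, (b) the RF center lies within 0.2 deg of the
stimulus center, (c) the mean firing rate is at least 1 spike/s for every
stimulus size, and (d) the spike-waveform signal-to-noise ratio exceeds 1.5
(strictly).  Bipolar referencing subtracts a neighboring electrode's trace to
cancel components common to both electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray


@dataclass(frozen=True)
class SiteMetrics:
    """Per-site quantities entering the selection filters (all >= 0)."""

    site_id: object
    mean_rate_by_condition: tuple[float, ...]
    snr: float
    rf_sd_deg: float
    rf_distance_deg: float

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.mean_rate_by_condition)
        if any(r < 0 for r in rates):
            raise ValueError("firing rates must be nonnegative")
        if self.snr < 0 or self.rf_sd_deg < 0 or self.rf_distance_deg < 0:
            raise ValueError("metrics must be nonnegative")
        object.__setattr__(self, "mean_rate_by_condition", rates)


@dataclass(frozen=True)
class SelectionThresholds:
    """Inclusion thresholds; inequality strictness follows the stated rules:
    rf_sd strictly below, rf_distance at most, rate at least, snr strictly
    above."""

    rf_sd_max_deg: float = 0.1
    rf_distance_max_deg: float = 0.2
    min_rate_spikes_s: float = 1.0
    min_snr: float = 1.5


@dataclass(frozen=True)
class SiteDecision:
    site_id: object
    included: bool
    reasons: tuple[str, ...]  # machine-readable exclusion reasons


def firing_rate(
    spike_times_by_trial: Sequence[Sequence[float]],
    window: tuple[float, float],
) -> float:
    """Trial-mean spike count in the window divided by the window length (s)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if len(spike_times_by_trial) == 0:
        raise ValueError("no trials")
    counts = [
        int(np.sum((np.asarray(st, dtype=float) >= t0)
                   & (np.asarray(st, dtype=float) < t1)))
        for st in spike_times_by_trial
    ]
    return float(np.mean(counts)) / (t1 - t0)


def waveform_snr(snippets: NDArray[np.float64]) -> float:
    """Spike-waveform SNR: peak-to-peak of the mean snippet over twice the
    residual SD.

    Residuals are the snippets after subtracting the mean snippet.  With
    identical snippets the residual SD is 0 and the SNR is reported as
    ``inf`` (degenerate, noise-free).
    """
    arr = np.atleast_2d(np.asarray(snippets, dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 snippets")
    mean_wave = arr.mean(axis=0)
    p2p = float(mean_wave.max() - mean_wave.min())
    resid_sd = float((arr - mean_wave).std())
    if resid_sd == 0:
        return math.inf
    return p2p / (2.0 * resid_sd)


def select_sites(
    metrics: Sequence[SiteMetrics],
    thresholds: SelectionThresholds = SelectionThresholds(),
    size_study: bool = True,
) -> list[SiteDecision]:
    """Deterministic inclusion decisions with per-site exclusion reasons.

    The RF-stability filter applies to every study; the RF-distance, firing-
    rate and SNR filters apply only to the size study (full-screen studies
    use all RF-stable sites).  The rate filter requires the minimum rate over
    conditions to pass, i.e. the criterion holds for all stimulus sizes.
    """
    decisions = []
    for m in metrics:
        reasons: list[str] = []
        if not m.rf_sd_deg < thresholds.rf_sd_max_deg:
            reasons.append("rf_sd")
        if size_study:
            if not m.rf_distance_deg <= thresholds.rf_distance_max_deg:
                reasons.append("rf_distance")
            if not (
                m.mean_rate_by_condition
                and min(m.mean_rate_by_condition) >= thresholds.min_rate_spikes_s
            ):
                reasons.append("rate")
            if not m.snr > thresholds.min_snr:
                reasons.append("snr")
        decisions.append(
            SiteDecision(m.site_id, included=not reasons,
                         reasons=tuple(reasons))
        )
    return decisions


def rf_stability_sd(
    estimates_deg: Sequence[tuple[float, float]]
) -> float:
    """SD of the radial deviations of per-session RF-center estimates from
    their mean position, in degrees."""
    pts = np.asarray(estimates_deg, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 two-dimensional estimates")
    dev = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    return float(np.sqrt(np.mean(dev**2)))


def bipolar_reference(
    trace_a: NDArray[np.float64], trace_b: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Elementwise difference a - b of two equal-length traces.

    Components common to both electrodes (shared oscillations, line noise)
    cancel; downstream analyses accept the difference transparently.
    Antisymmetric: bipolar(a, b) == -bipolar(b, a).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have identical shapes")
    return a - b
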