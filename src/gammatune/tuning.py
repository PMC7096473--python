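"""Tuning curves and circular orientation statistics.

Orientation is an axial (180-degree periodic) quantity, so circular
statistics operate on doubled angles.  With per-orientation band powers R_i
at orientations theta_i:

    preferred = 0.5 * atan2( sum_i R_i sin 2*theta_i,
                             sum_i R_i cos 2*theta_i )   mod 180

    selectivity = | sum_i R_i exp(j 2*theta_i) | / sum_i R_i

Selectivity is 0 for a flat profile on an evenly spaced grid and 1 when a
single orientation carries all the power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from gammatune.spectral import BandDefinition

#: Relative resultant length below which the preferred orientation is
#: considered undefined (perfectly balanced profile).
_RESULTANT_TOL = 1e-12


@dataclass(frozen=True)
class TuningCurve:
    """Band-power change (dB) as a function of one stimulus parameter."""

    parameter: str
    x: NDArray[np.float64]
    y: NDArray[np.float64]
    band: BandDefinition
    site_id: object = None
    signal_class: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and of equal length")
        if self.parameter != "orientation_deg" and np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class OrientationTuning:
    """Per-orientation band powers with derived circular statistics."""

    theta_deg: NDArray[np.float64]
    R: NDArray[np.float64]
    preferred_deg: float  # NaN when the doubled-angle resultant vanishes
    selectivity: float

    @property
    def preferred_defined(self) -> bool:
        return not math.isnan(self.preferred_deg)


@dataclass(frozen=True)
class PeakEstimate:
    """Location of the maximum baseline-corrected change within a band."""

    peak_hz: float
    peak_db: float
    band: BandDefinition
    on_edge: bool


def _doubled_angle_resultant(
    R: NDArray[np.float64], theta_deg: NDArray[np.float64]
) -> complex:
    theta2 = 2.0 * np.deg2rad(theta_deg)
    return complex(np.sum(R * np.cos(theta2)), np.sum(R * np.sin(theta2)))


def _validate_R_theta(R, theta_deg):
    R = np.asarray(R, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if R.shape != theta.shape or R.ndim != 1:
        raise ValueError("R and theta must be 1-D and of equal length")
    if np.any(R < 0):
        raise ValueError("band powers R must be nonnegative")
    if len(set(np.round(theta % 180.0, 9))) != len(theta):
        raise ValueError("orientations must be distinct axial angles")
    return R, theta


def preferred_orientation(
    R: Sequence[float], theta_deg: Sequence[float]
) -> float:
    """Axial circular mean of orientations weighted by band power, in [0, 180).

    Returns NaN when the doubled-angle resultant vector is (numerically)
    zero, e.g. for a perfectly uniform profile on an evenly spaced grid: the
    preferred orientation is then undefined.
    """
    R, theta = _validate_R_theta(R, theta_deg)
    total = float(R.sum())
    if total == 0:
        raise ValueError("R must not be all zero")
    z = _doubled_angle_resultant(R, theta)
    if abs(z) <= _RESULTANT_TOL * total:
        return math.nan
    return math.degrees(0.5 * math.atan2(z.imag, z.real)) % 180.0


def orientation_selectivity(
    R: Sequence[float], theta_deg: Sequence[float]
) -> float:
    """Normalized doubled-angle resultant length, in [0, 1]."""
    R, theta = _validate_R_theta(R, theta_deg)
    total = float(R.sum())
    if total == 0:
        raise ValueError("sum of R is zero; selectivity undefined")
    return abs(_doubled_angle_resultant(R, theta)) / total


def orientation_tuning(
    R: Sequence[float], theta_deg: Sequence[float]
) -> OrientationTuning:
    """Bundle per-orientation powers with preferred orientation and selectivity."""
    Ra, theta = _validate_R_theta(R, theta_deg)
    return OrientationTuning(
        theta_deg=theta,
        R=Ra,
        preferred_deg=preferred_orientation(Ra, theta),
        selectivity=orientation_selectivity(Ra, theta),
    )


def axial_distance_deg(a: float, b: float) -> float:
    """Smallest distance between two axial angles, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def gamma_peak(
    f: Sequence[float],
    change_db: Sequence[float],
    band: BandDefinition,
) -> PeakEstimate:
    """Frequency of the maximum baseline-corrected change within a band.

    Ties break toward the lower frequency (conservative given the 1/f
    background).  A maximizer at the lowest or highest included bin is
    flagged ``on_edge``: the peak may lie outside the band.
    """
    f = np.asarray(f, dtype=float)
    change_db = np.asarray(change_db, dtype=float)
    mask = band.mask(f)
    if not mask.any():
        raise ValueError("band contains no frequency bins of the spectrum")
    fi = f[mask]
    ci = change_db[mask]
    k = int(np.argmax(ci))  # argmax returns the first (lowest-f) maximizer
    return PeakEstimate(
        peak_hz=float(fi[k]),
        peak_db=float(ci[k]),
        band=band,
        on_edge=(k == 0 or k == len(fi) - 1),
    )


def salient_peaks(
    f: Sequence[float],
    change_db_by_value: Mapping[float, Sequence[float]],
    band: BandDefinition,
    min_salience_db: float = 1.0,
) -> dict[float, PeakEstimate]:
    """Peak-frequency estimates restricted to conditions with salient peaks.

    A peak is salient when its dB change exceeds the median in-band change
    by at least ``min_salience_db``; conditions without a salient peak (e.g.
    very low contrasts, where no clear gamma bump exists) are dropped rather
    than reported at an arbitrary frequency.
    """
    f = np.asarray(f, dtype=float)
    mask = band.mask(f)
    out: dict[float, PeakEstimate] = {}
    for value, change in change_db_by_value.items():
        change = np.asarray(change, dtype=float)
        pk = gamma_peak(f, change, band)
        if pk.peak_db >= float(np.median(change[mask])) + min_salience_db:
            out[value] = pk
    return out


def compare_tuning(
    y_a: Sequence[float], y_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between two tuning curves on a common grid.

    Returns (r, p) with a two-sided p-value from the t distribution with
    n - 2 degrees of freedom.  If either curve has zero variance, r is
    undefined and (nan, nan) is returned.
    """
    a = np.asarray(y_a, dtype=float)
    b = np.asarray(y_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be 1-D and on the same grid")
    if a.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return (math.nan, math.nan)
    res = stats.pearsonr(a, b)
    return (float(res.statistic), float(res.pvalue))


def bootstrap_median_se(
    values: Sequence[float], n_boot: int = 10_000, seed: int = 0
) -> float:
    """Bootstrap standard error of the median.

    Resamples with replacement ``n_boot`` times using
    ``numpy.random.default_rng(seed)`` drawing index arrays with
    ``rng.integers``, and returns the sample SD (ddof=1) of the resampled
    medians.  Deterministic for a fixed seed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    medians = np.median(v[idx], axis=1)
    return float(np.std(medians, ddof=1))


def tuning_over_parameter(
    delta_by_condition: Mapping[float, float],
    parameter: str,
    band: BandDefinition,
    expected_values: Sequence[float] | None = None,
    site_id: object = None,
    signal_class: str | None = None,
) -> TuningCurve:
    """Assemble a per-site tuning curve from per-condition dB changes.

    ``delta_by_condition`` maps each value of the varied stimulus parameter
    (radius, orientation, SF or contrast) to its band-power change in dB; for
    the size study the caller pools trials across orientations before
    computing the per-radius change.  ``expected_values``, when given, lists
    the parameter values the design requires; a missing one raises.
    """
    if expected_values is not None:
        missing = [v for v in expected_values if v not in delta_by_condition]
        if missing:
            raise ValueError(f"missing conditions for {parameter}: {missing}")
    x = np.array(sorted(delta_by_condition.keys()), dtype=float)
    y = np.array([delta_by_condition[v] for v in sorted(delta_by_condition)])
    return TuningCurve(parameter=parameter, x=x, y=y, band=band,
                       site_id=site_id, signal_class=signal_class)


def average_tuning_curves(
    curves: Sequence[TuningCurve],
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Cross-site mean tuning curve with SEM.

    All curves must share the same x grid.  Returns (x, mean, sem); SEM is 0
    for a single site.
    """
    if not curves:
        raise ValueError("no curves to average")
    x = curves[0].x
    for c in curves[1:]:
        if not np.array_equal(c.x, x):
            raise ValueError("tuning curves are on different parameter grids")
    Y = np.stack([c.y for c in curves])
    mean = Y.mean(axis=0)
    sem = (
        Y.std(axis=0, ddof=1) / np.sqrt(len(curves))
        if len(curves) > 1
        else np.zeros_like(mean)
    )
    return x, mean, sem
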