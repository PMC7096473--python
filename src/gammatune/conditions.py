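"""Stimulus conditions and study presets.

A condition is one grating parameter tuple (radius, orientation, spatial
frequency, contrast, temporal frequency).  Six named study designs are
provided, each a full crossed grid together with the analysis windows, bands
and line frequency used for that design.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Union

#: Sentinel radius for full-screen gratings (infinite extent).
FULLSCREEN = math.inf


class StudyKind(str, enum.Enum):
    """Named experimental designs."""

    size_M12 = "size_M12"
    size_M34 = "size_M34"
    orientation = "orientation"
    spatial_frequency = "spatial_frequency"
    contrast_M3 = "contrast_M3"
    contrast_M4 = "contrast_M4"


@dataclass(frozen=True)
class StimulusCondition:
    """One grating stimulus.

    Parameters
    ----------
    radius_deg:
        Grating radius in degrees of visual angle; ``math.inf`` (or the
        string ``"fullscreen"``) denotes a full-screen grating.
    orientation_deg:
        Axial orientation, stored modulo 180.
    sf_cpd:
        Spatial frequency in cycles per degree (> 0).
    contrast_pct:
        Michelson contrast in percent, 0-100.  Contrast 0 is a blank screen:
        no stimulus-driven signal components.
    tf_cps:
        Temporal frequency in cycles per second (0 = static grating).
    """

    radius_deg: float
    orientation_deg: float
    sf_cpd: float
    contrast_pct: float
    tf_cps: float = 0.0

    def __post_init__(self) -> None:
        radius: Union[float, str] = self.radius_deg
        if isinstance(radius, str):
            if radius.lower() != "fullscreen":
                raise ValueError(f"unknown radius label {radius!r}")
            object.__setattr__(self, "radius_deg", FULLSCREEN)
        elif radius <= 0:
            raise ValueError("radius_deg must be positive (or fullscreen)")
        object.__setattr__(
            self, "orientation_deg", float(self.orientation_deg) % 180.0
        )
        if self.sf_cpd <= 0:
            raise ValueError("sf_cpd must be > 0")
        if not 0.0 <= self.contrast_pct <= 100.0:
            raise ValueError("contrast_pct must lie in [0, 100]")
        if self.tf_cps < 0:
            raise ValueError("tf_cps must be >= 0")

    @property
    def is_fullscreen(self) -> bool:
        return math.isinf(self.radius_deg)

    @property
    def is_blank(self) -> bool:
        return self.contrast_pct == 0.0


@dataclass(frozen=True)
class StudyPreset:
    """Analysis settings associated with a study design.

    Windows are (start, stop) in seconds relative to stimulus onset; bands
    are (lo, hi) in Hz.  ``slope_stim_window`` is the stimulus window used
    for the high-gamma PSD slope fit, which is shorter than the band-power
    stimulus window for the simultaneous-recording designs.
    """

    study: StudyKind
    baseline_window: tuple[float, float]
    stim_window: tuple[float, float]
    gamma_band: tuple[float, float]
    high_gamma_band: tuple[float, float]
    line_hz: float
    slope_stim_window: tuple[float, float]
    parameter: str  # which condition field the study varies


_ORI_8 = tuple(22.5 * k for k in range(8))
_ORI_6 = tuple(30.0 * k for k in range(6))

_PRESETS: dict[StudyKind, StudyPreset] = {
    StudyKind.size_M12: StudyPreset(
        StudyKind.size_M12, (-0.2, 0.0), (0.2, 0.4), (30.0, 65.0),
        (150.0, 250.0), 60.0, (0.2, 0.4), "radius_deg",
    ),
    StudyKind.size_M34: StudyPreset(
        StudyKind.size_M34, (-0.5, 0.0), (0.25, 0.75), (30.0, 65.0),
        (150.0, 250.0), 50.0, (0.25, 0.5), "radius_deg",
    ),
    StudyKind.orientation: StudyPreset(
        StudyKind.orientation, (-0.5, 0.0), (0.25, 0.75), (45.0, 70.0),
        (150.0, 250.0), 50.0, (0.25, 0.5), "orientation_deg",
    ),
    StudyKind.spatial_frequency: StudyPreset(
        StudyKind.spatial_frequency, (-0.5, 0.0), (0.25, 0.75), (45.0, 70.0),
        (150.0, 250.0), 50.0, (0.25, 0.5), "sf_cpd",
    ),
    StudyKind.contrast_M3: StudyPreset(
        StudyKind.contrast_M3, (-0.5, 0.0), (0.25, 0.75), (20.0, 75.0),
        (150.0, 250.0), 50.0, (0.25, 0.5), "contrast_pct",
    ),
    StudyKind.contrast_M4: StudyPreset(
        StudyKind.contrast_M4, (-0.5, 0.0), (0.25, 0.75), (20.0, 75.0),
        (150.0, 250.0), 50.0, (0.25, 0.5), "contrast_pct",
    ),
}


def _coerce_study(study: Union[str, StudyKind]) -> StudyKind:
    try:
        return StudyKind(study)
    except ValueError:
        names = ", ".join(s.value for s in StudyKind)
        raise ValueError(f"unknown study {study!r}; expected one of: {names}")


def study_preset(study: Union[str, StudyKind]) -> StudyPreset:
    """Return the analysis preset (windows, bands, line frequency) for a design."""
    return _PRESETS[_coerce_study(study)]


def make_condition_grid(study: Union[str, StudyKind]) -> list[StimulusCondition]:
    """Full crossed stimulus grid for one of the six named designs.

    size_M12:  6 radii {0.3,0.72,1.14,1.56,1.98,2.40} deg x 6 orientations
               {0,30,...,150} deg, 4 cpd, 100% contrast.
    size_M34:  6 radii {0.3,0.6,1.2,2.4,4.8,9.6} deg x 8 orientations
               {0,22.5,...,157.5} deg, 4 cpd, 100% contrast.
    orientation: full-screen, 8 orientations, 4 cpd, 100% contrast.
    spatial_frequency: full-screen, 90 deg, SFs {0.5,1,2,4,8} cpd, 100%.
    contrast_M3: full-screen, 90 deg, 4 cpd, contrasts
               {100,50,25,12.5,6.25,3.125,0}%.
    contrast_M4: full-screen, 90 deg, 2 cpd, contrasts
               {100,50,25,12.5,6.25,0}%.
    """
    kind = _coerce_study(study)
    if kind is StudyKind.size_M12:
        radii = (0.3, 0.72, 1.14, 1.56, 1.98, 2.40)
        return [
            StimulusCondition(r, o, 4.0, 100.0)
            for r in radii for o in _ORI_6
        ]
    if kind is StudyKind.size_M34:
        radii = (0.3, 0.6, 1.2, 2.4, 4.8, 9.6)
        return [
            StimulusCondition(r, o, 4.0, 100.0)
            for r in radii for o in _ORI_8
        ]
    if kind is StudyKind.orientation:
        return [StimulusCondition(FULLSCREEN, o, 4.0, 100.0) for o in _ORI_8]
    if kind is StudyKind.spatial_frequency:
        return [
            StimulusCondition(FULLSCREEN, 90.0, sf, 100.0)
            for sf in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
    if kind is StudyKind.contrast_M3:
        return [
            StimulusCondition(FULLSCREEN, 90.0, 4.0, c)
            for c in (100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 0.0)
        ]
    if kind is StudyKind.contrast_M4:
        return [
            StimulusCondition(FULLSCREEN, 90.0, 2.0, c)
            for c in (100.0, 50.0, 25.0, 12.5, 6.25, 0.0)
        ]
    raise AssertionError("unreachable")
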