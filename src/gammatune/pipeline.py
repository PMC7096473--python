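"""Study-level orchestration: simulate/load -> select -> spectra -> tables.

A :class:`StudyConfig` names one of the six designs and carries every
analysis setting (bands, windows, line frequency, selection thresholds,
simulator inputs).  Unspecified settings are filled from the design preset.
:func:`run_study` executes the full chain on synthetic or same-schema real
data and writes CSV/JSON outputs plus a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gammatune import io as gio
from gammatune.conditions import (
    StimulusCondition,
    StudyKind,
    make_condition_grid,
    study_preset,
)
from gammatune.psd_slope import SlopeComparison, SlopeFit, compare_slopes, fit_slope
from gammatune.selection import (
    SelectionThresholds,
    SiteDecision,
    SiteMetrics,
    firing_rate,
    rf_stability_sd,
    select_sites,
    waveform_snr,
)
from gammatune.simulate import (
    ChannelSpec,
    TrialSet,
    TuningMapParams,
    default_params,
    simulate_session,
)
from gammatune.spectral import (
    BandDefinition,
    band_power_change,
    baseline_spectrum,
    change_spectrum,
    line_exclusions,
    psd_in_window,
)
from gammatune.tuning import (
    TuningCurve,
    average_tuning_curves,
    compare_tuning,
    gamma_peak,
    orientation_tuning,
    tuning_over_parameter,
)

logger = logging.getLogger("gammatune")


class ConfigError(ValueError):
    """Raised by :func:`validate_config`; ``errors`` lists (field, message)."""

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        msg = "; ".join(f"{f}: {m}" for f, m in errors)
        super().__init__(f"invalid study configuration: {msg}")


@dataclass
class StudyConfig:
    """Configuration of one study run.

    Fields left as ``None`` are filled from the design preset by
    :func:`validate_config`.  ``grid_mode`` is ``"full"`` for the complete
    crossed stimulus grid or ``"parameter_only"`` for one condition per value
    of the varied parameter (other parameters at their preferred values),
    which is the natural grid when only the study parameter matters.
    """

    study: StudyKind | str
    seed: int = 0
    n_repeats: int = 20
    out_dir: str | Path | None = None
    input_path: str | Path | None = None
    # simulator settings (ignored when input_path is given)
    n_lfp: int = 1
    n_ecog: int = 1
    shared_gamma_fraction: float = 0.5
    grid_mode: str = "parameter_only"
    lfp_params: TuningMapParams | None = None
    ecog_params: TuningMapParams | None = None
    # analysis settings (None -> preset default)
    gamma_band: tuple[float, float] | None = None
    high_gamma_band: tuple[float, float] | None = None
    baseline_window: tuple[float, float] | None = None
    stim_window: tuple[float, float] | None = None
    slope_stim_window: tuple[float, float] | None = None
    line_hz: float | None = None
    line_halfwidth_hz: float = 2.0
    fs_hz: float = 2000.0
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    apply_selection: bool | None = None  # None -> size studies only


def validate_config(config: StudyConfig | Mapping) -> StudyConfig:
    """Normalize a configuration, filling preset defaults; raises ConfigError
    with the full list of problems if any field is inconsistent."""
    if isinstance(config, Mapping):
        known = {f.name for f in dataclasses.fields(StudyConfig)}
        errors = [
            (k, "unknown configuration key") for k in config if k not in known
        ]
        if errors:
            raise ConfigError(errors)
        kwargs = dict(config)
        if isinstance(kwargs.get("thresholds"), Mapping):
            kwargs["thresholds"] = SelectionThresholds(**kwargs["thresholds"])
        for key in ("lfp_params", "ecog_params"):
            if isinstance(kwargs.get(key), Mapping):
                kwargs[key] = TuningMapParams(**kwargs[key])
        config = StudyConfig(**kwargs)
    cfg = dataclasses.replace(config)
    errors: list[tuple[str, str]] = []
    try:
        cfg.study = StudyKind(cfg.study)
    except ValueError:
        errors.append(("study", f"unknown study {cfg.study!r}"))
        raise ConfigError(errors)
    preset = study_preset(cfg.study)

    cfg.gamma_band = tuple(cfg.gamma_band or preset.gamma_band)
    cfg.high_gamma_band = tuple(cfg.high_gamma_band or preset.high_gamma_band)
    cfg.baseline_window = tuple(cfg.baseline_window or preset.baseline_window)
    cfg.stim_window = tuple(cfg.stim_window or preset.stim_window)
    cfg.slope_stim_window = tuple(
        cfg.slope_stim_window or preset.slope_stim_window
    )
    if cfg.line_hz is None:
        cfg.line_hz = preset.line_hz

    for name in ("gamma_band", "high_gamma_band"):
        lo, hi = getattr(cfg, name)
        if not lo < hi:
            errors.append((name, f"band lo ({lo}) must be < hi ({hi})"))
        elif hi > cfg.fs_hz / 2:
            errors.append((name, f"band hi ({hi}) exceeds Nyquist"))
    for name in ("baseline_window", "stim_window", "slope_stim_window"):
        t0, t1 = getattr(cfg, name)
        if not t0 < t1:
            errors.append((name, f"window start ({t0}) must precede stop ({t1})"))
    if cfg.n_repeats < 1:
        errors.append(("n_repeats", "must be >= 1"))
    if not 0.0 <= cfg.shared_gamma_fraction <= 1.0:
        errors.append(("shared_gamma_fraction", "must lie in [0, 1]"))
    if cfg.grid_mode not in ("full", "parameter_only"):
        errors.append(("grid_mode", "must be 'full' or 'parameter_only'"))
    if cfg.line_hz is not None and cfg.line_hz <= 0:
        errors.append(("line_hz", "must be positive"))
    if cfg.input_path is None and (cfg.n_lfp + cfg.n_ecog) < 1:
        errors.append(("n_lfp", "need at least one channel"))
    if errors:
        raise ConfigError(errors)

    if cfg.apply_selection is None:
        cfg.apply_selection = cfg.study in (StudyKind.size_M12, StudyKind.size_M34)
    if cfg.lfp_params is None:
        cfg.lfp_params = default_params("LFP", line_hz=cfg.line_hz)
    if cfg.ecog_params is None:
        cfg.ecog_params = default_params("ECoG", line_hz=cfg.line_hz)
    return cfg


def _parameter_only_grid(study: StudyKind) -> list[StimulusCondition]:
    """One condition per value of the varied parameter.

    For the size designs the full grid crosses radius with orientation and
    the analysis pools trials across orientations per radius; the reduced
    grid instead presents each radius at the preferred orientation (90 deg).
    The full-screen designs already vary a single parameter.
    """
    preset = study_preset(study)
    full = make_condition_grid(study)
    if preset.parameter != "radius_deg":
        return full
    radii = sorted({c.radius_deg for c in full})
    proto = full[0]
    return [
        StimulusCondition(r, 90.0, proto.sf_cpd, proto.contrast_pct)
        for r in radii
    ]


def _group_trials(
    ts: TrialSet, parameter: str
) -> dict[float, np.ndarray]:
    """Trial indices grouped by the varied parameter value (pooling any other
    parameters, e.g. orientations within a radius for the size study)."""
    groups: dict[float, list[int]] = {}
    for i, cond in enumerate(ts.conditions):
        groups.setdefault(float(getattr(cond, parameter)), []).append(i)
    return {k: np.asarray(v, dtype=np.intp) for k, v in sorted(groups.items())}


@dataclass
class SiteAnalysis:
    """Per-site spectra, band-power changes and slopes."""

    channel_id: str
    signal_class: str
    gamma_curve: TuningCurve
    high_gamma_curve: TuningCurve
    gamma_results: list
    high_gamma_results: list
    orientation: object | None  # OrientationTuning for orientation designs
    slope_stim: SlopeFit | None
    slope_base: SlopeFit | None
    change_spectra: dict[float, np.ndarray]
    freq_grid: np.ndarray


def analyze_trialset(ts: TrialSet, cfg: StudyConfig) -> SiteAnalysis:
    """Run the spectral chain for one channel."""
    preset = study_preset(cfg.study)
    parameter = preset.parameter
    nyq = ts.fs_hz / 2.0
    gamma = BandDefinition(
        *cfg.gamma_band,
        exclusions=line_exclusions(cfg.line_hz, cfg.gamma_band[1],
                                   cfg.line_halfwidth_hz),
    )
    high_gamma = BandDefinition(
        *cfg.high_gamma_band,
        exclusions=line_exclusions(cfg.line_hz, cfg.high_gamma_band[1],
                                   cfg.line_halfwidth_hz),
    )
    groups = _group_trials(ts, parameter)

    stim_psds = {}
    base_psds = {}
    for value, idx in groups.items():
        stim_psds[value] = psd_in_window(
            ts.traces[idx], ts.t_axis, cfg.stim_window, ts.fs_hz
        )
        base_psds[value] = psd_in_window(
            ts.traces[idx], ts.t_axis, cfg.baseline_window, ts.fs_hz
        )
    pooled_base = baseline_spectrum(
        ts.traces, ts.t_axis, ts.fs_hz, window=cfg.baseline_window
    )

    gamma_results = band_power_change(stim_psds, base_psds, gamma)
    hg_results = band_power_change(stim_psds, base_psds, high_gamma)

    def curve(results, band):
        return tuning_over_parameter(
            {r.condition_id: r.delta_db for r in results},
            parameter,
            band,
            site_id=ts.channel_id,
            signal_class=ts.signal_class,
        )

    orientation = None
    if parameter == "orientation_deg":
        # R_i: linear stimulus-window power summed over the gamma band
        thetas = sorted(groups)
        R = [10.0 ** next(r.st for r in gamma_results if r.condition_id == th)
             for th in thetas]
        orientation = orientation_tuning(R, thetas)

    slope_stim = slope_base = None
    if parameter == "radius_deg":
        smallest = min(groups)
        idx = groups[smallest]
        slope_band = BandDefinition(
            *cfg.high_gamma_band,
            exclusions=line_exclusions(cfg.line_hz, cfg.high_gamma_band[1],
                                       cfg.line_halfwidth_hz),
        )
        psd_s = psd_in_window(
            ts.traces[idx], ts.t_axis, cfg.slope_stim_window, ts.fs_hz
        )
        psd_b = psd_in_window(
            ts.traces[idx], ts.t_axis, cfg.baseline_window, ts.fs_hz
        )
        slope_stim = fit_slope(psd_s, slope_band, window_label="stimulus")
        slope_base = fit_slope(psd_b, slope_band, window_label="baseline")

    spectra = {
        value: change_spectrum(stim_psds[value], _on_grid(pooled_base, stim_psds[value]))
        for value in groups
    }
    return SiteAnalysis(
        channel_id=ts.channel_id,
        signal_class=ts.signal_class,
        gamma_curve=curve(gamma_results, gamma),
        high_gamma_curve=curve(hg_results, high_gamma),
        gamma_results=gamma_results,
        high_gamma_results=hg_results,
        orientation=orientation,
        slope_stim=slope_stim,
        slope_base=slope_base,
        change_spectra=spectra,
        freq_grid=stim_psds[min(groups)].f,
    )


def _on_grid(pooled_base, stim_psd):
    """Pooled baseline resampled to the stimulus-window frequency grid.

    The baseline window can be longer than the stimulus window (finer
    Rayleigh grid); band sums always use matched-window spectra, and the
    per-frequency change spectrum interpolates the pooled baseline onto the
    stimulus grid in the power domain.
    """
    from gammatune.spectral import PowerSpectrum

    if np.array_equal(pooled_base.f, stim_psd.f):
        return pooled_base
    P = np.interp(stim_psd.f, pooled_base.f, pooled_base.P)
    return PowerSpectrum(f=stim_psd.f, P=P, n_trials=pooled_base.n_trials,
                         window=pooled_base.window)


def site_metrics_for(ts: TrialSet, cfg: StudyConfig) -> SiteMetrics:
    """Selection metrics for one channel (rate, SNR, RF stability/distance).

    The RF-to-stimulus distance assumes the stimulus is centered on the
    channel's true RF center plus the offset of its mean session estimate --
    i.e. the stimulus is placed at the origin-referenced RF; real data would
    supply the actual stimulus center.
    """
    preset = study_preset(cfg.study)
    rates = tuple(
        firing_rate([ts.spikes[i] for i in idx], cfg.stim_window)
        for idx in _group_trials(ts, preset.parameter).values()
    )
    snr = waveform_snr(ts.snippets) if ts.snippets is not None else math.inf
    if ts.rf_center_per_session is not None and len(ts.rf_center_per_session) > 1:
        rf_sd = rf_stability_sd([tuple(p) for p in ts.rf_center_per_session])
        mean_est = np.mean(ts.rf_center_per_session, axis=0)
    else:
        rf_sd = 0.0
        mean_est = np.asarray(ts.rf_center_deg, dtype=float)
    rf_distance = float(np.linalg.norm(mean_est - np.asarray((0.0, 0.0))))
    return SiteMetrics(
        site_id=ts.channel_id,
        mean_rate_by_condition=rates,
        snr=snr,
        rf_sd_deg=rf_sd,
        rf_distance_deg=rf_distance,
    )


@dataclass
class StudyResult:
    """Everything a study run produces, plus output file paths if written."""

    config: StudyConfig
    trialsets: list[TrialSet]
    decisions: list[SiteDecision]
    sites: list[SiteAnalysis]
    band_power: pd.DataFrame
    tuning: pd.DataFrame
    orientation: pd.DataFrame | None
    slopes: pd.DataFrame | None
    slope_comparison: dict[str, SlopeComparison] | None
    comparison: pd.DataFrame
    manifest: dict
    output_files: list[Path] = field(default_factory=list)


def _simulate_inputs(cfg: StudyConfig) -> list[TrialSet]:
    grid = (
        make_condition_grid(cfg.study)
        if cfg.grid_mode == "full"
        else _parameter_only_grid(StudyKind(cfg.study))
    )
    channels = [
        ChannelSpec("LFP", cfg.lfp_params) for _ in range(cfg.n_lfp)
    ] + [
        ChannelSpec("ECoG", cfg.ecog_params) for _ in range(cfg.n_ecog)
    ]
    return simulate_session(
        grid,
        cfg.n_repeats,
        channels,
        shared_gamma_fraction=cfg.shared_gamma_fraction,
        seed=cfg.seed,
        fs=cfg.fs_hz,
    )


def _class_mean_curves(
    sites: Sequence[SiteAnalysis], which: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_class: dict[str, list[TuningCurve]] = {}
    for s in sites:
        by_class.setdefault(s.signal_class, []).append(getattr(s, which))
    out = {}
    for cls, curves in by_class.items():
        x, mean, _ = average_tuning_curves(curves)
        out[cls] = (x, mean)
    return out


def run_study(config: StudyConfig | Mapping) -> StudyResult:
    """Execute a study end to end; deterministic under fixed seed + config."""
    cfg = validate_config(config)
    preset = study_preset(cfg.study)
    t0 = time.perf_counter()

    if cfg.input_path is not None:
        trialsets = gio.read_session(cfg.input_path)
        logger.info("loaded %d channels from %s", len(trialsets), cfg.input_path)
    else:
        trialsets = _simulate_inputs(cfg)
        logger.info("simulated %d channels (seed %d)", len(trialsets), cfg.seed)

    metrics = [site_metrics_for(ts, cfg) for ts in trialsets]
    decisions = select_sites(
        metrics, cfg.thresholds, size_study=bool(cfg.apply_selection)
    )
    included_ids = {d.site_id for d in decisions if d.included}
    analyzed = [ts for ts in trialsets if ts.channel_id in included_ids]
    if not analyzed:
        raise RuntimeError("selection stage excluded every site")
    logger.info("selection kept %d/%d sites", len(analyzed), len(trialsets))

    try:
        sites = [analyze_trialset(ts, cfg) for ts in analyzed]
    except Exception as exc:  # pragma: no cover - defensive re-raise
        raise RuntimeError(f"spectral stage failed: {exc}") from exc

    rows = []
    for s in sites:
        for band_name, results in (
            ("gamma", s.gamma_results),
            ("high_gamma", s.high_gamma_results),
        ):
            for r in results:
                rows.append(
                    dict(
                        site=s.channel_id,
                        signal_class=s.signal_class,
                        parameter=preset.parameter,
                        value=r.condition_id,
                        band=band_name,
                        st_log10=r.st,
                        bl_log10=r.bl,
                        bl_ave_log10=r.bl_ave,
                        delta_db=r.delta_db,
                    )
                )
    band_power = pd.DataFrame(rows)

    tuning_rows = []
    for s in sites:
        for band_name, curve in (
            ("gamma", s.gamma_curve),
            ("high_gamma", s.high_gamma_curve),
        ):
            for x, y in zip(curve.x, curve.y):
                tuning_rows.append(
                    dict(
                        site=s.channel_id,
                        signal_class=s.signal_class,
                        parameter=preset.parameter,
                        value=x,
                        band=band_name,
                        delta_db=y,
                    )
                )
    tuning = pd.DataFrame(tuning_rows)

    orientation_df = None
    if preset.parameter == "orientation_deg":
        orientation_df = pd.DataFrame(
            [
                dict(
                    site=s.channel_id,
                    signal_class=s.signal_class,
                    preferred_deg=s.orientation.preferred_deg,
                    selectivity=s.orientation.selectivity,
                )
                for s in sites
            ]
        )

    slopes_df = None
    slope_cmp = None
    if preset.parameter == "radius_deg":
        slope_rows = []
        for s in sites:
            for fit in (s.slope_stim, s.slope_base):
                slope_rows.append(
                    dict(
                        site=s.channel_id,
                        signal_class=s.signal_class,
                        window_label=fit.window_label,
                        m=fit.m,
                        c=fit.c,
                        residual_rms=fit.residual_rms,
                    )
                )
        slopes_df = pd.DataFrame(slope_rows)
        slope_cmp = {}
        for cls in sorted({s.signal_class for s in sites}):
            stim = [s.slope_stim.m for s in sites if s.signal_class == cls]
            base = [s.slope_base.m for s in sites if s.signal_class == cls]
            if len(stim) >= 2:
                slope_cmp[cls] = compare_slopes(stim, base)

    comparison_rows = []
    for which, band_name in (
        ("gamma_curve", "gamma"),
        ("high_gamma_curve", "high_gamma"),
    ):
        means = _class_mean_curves(sites, which)
        if "LFP" in means and "ECoG" in means:
            r, p = compare_tuning(means["LFP"][1], means["ECoG"][1])
            comparison_rows.append(dict(band=band_name, r=r, p=p))
    comparison = pd.DataFrame(comparison_rows)

    manifest = {
        "study": cfg.study.value,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "config_hash": _config_hash(cfg),
        "n_sites_simulated": len(trialsets),
        "n_sites_analyzed": len(sites),
        "versions": _versions(),
        "elapsed_s": None,
        "outputs": {},
    }

    result = StudyResult(
        config=cfg,
        trialsets=trialsets,
        decisions=decisions,
        sites=sites,
        band_power=band_power,
        tuning=tuning,
        orientation=orientation_df,
        slopes=slopes_df,
        slope_comparison=slope_cmp,
        comparison=comparison,
        manifest=manifest,
    )

    if cfg.out_dir is not None:
        _write_outputs(result)
    manifest["elapsed_s"] = round(time.perf_counter() - t0, 3)
    logger.info("study %s finished in %.1f s", cfg.study.value,
                manifest["elapsed_s"])
    return result


def _config_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["study"] = StudyKind(cfg.study).value
    for k, v in list(d.items()):
        if isinstance(v, Path):
            d[k] = str(v)
        if isinstance(v, tuple):
            d[k] = list(v)
    d["thresholds"] = dataclasses.asdict(cfg.thresholds)
    return d


def _config_hash(cfg: StudyConfig) -> str:
    blob = json.dumps(_config_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _versions() -> dict:
    import scipy

    import gammatune

    return {
        "gammatune": gammatune.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _write_outputs(result: StudyResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_df(df: pd.DataFrame | None, name: str) -> None:
        if df is None:
            return
        path = out / name
        df.to_csv(path, index=False)
        files.append(path)

    save_df(result.band_power, "band_power.csv")
    save_df(result.tuning, "tuning.csv")
    save_df(result.orientation, "orientation.csv")
    save_df(result.slopes, "slopes.csv")
    save_df(result.comparison, "comparison.csv")
    selection = pd.DataFrame(
        [
            dict(site=d.site_id, included=d.included,
                 reasons=";".join(d.reasons))
            for d in result.decisions
        ]
    )
    save_df(selection, "selection.csv")
    if result.slope_comparison:
        path = out / "slope_summary.json"
        payload = {
            cls: dataclasses.asdict(cmp)
            for cls, cmp in result.slope_comparison.items()
        }
        path.write_text(json.dumps(payload, indent=2))
        files.append(path)

    hashes = {}
    for path in files:
        hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    result.manifest["outputs"] = hashes
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, default=str))
    files.append(manifest_path)
    result.output_files = files
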