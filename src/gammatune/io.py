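"""HDF5 serialization of simulated (or same-schema real) sessions.

Layout: one group per channel with datasets ``traces`` (trials x samples),
``t_axis``, ``spike_times`` (ragged, vlen), ``conditions`` (structured
table: radius/orientation/sf/contrast/tf), ``rf_center_per_session`` and
``snippets``; attributes ``fs``, ``signal_class``, ``rf_center``.  The
ground-truth tuning parameters used by the simulator are written to a
sidecar JSON next to the HDF5 file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

from gammatune.conditions import StimulusCondition
from gammatune.simulate import TrialSet, TuningMapParams

_COND_DTYPE = np.dtype(
    [
        ("radius_deg", "f8"),
        ("orientation_deg", "f8"),
        ("sf_cpd", "f8"),
        ("contrast_pct", "f8"),
        ("tf_cps", "f8"),
    ]
)


def _conditions_to_table(conds: Sequence[StimulusCondition]) -> np.ndarray:
    table = np.empty(len(conds), dtype=_COND_DTYPE)
    for i, c in enumerate(conds):
        table[i] = (
            c.radius_deg,
            c.orientation_deg,
            c.sf_cpd,
            c.contrast_pct,
            c.tf_cps,
        )
    return table


def _table_to_conditions(table: np.ndarray) -> list[StimulusCondition]:
    return [
        StimulusCondition(
            radius_deg=float(row["radius_deg"]),
            orientation_deg=float(row["orientation_deg"]),
            sf_cpd=float(row["sf_cpd"]),
            contrast_pct=float(row["contrast_pct"]),
            tf_cps=float(row["tf_cps"]),
        )
        for row in table
    ]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".params.json")


def write_session(
    path: str | Path,
    trialsets: Sequence[TrialSet],
    params_by_channel: Mapping[str, TuningMapParams] | None = None,
) -> Path:
    """Write a multichannel session; returns the HDF5 path.

    When ``params_by_channel`` is given, the ground-truth tuning parameters
    are written to ``<path>.params.json``.
    """
    path = Path(path)
    vlen = h5py.vlen_dtype(np.float64)
    with h5py.File(path, "w") as h5:
        for ts in trialsets:
            g = h5.create_group(ts.channel_id)
            g.attrs["fs"] = ts.fs_hz
            g.attrs["signal_class"] = ts.signal_class
            g.attrs["rf_center"] = np.asarray(ts.rf_center_deg, dtype=float)
            g.create_dataset("traces", data=ts.traces)
            g.create_dataset("t_axis", data=ts.t_axis)
            spikes = g.create_dataset(
                "spike_times", shape=(len(ts.spikes),), dtype=vlen
            )
            for i, sp in enumerate(ts.spikes):
                spikes[i] = np.asarray(sp, dtype=float)
            g.create_dataset("conditions", data=_conditions_to_table(ts.conditions))
            if ts.rf_center_per_session is not None:
                g.create_dataset(
                    "rf_center_per_session", data=ts.rf_center_per_session
                )
            if ts.snippets is not None:
                g.create_dataset("snippets", data=ts.snippets)
    if params_by_channel is not None:
        payload = {
            cid: dataclasses.asdict(p) for cid, p in params_by_channel.items()
        }
        sidecar_path(path).write_text(json.dumps(payload, indent=2))
    return path


def read_session(path: str | Path) -> list[TrialSet]:
    """Read a session written by :func:`write_session`."""
    out: list[TrialSet] = []
    with h5py.File(path, "r") as h5:
        for cid in sorted(h5.keys()):
            g = h5[cid]
            out.append(
                TrialSet(
                    channel_id=cid,
                    signal_class=str(g.attrs["signal_class"]),
                    fs_hz=float(g.attrs["fs"]),
                    t_axis=np.asarray(g["t_axis"]),
                    traces=np.asarray(g["traces"]),
                    spikes=[np.asarray(sp, dtype=float) for sp in g["spike_times"]],
                    conditions=_table_to_conditions(np.asarray(g["conditions"])),
                    rf_center_deg=tuple(np.asarray(g.attrs["rf_center"], dtype=float)),
                    rf_center_per_session=(
                        np.asarray(g["rf_center_per_session"])
                        if "rf_center_per_session" in g
                        else None
                    ),
                    snippets=(
                        np.asarray(g["snippets"]) if "snippets" in g else None
                    ),
                )
            )
    return out


def read_ground_truth(path: str | Path) -> dict[str, TuningMapParams]:
    """Read the sidecar JSON of ground-truth tuning parameters, if present."""
    sp = sidecar_path(path)
    if not sp.exists():
        raise FileNotFoundError(f"no ground-truth sidecar at {sp}")
    payload = json.loads(sp.read_text())
    return {cid: TuningMapParams(**kw) for cid, kw in payload.items()}
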