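"""CSV / TOML / JSON input-output.

File conventions (all UTF-8, '.' decimal separator, header row mandatory):

* heat CSV      — ``injection_index`` (1-based), ``volume_ul``, ``heat_uj``
* trace CSV     — ``time_s``, ``power_uw``
* schedule CSV  — ``injection_index``, ``volume_ul``, optional ``time_s``
* experiment config — TOML, keys of :class:`itcfit.report.ExperimentConfig`

Heats are microjoules and volumes microlitres at the file boundary,
joules and litres in memory.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import PowerTrace
from .titration import InjectionSchedule, TitrationCurve

__all__ = [
    "read_heats_csv", "write_heats_csv",
    "read_trace_csv", "write_trace_csv",
    "read_schedule_csv", "write_schedule_csv",
    "read_config_toml", "write_json",
]

_HEAT_COLS = ["injection_index", "volume_ul", "heat_uj"]


def write_heats_csv(path, curve: TitrationCurve) -> None:
    df = pd.DataFrame({
        "injection_index": np.arange(1, curve.schedule.n_injections + 1),
        "volume_ul": np.asarray(curve.schedule.injection_volumes) * 1e6,
        "heat_uj": curve.heats * 1e6,
    })
    df.to_csv(path, index=False)


def read_heats_csv(path, *, syringe_guest_molar: float, cell_host_molar: float,
                   cell_volume: float = 988e-6,
                   temperature: float = 298.15) -> TitrationCurve:
    """Read a heat CSV; concentrations come from the experiment config."""
    df = pd.read_csv(path)
    missing = [c for c in _HEAT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.sort_values("injection_index")
    schedule = InjectionSchedule(
        syringe_guest_molar=syringe_guest_molar,
        cell_host_molar=cell_host_molar,
        injection_volumes=tuple(df["volume_ul"].to_numpy() * 1e-6),
        cell_volume=cell_volume,
        temperature=temperature,
        syringe_capacity=None,
    )
    return TitrationCurve(schedule=schedule, heats=df["heat_uj"].to_numpy() * 1e-6)


def write_trace_csv(path, trace: PowerTrace) -> None:
    pd.DataFrame({"time_s": trace.time,
                  "power_uw": trace.power * 1e6}).to_csv(path, index=False)


def read_trace_csv(path, injection_times) -> PowerTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "power_uw"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PowerTrace(time=df["time_s"].to_numpy(),
                      power=df["power_uw"].to_numpy() * 1e-6,
                      injection_times=np.asarray(injection_times, float))


def write_schedule_csv(path, schedule: InjectionSchedule,
                       injection_times=None) -> None:
    data = {
        "injection_index": np.arange(1, schedule.n_injections + 1),
        "volume_ul": np.asarray(schedule.injection_volumes) * 1e6,
    }
    if injection_times is not None:
        data["time_s"] = np.asarray(injection_times, float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_schedule_csv(path):
    """Returns (volumes_l, times_s or None)."""
    df = pd.read_csv(path).sort_values("injection_index")
    if "volume_ul" not in df.columns:
        raise ValueError(f"{path}: missing column 'volume_ul'")
    vols = tuple(df["volume_ul"].to_numpy() * 1e-6)
    times = df["time_s"].to_numpy(float) if "time_s" in df.columns else None
    return vols, times


def read_config_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
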