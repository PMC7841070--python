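"""Pipeline composition: config → heats → global fit → thermodynamic table.

``run_pipeline`` ties the library together for the common case: several
blank-corrected heat files (or raw trace + schedule pairs) for one
host–guest system, fitted jointly, reported as the standard table row

    Guest | log K | ΔH (kJ/mol) | ΔS (J/mol/deg)

in parenthetical-uncertainty notation, plus ΔG, TΔS, the Wiseman c
value and fit diagnostics.  A titration that carries no binding signal
(the monomer-control outcome) is reported as "no detectable binding"
rather than as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import io as _io
from .model import IndeterminateParametersError, OneSiteBindingModel
from .signal import integrate_peaks
from .titration import InjectionSchedule, TitrationCurve

__all__ = ["ExperimentConfig", "run_pipeline", "format_report_table"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment metadata; defaults are the nano-ITC setup modelled here."""

    cell_volume_ul: float = 988.0
    syringe_volume_ul: float = 250.0
    temperature_c: float = 25.0
    host_name: str = "host"
    guest_name: str = "guest"
    host_cell_mm: float = 0.2
    guest_syringe_mm: float = 2.0
    buffer: str = "10 mM MOPS, pH 7.2"

    def __post_init__(self) -> None:
        if min(self.cell_volume_ul, self.syringe_volume_ul,
               self.host_cell_mm, self.guest_syringe_mm) <= 0:
            raise ValueError("volumes and concentrations must be positive")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    @classmethod
    def from_toml(cls, path) -> "ExperimentConfig":
        return cls(**_io.read_config_toml(path))


def _load_curve(config: ExperimentConfig, heats_csv=None,
                trace_csv=None, schedule_csv=None,
                baseline_window_s: float = 10.0) -> TitrationCurve:
    if heats_csv is not None:
        return _io.read_heats_csv(
            heats_csv,
            syringe_guest_molar=config.guest_syringe_mm * 1e-3,
            cell_host_molar=config.host_cell_mm * 1e-3,
            cell_volume=config.cell_volume_ul * 1e-6,
            temperature=config.temperature_k)
    vols, times = _io.read_schedule_csv(schedule_csv)
    if times is None:
        raise ValueError(f"{schedule_csv}: trace integration needs a time_s column")
    trace = _io.read_trace_csv(trace_csv, injection_times=times)
    heats = integrate_peaks(trace, baseline_window_s=baseline_window_s)
    schedule = InjectionSchedule(
        syringe_guest_molar=config.guest_syringe_mm * 1e-3,
        cell_host_molar=config.host_cell_mm * 1e-3,
        injection_volumes=vols,
        cell_volume=config.cell_volume_ul * 1e-6,
        temperature=config.temperature_k,
        syringe_capacity=None)
    return TitrationCurve(schedule=schedule, heats=heats)


def run_pipeline(config: ExperimentConfig, heat_csvs=()) -> dict:
    """Fit the listed net-heat CSVs jointly and return a report record.

    The record always carries ``host``, ``guest``, ``n_datasets`` and a
    ``status`` of ``"converged"`` or ``"no detectable binding"``; on
    convergence it adds the full thermodynamic signature and
    diagnostics from :class:`OneSiteBindingResults`.
    """
    paths = list(heat_csvs)
    if not paths:
        raise ValueError("no input files given")
    curves = [_load_curve(config, heats_csv=p) for p in paths]
    report: dict = {
        "host": config.host_name,
        "guest": config.guest_name,
        "buffer": config.buffer,
        "temperature_k": config.temperature_k,
        "n_datasets": len(curves),
        "inputs": [str(p) for p in paths],
    }
    model = OneSiteBindingModel(curves)
    try:
        res = model.fit()
    except IndeterminateParametersError as exc:
        report["status"] = "no detectable binding"
        report["detail"] = str(exc)
        return report
    report["status"] = "converged"
    report.update(res.to_json_record())
    report["summary"] = res.summary()
    return report


def format_report_table(reports) -> str:
    """Aligned text table over one or more pipeline reports."""
    header = f"{'Guest':<16} {'logK':>12} {'dH (kJ/mol)':>14} {'dS (J/mol/deg)':>15}"
    lines = [header, "-" * len(header)]
    for rec in reports:
        if rec.get("status") != "converged":
            lines.append(f"{rec['guest']:<16} {'no detectable binding':>43}")
            continue
        lines.append(
            f"{rec['guest']:<16} {rec['log_k_parenthetical']:>12} "
            f"{rec['delta_h_parenthetical']:>14} {rec['delta_s_parenthetical']:>15}")
    return "\n".join(lines)
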