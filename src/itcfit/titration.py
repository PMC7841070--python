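"""Forward model of an overfilled-cell titration.

In overfilled mode the active cell volume V0 is constant: each
injection of volume v expels an equal volume of cell liquid.  The
discrete-plug convention adopted here is that the expelled plug leaves
with the *pre-injection* cell composition and the injected titrant is
fully retained, followed by instantaneous mixing.  With the dilution
factor d_j = 1 − v_j/V0 this gives the recurrences

    h_j = h_{j−1} · d_j
    g_j = g_{j−1} · d_j + c_syr · v_j / V0

starting from h_0 = [host]_cell, g_0 = 0.

The heat of injection j is the enthalpy of the complex formed in the
active volume during that injection,

    Q_j = −δn_j · ΔH0,   δn_j = V0·([HG]_j − [HG]_{j−1}·d_j),

where the d_j factor accounts for complex carried out in the expelled
plug.  An exothermic reaction (ΔH0 < 0) therefore yields positive
evolved heat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .speciation import complex_concentration
from .thermo import STANDARD_TEMPERATURE, BindingParameters

__all__ = [
    "InjectionSchedule",
    "TitrationCurve",
    "concentration_trajectory",
    "concentrations_after_injection",
    "predicted_heats",
]

DEFAULT_CELL_VOLUME_L = 988e-6
DEFAULT_SYRINGE_CAPACITY_L = 250e-6


@dataclass(frozen=True)
class InjectionSchedule:
    """Design of one titration: volumes and starting concentrations.

    Parameters
    ----------
    syringe_guest_molar : float
        Guest (titrant) concentration in the syringe, mol/L.
    cell_host_molar : float
        Host analytical concentration initially in the cell, mol/L.
    injection_volumes : tuple of float
        Per-injection volumes, L, in injection order.
    cell_volume : float
        Active cell volume V0, L.
    temperature : float
        K.
    syringe_capacity : float or None
        Total syringe volume, L; the schedule may not exceed it.
    """

    syringe_guest_molar: float
    cell_host_molar: float
    injection_volumes: tuple = ()
    cell_volume: float = DEFAULT_CELL_VOLUME_L
    temperature: float = STANDARD_TEMPERATURE
    syringe_capacity: float | None = DEFAULT_SYRINGE_CAPACITY_L

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes",
                           tuple(float(v) for v in self.injection_volumes))
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be > 0")
        if self.syringe_guest_molar < 0 or self.cell_host_molar < 0:
            raise ValueError("concentrations must be >= 0")
        for j, v in enumerate(self.injection_volumes, start=1):
            if v <= 0:
                raise ValueError(f"injection {j}: volume must be > 0, got {v}")
            if v >= self.cell_volume:
                raise ValueError(
                    f"injection {j}: volume {v} must be smaller than the "
                    f"active cell volume {self.cell_volume}")
        if (self.syringe_capacity is not None
                and sum(self.injection_volumes) > self.syringe_capacity * (1 + 1e-12)):
            raise ValueError(
                f"total injected volume {sum(self.injection_volumes):g} L exceeds "
                f"syringe capacity {self.syringe_capacity:g} L")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def concentration_trajectory(schedule: InjectionSchedule):
    """Post-mixing totals after each injection.

    Returns ``(h, g)``: arrays of length n+1 with the pre-titration
    state at index 0 and the state after injection j at index j.
    """
    v = np.asarray(schedule.injection_volumes, dtype=float)
    n = v.size
    h = np.empty(n + 1)
    g = np.empty(n + 1)
    h[0] = schedule.cell_host_molar
    g[0] = 0.0
    v0 = schedule.cell_volume
    d = 1.0 - v / v0
    for j in range(n):
        h[j + 1] = h[j] * d[j]
        g[j + 1] = g[j] * d[j] + schedule.syringe_guest_molar * v[j] / v0
    return h, g


def concentrations_after_injection(schedule: InjectionSchedule, j: int):
    """Totals ``(h_j, g_j)`` after injection ``j`` (1-based)."""
    if not 1 <= j <= schedule.n_injections:
        raise ValueError(f"injection index {j} out of range 1..{schedule.n_injections}")
    h, g = concentration_trajectory(schedule)
    return float(h[j]), float(g[j])


def predicted_heats(schedule: InjectionSchedule,
                    params: BindingParameters) -> np.ndarray:
    """Per-injection heats, J, under the one-site model (see module docs)."""
    h, g = concentration_trajectory(schedule)
    hg = complex_concentration(h, g, params.k)
    v = np.asarray(schedule.injection_volumes, dtype=float)
    d = 1.0 - v / schedule.cell_volume
    dn = schedule.cell_volume * (hg[1:] - hg[:-1] * d)
    return -dn * params.delta_h * 1000.0  # kJ/mol -> J/mol


@dataclass(frozen=True)
class TitrationCurve:
    """One titration: its schedule and the per-injection heats (J, signed)."""

    schedule: InjectionSchedule
    heats: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        heats = np.asarray(self.heats, dtype=float)
        if heats.shape != (self.schedule.n_injections,):
            raise ValueError(
                f"{heats.size} heats for {self.schedule.n_injections} injections")
        object.__setattr__(self, "heats", heats)

    @property
    def totals(self):
        """Post-injection totals (h_tot_j, g_tot_j), mol/L, length n each."""
        h, g = concentration_trajectory(self.schedule)
        return h[1:], g[1:]

    @classmethod
    def from_model(cls, schedule: InjectionSchedule,
                   params: BindingParameters) -> "TitrationCurve":
        return cls(schedule=schedule, heats=predicted_heats(schedule, params))
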