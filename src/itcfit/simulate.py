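"""Synthetic nano-ITC experiments with the statistical structure the
analysis assumes.

A recipe describes one host–guest experiment the way the instrument
sees it: an overfilled 988 µl cell loaded with host (0.2 mM micellar,
or 2.5 µM for the monomer control), a 250 µl syringe of guest (2–10 mM)
delivered as 25 × 10 µl injections, i.i.d. Gaussian heat noise, and a
matched guest-into-buffer blank run whose heats are linear in the moles
of guest injected.  Raw power traces are rendered as Gaussian pulses
whose areas equal the per-injection heats, on an optional linear
baseline drift, so the peak-integration stage can be exercised
end-to-end.

All randomness flows from the recipe seed through one named generator
(numpy PCG64), so a fixed recipe reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signal import PowerTrace
from .thermo import BindingParameters
from .titration import (
    DEFAULT_CELL_VOLUME_L,
    InjectionSchedule,
    TitrationCurve,
    predicted_heats,
)

__all__ = [
    "ExperimentRecipe",
    "default_schedule",
    "micellar_recipe",
    "monomer_control_recipe",
    "simulate_titration",
    "simulate_power_trace",
]

#: Default noise level as a fraction of the largest noiseless heat.
DEFAULT_NOISE_FRACTION = 0.02
#: Default blank magnitude as a fraction of the largest reaction heat.
DEFAULT_BLANK_FRACTION = 0.10


def default_schedule(cell_host_molar: float = 2e-4,
                     syringe_guest_molar: float = 2e-3,
                     n_injections: int = 25,
                     injection_volume: float = 10e-6) -> InjectionSchedule:
    """The experiment design used throughout: 25 × 10 µl from a 250 µl
    syringe into a 988 µl cell, host 0.2 mM, guest 2 mM, 25 °C."""
    return InjectionSchedule(
        syringe_guest_molar=syringe_guest_molar,
        cell_host_molar=cell_host_molar,
        injection_volumes=(injection_volume,) * n_injections,
        cell_volume=DEFAULT_CELL_VOLUME_L,
    )


@dataclass(frozen=True)
class ExperimentRecipe:
    """Everything needed to simulate one titration plus its blank.

    Parameters
    ----------
    binding : BindingParameters
        Generating truth (log K, ΔH, T).
    schedule : InjectionSchedule
        Injection design shared by titration and blank.
    noise_sd : float
        Gaussian heat noise per injection, J (i.i.d.).
    dilution_coefficient : float
        Blank (dilution) heat per mole of injected guest, J/mol.
    seed : int
        Seed of the PCG64 generator; fixed seed → identical outputs.
    response_sigma_s : float
        Gaussian pulse width for trace synthesis, s.
    injection_spacing_s, sample_rate_hz, baseline_drift_w :
        Trace rendering: time between injections, sampling rate, and
        total linear baseline drift over the run (W).
    """

    binding: BindingParameters
    schedule: InjectionSchedule
    noise_sd: float
    dilution_coefficient: float = 0.0
    seed: int = 0
    response_sigma_s: float = 2.0
    injection_spacing_s: float = 300.0
    sample_rate_hz: float = 1.0
    baseline_drift_w: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.response_sigma_s <= 0 or self.injection_spacing_s <= 0:
            raise ValueError("trace parameters must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _auto_scales(binding: BindingParameters, schedule: InjectionSchedule):
    q = predicted_heats(schedule, binding)
    return float(np.max(np.abs(q))) if q.size else 0.0


def micellar_recipe(log_k: float, delta_h: float, *,
                    cell_host_molar: float = 2e-4,
                    syringe_guest_molar: float = 2e-3,
                    noise_fraction: float = DEFAULT_NOISE_FRACTION,
                    blank_fraction: float = DEFAULT_BLANK_FRACTION,
                    seed: int = 0) -> ExperimentRecipe:
    """Recipe for a micellar-host titration at the standard design.

    Noise sd is ``noise_fraction`` of the largest noiseless heat; the
    dilution coefficient is sized so blank heats are ``blank_fraction``
    of the peak reaction heat.
    """
    binding = BindingParameters(log_k=log_k, delta_h=delta_h)
    schedule = default_schedule(cell_host_molar=cell_host_molar,
                                syringe_guest_molar=syringe_guest_molar)
    qmax = _auto_scales(binding, schedule)
    moles_per_inj = schedule.injection_volumes[0] * syringe_guest_molar
    coeff = blank_fraction * qmax / moles_per_inj if moles_per_inj > 0 else 0.0
    return ExperimentRecipe(binding=binding, schedule=schedule,
                            noise_sd=noise_fraction * qmax,
                            dilution_coefficient=coeff, seed=seed)


def monomer_control_recipe(log_k: float = 2.6, delta_h: float = -21.35, *,
                           noise_sd: float = 0.5e-6,
                           seed: int = 0) -> ExperimentRecipe:
    """The monomer control: host 500-fold diluted to 2.5 µM, where the
    predicted binding heats fall below the instrument noise floor."""
    recipe = micellar_recipe(log_k, delta_h, cell_host_molar=2.5e-6, seed=seed)
    return replace(recipe, noise_sd=noise_sd)


def simulate_titration(recipe: ExperimentRecipe,
                       rng: np.random.Generator | None = None):
    """Simulate one titration and its matched blank.

    Returns ``(gross, blank)`` as :class:`TitrationCurve` objects under
    the identical schedule: gross = model heats + linear dilution heat
    + noise; blank = the same dilution heat with independent noise.
    """
    if rng is None:
        rng = recipe.rng()
    schedule = recipe.schedule
    v = np.asarray(schedule.injection_volumes, float)
    moles_injected = v * schedule.syringe_guest_molar
    dilution = recipe.dilution_coefficient * moles_injected
    q_model = predicted_heats(schedule, recipe.binding)
    gross = q_model + dilution + rng.normal(0.0, recipe.noise_sd, v.size)
    blank = dilution + rng.normal(0.0, recipe.noise_sd, v.size)
    return (TitrationCurve(schedule=schedule, heats=gross),
            TitrationCurve(schedule=schedule, heats=blank))


def simulate_power_trace(heats, schedule: InjectionSchedule,
                         recipe: ExperimentRecipe) -> PowerTrace:
    """Render per-injection heats (J) as a thermogram.

    Each injection becomes a Gaussian power pulse of width
    ``response_sigma_s`` centred shortly after its injection time, with
    area equal to its heat, superposed on a linear baseline drifting by
    ``baseline_drift_w`` over the run.  Raises if pulses would leak
    more than 1e−6 of their area outside their injection interval.
    """
    heats = np.asarray(heats, float)
    sigma = recipe.response_sigma_s
    spacing = recipe.injection_spacing_s
    if sigma >= spacing / 6.0:
        raise ValueError("response_sigma_s must be < injection spacing / 6")
    if heats.shape != (schedule.n_injections,):
        raise ValueError("one heat per scheduled injection required")

    n = heats.size
    inj_times = spacing * (1.0 + np.arange(n))
    centers = inj_times + 6.0 * sigma
    # area fraction outside [t_inj, t_inj + spacing]
    leak = 0.5 * math.erfc(6.0 / math.sqrt(2.0)) \
        + 0.5 * math.erfc((spacing - 6.0 * sigma) / (sigma * math.sqrt(2.0)))
    if leak > 1e-6:
        raise ValueError(f"pulse area leakage {leak:.2e} exceeds 1e-6")

    t_end = spacing * (n + 2)
    t = np.arange(0.0, t_end + 0.5 / recipe.sample_rate_hz, 1.0 / recipe.sample_rate_hz)
    power = np.full_like(t, 0.0)
    power += recipe.baseline_drift_w * t / t_end
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    for q, c in zip(heats, centers):
        power += q * norm * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return PowerTrace(time=t, power=power, injection_times=inj_times)
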