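"""Thermodynamic constants, parameter containers and signature conversions.

An ITC fit yields the association constant (as its decadic logarithm,
``log_k``) and the molar enthalpy of complex formation ``delta_h``.  The
rest of the thermodynamic signature follows from the standard relations

    ΔG = −R·T·ln(10)·log K          (standard state 1 mol/L)
    ΔS = (ΔH − ΔG) / T

Units follow calorimetric-table convention: ΔG, ΔH and TΔS in kJ/mol,
ΔS in J/(mol·K).  Internally everything is SI (J, mol, K) and converted
at the boundary.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "STANDARD_TEMPERATURE",
    "BindingParameters",
    "DerivedThermo",
    "UncertainValue",
    "delta_g_from_logk",
    "delta_s_from",
    "derive_thermo",
    "wiseman_c",
    "format_parenthetical",
    "parse_parenthetical",
]

#: CODATA molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314462618

#: 25 degrees Celsius, the temperature of all experiments modelled here.
STANDARD_TEMPERATURE = 298.15


def _require_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BindingParameters:
    """Fitted parameters of a 1:1 association equilibrium H + G = HG.

    Parameters
    ----------
    log_k : float
        Decadic logarithm of the association constant K (L/mol,
        standard state 1 mol/L, so K is dimensionless inside the log).
    delta_h : float
        Molar enthalpy of complex formation, kJ/mol.  Negative for an
        exothermic association.
    temperature : float
        Absolute temperature, K.
    """

    log_k: float
    delta_h: float
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        _require_finite(log_k=self.log_k, delta_h=self.delta_h,
                        temperature=self.temperature)
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def k(self) -> float:
        """Association constant, L/mol."""
        return 10.0 ** self.log_k

    def to_json_record(self) -> dict:
        """Flat JSON-ready record with unit-suffixed keys."""
        derived = derive_thermo(self)
        return {
            "log_k": self.log_k,
            "delta_h_kj_per_mol": self.delta_h,
            "temperature_k": self.temperature,
            **derived.to_json_record(),
        }


@dataclass(frozen=True)
class DerivedThermo:
    """Derived part of the signature: ΔG (kJ/mol), ΔS (J/mol/K), TΔS (kJ/mol)."""

    delta_g: float
    delta_s: float
    t_delta_s: float

    def to_json_record(self) -> dict:
        return {
            "delta_g_kj_per_mol": self.delta_g,
            "delta_s_j_per_mol_k": self.delta_s,
            "t_delta_s_kj_per_mol": self.t_delta_s,
        }


@dataclass(frozen=True)
class UncertainValue:
    """A value with a standard deviation in the same units."""

    value: float
    sd: float

    def __post_init__(self) -> None:
        _require_finite(value=self.value, sd=self.sd)
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    def __str__(self) -> str:
        return format_parenthetical(self)


def delta_g_from_logk(log_k: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Standard Gibbs energy of association, kJ/mol, from log K.

    ΔG = −R·T·ln(10)·log K / 1000.
    """
    _require_finite(log_k=log_k, temperature=temperature)
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return -GAS_CONSTANT * temperature * math.log(10.0) * log_k / 1000.0


def delta_s_from(log_k: float, delta_h: float,
                 temperature: float = STANDARD_TEMPERATURE) -> float:
    """Association entropy, J/(mol K), from log K and ΔH (kJ/mol).

    ΔS = (ΔH − ΔG)/T = (ΔH + R·T·ln10·log K)/T, returned in J/(mol K).
    """
    _require_finite(delta_h=delta_h)
    dg = delta_g_from_logk(log_k, temperature)
    return (delta_h - dg) * 1000.0 / temperature


def derive_thermo(params: BindingParameters) -> DerivedThermo:
    """Full derived signature for a set of fitted parameters."""
    dg = delta_g_from_logk(params.log_k, params.temperature)
    ds = delta_s_from(params.log_k, params.delta_h, params.temperature)
    return DerivedThermo(delta_g=dg, delta_s=ds,
                         t_delta_s=params.temperature * ds / 1000.0)


def wiseman_c(log_k: float, cell_host_molar: float) -> float:
    """Wiseman c parameter, c = K·[host]_cell (dimensionless).

    Governs isotherm sigmoidicity; c below ~1 gives a featureless curve
    and a poorly determined K.
    """
    _require_finite(log_k=log_k, cell_host_molar=cell_host_molar)
    if cell_host_molar <= 0:
        raise ValueError(f"cell_host_molar must be > 0, got {cell_host_molar}")
    return 10.0 ** log_k * cell_host_molar


def _sd_exponent(sd: float) -> int:
    """Decimal exponent of sd rounded to one significant digit."""
    e = math.floor(math.log10(sd))
    if round(sd / 10.0 ** e) >= 10:  # e.g. 0.095 rounds up a decade
        e += 1
    return e


def format_parenthetical(uv: UncertainValue) -> str:
    """Render a value with parenthetical uncertainty, e.g. ``5.1 (3)``.

    The standard deviation is rounded to one significant digit and the
    value to the decimal place of that digit; the digit(s) in
    parentheses apply to the last printed place of the value.  A zero
    sd renders the value alone.
    """
    if uv.sd < 0:
        raise ValueError("sd must be >= 0")
    if uv.sd == 0:
        return str(uv.value)
    e = _sd_exponent(uv.sd)
    sd_digits = int(round(uv.sd / 10.0 ** e))
    if e < 0:
        value_str = f"{uv.value:.{-e}f}"
        sd_str = str(sd_digits)
    else:
        # sd of 10^e scale: value rounded to the same place, sd shown in full
        scaled = round(uv.value / 10.0 ** e) * 10 ** e
        value_str = str(int(scaled))
        sd_str = str(sd_digits * 10 ** e)
    return f"{value_str} ({sd_str})"


_PARENTHETICAL_RE = re.compile(
    r"^\s*(?P<value>[+-]?\d+(?:\.(?P<frac>\d+))?)\s*(?:\((?P<sd>\d+)\))?\s*$"
)


def parse_parenthetical(text: str) -> UncertainValue:
    """Inverse of :func:`format_parenthetical`: ``"5.1 (3)"`` -> (5.1, 0.3)."""
    m = _PARENTHETICAL_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse parenthetical notation: {text!r}")
    value = float(m.group("value"))
    if m.group("sd") is None:
        return UncertainValue(value=value, sd=0.0)
    n_frac = len(m.group("frac") or "")
    sd = float(m.group("sd")) * 10.0 ** (-n_frac)
    return UncertainValue(value=value, sd=sd)
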