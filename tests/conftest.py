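import numpy as np
import pytest

from itcfit import BindingParameters, default_schedule

#: Published thermodynamic signatures (log K, ΔH kJ/mol, ΔS J/mol/K) for the
#: six drug–micelle pairs at 25 °C: (host, guest) -> row.
TABLE_ROWS = {
    ("CholineC4dod", "tetracycline"): (5.1, 2.41, 107.0),
    ("CholineC4dod", "ofloxacin"): (2.5, 23.5, 127.0),
    ("CholineC4dod", "chloramphenicol"): (2.6, -21.35, -21.5),
    ("MedeaC4dod", "tetracycline"): (5.1, 2.31, 105.0),
    ("MedeaC4dod", "ofloxacin"): (2.6, 19.2, 114.0),
    ("MedeaC4dod", "chloramphenicol"): (2.6, -18.55, -11.7),
}


@pytest.fixture
def schedule():
    """The standard design: 25 × 10 µl into a 988 µl cell, host 0.2 mM,
    guest 2 mM."""
    return default_schedule()


@pytest.fixture
def tetracycline_params():
    return BindingParameters(log_k=5.1, delta_h=2.41)


def hg_bisect(h: float, g: float, k: float) -> float:
    """Independent bisection oracle for the 1:1 equilibrium.

    Brackets [HG] in [0, min(h, g)] on the mass-action residual
    k·(h−y)(g−y) − y, which is positive below the root and negative
    above it.
    """
    if h == 0.0 or g == 0.0 or k == 0.0:
        return 0.0
    lo, hi = 0.0, min(h, g)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if k * (h - mid) * (g - mid) - mid > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_heats(schedule, params) -> np.ndarray:
    """Composite oracle: bisection speciation chained with explicit mole
    bookkeeping, independent of the package's forward model."""
    v0 = schedule.cell_volume
    h, g = schedule.cell_host_molar, 0.0
    k = 10.0 ** params.log_k
    hg_prev = hg_bisect(h, g, k)
    out = []
    for v in schedule.injection_volumes:
        d = 1.0 - v / v0
        h *= d
        g = g * d + schedule.syringe_guest_molar * v / v0
        hg = hg_bisect(h, g, k)
        out.append(-(v0 * (hg - hg_prev * d)) * params.delta_h * 1000.0)
        hg_prev = hg
    return np.asarray(out)
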