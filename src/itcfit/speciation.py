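"""1:1 mass-action equilibrium between guest and the micellar host.

The host is the amphiphile expressed on its analytical (per-monomer)
concentration scale; the one-site model treats binding to the micellar
pseudo-component as H + G = HG with a single association constant

    K = [HG] / ([H][G]).

Eliminating the free species with the two mass balances gives a
quadratic in [HG]; the physical root is evaluated in a cancellation-free
form so it stays accurate when K·h_tot >> 1 or when h_tot ~ g_tot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EquilibriumState", "solve_1to1", "complex_concentration"]


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound concentrations at one titration point (mol/L)."""

    h_tot: float
    g_tot: float
    k: float
    free_h: float
    free_g: float
    complex_hg: float


def complex_concentration(h_tot, g_tot, k):
    """Equilibrium [HG] for totals ``h_tot``, ``g_tot`` and constant ``k``.

    Vectorised over numpy arrays.  Uses the stable root

        [HG] = 2·h·g / (b + sqrt(disc)),   b = h + g + 1/k,

    with the discriminant expanded as (h−g)² + 2(h+g)/k + 1/k², which is
    manifestly non-negative and free of the b² − 4hg cancellation.
    ``k = 0`` gives [HG] = 0 exactly.
    """
    h = np.asarray(h_tot, dtype=float)
    g = np.asarray(g_tot, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(h < 0) or np.any(g < 0):
        raise ValueError("concentrations must be >= 0")
    if np.any(k < 0):
        raise ValueError("association constant must be >= 0")
    with np.errstate(divide="ignore"):
        inv_k = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), np.inf)
    with np.errstate(over="ignore"):
        b = h + g + inv_k
        disc = (h - g) ** 2 + 2.0 * (h + g) * inv_k + inv_k**2
    denom = b + np.sqrt(disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        hg = np.where(denom > 0, 2.0 * h * g / np.where(denom > 0, denom, 1.0), 0.0)
    hg = np.where(np.isfinite(denom), hg, 0.0)  # k == 0 -> inf denom -> no binding
    return hg if hg.ndim else float(hg)


def solve_1to1(h_tot: float, g_tot: float, k: float) -> EquilibriumState:
    """Solve H + G = HG at one point and return the full speciation.

    Satisfies both mass balances to relative 1e-10 and the mass-action
    law to relative 1e-8; 0 <= [HG] <= min(h_tot, g_tot).
    """
    h, g, k = float(h_tot), float(g_tot), float(k)
    hg = complex_concentration(h, g, k)
    free_h, free_g = h - hg, g - hg
    if hg > 0.0 and np.isfinite(k) and k > 0.0:
        # h − hg and g − hg cancel near saturation; instead solve the
        # deficient component's own quadratic in its stable rational form
        # and use fg − fh = g − h (both balances lose the same [HG])
        if h >= g:
            a = 1.0 + k * (h - g)
            free_g = 2.0 * g / (a + np.sqrt(a * a + 4.0 * k * g))
            free_h = free_g + (h - g)
        else:
            a = 1.0 + k * (g - h)
            free_h = 2.0 * h / (a + np.sqrt(a * a + 4.0 * k * h))
            free_g = free_h + (g - h)
        hg = k * free_h * free_g
    return EquilibriumState(
        h_tot=h,
        g_tot=g,
        k=k,
        free_h=free_h,
        free_g=free_g,
        complex_hg=hg,
    )
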