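"""Global least-squares refinement of (log K, ΔH) across titrations.

The estimator minimises the unweighted sum of squared heat residuals

    U = Σ_datasets Σ_injections (Q_obs − Q_calc)²

with Q_calc from the overfilled-cell one-site forward model, the two
parameters shared by every titration ("simultaneous" or global
refinement).  Fitting is done in (log K, ΔH) — log-space both matches
how binding constants are reported (symmetric errors on log K) and
conditions the optimiser.

Minimisation is Levenberg–Marquardt with a deterministic multistart
over log K ∈ {1, …, 8}; ΔH is seeded from the first-injection heat.
Parameter standard deviations come from the asymptotic covariance
s²·(JᵀJ)⁻¹ with s² = U/(n − 2).

Usage follows the Model/Results convention::

    model = OneSiteBindingModel([(schedule1, q1), (schedule2, q2)])
    res = model.fit()
    res.params.log_k, res.bse, res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .speciation import complex_concentration
from .thermo import (
    BindingParameters,
    DerivedThermo,
    UncertainValue,
    derive_thermo,
    format_parenthetical,
    wiseman_c,
)
from .titration import TitrationCurve, concentration_trajectory

__all__ = [
    "OneSiteBindingModel",
    "OneSiteBindingResults",
    "FitError",
    "ConvergenceError",
    "IndeterminateParametersError",
]

_UJ = 1e6  # residuals are scaled to microjoules inside the optimiser

LOGK_MULTISTART = tuple(range(1, 9))


class FitError(RuntimeError):
    """Base class for fitting failures."""


class ConvergenceError(FitError):
    """No multistart seed converged."""


class IndeterminateParametersError(FitError):
    """The data do not determine (log K, ΔH) — e.g. no detectable heat."""


class OneSiteBindingModel:
    """Heats from one or more titrations bound to shared (log K, ΔH).

    Parameters
    ----------
    datasets : sequence
        Either ``TitrationCurve`` objects (heats = blank-corrected net
        heats, J) or ``(InjectionSchedule, heats)`` pairs.
    """

    def __init__(self, datasets: Sequence) -> None:
        curves = []
        for d in datasets:
            if isinstance(d, TitrationCurve):
                curves.append(d)
            else:
                schedule, heats = d
                curves.append(TitrationCurve(schedule=schedule, heats=np.asarray(heats, float)))
        if not curves:
            raise ValueError("at least one dataset is required")
        self.datasets: tuple = tuple(curves)
        temps = {c.schedule.temperature for c in curves}
        if len(temps) > 1:
            raise ValueError(f"datasets at different temperatures: {sorted(temps)}")
        self.temperature = curves[0].schedule.temperature
        # Precompute per-dataset trajectories; only [HG] depends on parameters.
        self._traj = []
        for c in curves:
            h, g = concentration_trajectory(c.schedule)
            v = np.asarray(c.schedule.injection_volumes, float)
            d = 1.0 - v / c.schedule.cell_volume
            self._traj.append((h, g, d, c.schedule.cell_volume))
        self.q_obs = np.concatenate([c.heats for c in curves])
        self.n_points = int(self.q_obs.size)
        self.n_parameters = 2

    @classmethod
    def from_curves(cls, *curves: TitrationCurve) -> "OneSiteBindingModel":
        return cls(curves)

    # -- forward model -------------------------------------------------

    def predict(self, log_k: float, delta_h: float) -> np.ndarray:
        """Concatenated model heats, J, across all datasets."""
        # beyond |log K| = 30 the isotherm is saturated/flat; clipping keeps
        # optimiser excursions finite without changing any realistic fit
        k = float(10.0 ** np.clip(log_k, -30.0, 30.0))
        dh_j = delta_h * 1000.0
        out = []
        for h, g, d, v0 in self._traj:
            hg = complex_concentration(h, g, k)
            dn = v0 * (hg[1:] - hg[:-1] * d)
            out.append(-dn * dh_j)
        return np.concatenate(out)

    def objective_u(self, log_k: float, delta_h: float) -> float:
        """The least-squares objective U = Σ (Q_obs − Q_calc)², in J²."""
        r = self.q_obs - self.predict(log_k, delta_h)
        return float(r @ r)

    def _residuals_uj(self, theta: np.ndarray) -> np.ndarray:
        return (self.q_obs - self.predict(theta[0], theta[1])) * _UJ

    def _jac_uj(self, theta: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the µJ residuals w.r.t. (log K, ΔH).

        With [HG] the root of k([H]−y)([G]−y) = y, implicit
        differentiation gives
            d[HG]/dlogK = ln10 · k·fh·fg / (1 + k·(fh + fg)),
        and Q is linear in ΔH.
        """
        log_k, delta_h = theta
        k = float(10.0 ** np.clip(log_k, -30.0, 30.0))
        dh_j = delta_h * 1000.0
        rows_k, rows_h = [], []
        ln10 = np.log(10.0)
        for h, g, d, v0 in self._traj:
            hg = complex_concentration(h, g, k)
            fh = h - hg
            fg = g - hg
            dhg = ln10 * k * fh * fg / (1.0 + k * (fh + fg))
            ddn = v0 * (dhg[1:] - dhg[:-1] * d)
            dn = v0 * (hg[1:] - hg[:-1] * d)
            rows_k.append(dh_j * ddn)      # dres/dlogK = -dQ/dlogK = +ΔH·dδn
            rows_h.append(1000.0 * dn)     # dres/dΔH(kJ) = +1000·δn
        return np.column_stack([np.concatenate(rows_k),
                                np.concatenate(rows_h)]) * _UJ

    # -- fitting -------------------------------------------------------

    def _delta_h_seed(self) -> float:
        """ΔH guess (kJ/mol) assuming the first injection binds completely."""
        c = self.datasets[0]
        v1 = c.schedule.injection_volumes[0]
        moles = v1 * c.schedule.syringe_guest_molar
        if moles <= 0:
            return 1.0
        dh = -c.heats[0] / moles / 1000.0
        return dh if abs(dh) > 1e-9 else 1.0

    def _is_indeterminate(self, sol) -> bool:
        """True when the solution carries no usable binding information.

        Two gates: (a) the normal equations are numerically singular
        (flat objective surface, e.g. all heats ~ 0); (b) the fitted
        model does not reduce the sum of squares significantly relative
        to the no-binding null Q ≡ 0 (partial F-test at 5%) — the
        "no detectable net heat" outcome of a monomer-control run.
        """
        jtj = sol.jac.T @ sol.jac
        cond = np.linalg.cond(jtj)
        if not np.isfinite(cond) or cond > 1e12:
            return True
        dof = self.n_points - self.n_parameters
        if dof <= 0:
            return False
        u0 = float(self.q_obs @ self.q_obs) * _UJ**2
        u = 2.0 * sol.cost  # least_squares cost = U/2 in uJ^2
        if u <= 0:
            return False
        f = ((u0 - u) / self.n_parameters) / (u / dof)
        return f < stats.f.ppf(0.95, self.n_parameters, dof)

    def fit(self, start: BindingParameters | None = None,
            multistart_logk: Sequence[float] = LOGK_MULTISTART,
            xtol: float = 1e-14, max_nfev: int = 400) -> "OneSiteBindingResults":
        """Fit by Levenberg–Marquardt with deterministic multistart.

        Raises
        ------
        IndeterminateParametersError
            If the heats carry no binding signal (singular JᵀJ), as in
            a monomer-control titration.
        ConvergenceError
            If no start converges.
        """
        if self.n_points < self.n_parameters:
            raise ValueError("need at least 2 injections to fit 2 parameters")
        if np.max(np.abs(self.q_obs)) == 0.0:
            raise IndeterminateParametersError(
                "all observed heats are zero: log K and ΔH are indeterminate")

        seeds = []
        if start is not None:
            seeds.append((start.log_k, start.delta_h))
        dh0 = self._delta_h_seed()
        seeds.extend((float(lk), dh0) for lk in multistart_logk)

        best = None
        best_any = None
        for lk0, dh0_i in seeds:
            sol = optimize.least_squares(
                self._residuals_uj, x0=np.array([lk0, dh0_i]),
                jac=self._jac_uj,
                method="lm", xtol=xtol, ftol=1e-14, gtol=1e-14,
                max_nfev=max_nfev)
            if best_any is None or sol.cost < best_any.cost:
                best_any = sol
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            # nothing converged: distinguish a flat, uninformative surface
            # (the no-binding outcome) from a genuine optimiser failure
            if best_any is not None and self._is_indeterminate(best_any):
                raise IndeterminateParametersError(
                    "the data do not determine log K and ΔH "
                    "(no detectable binding signal)")
            raise ConvergenceError("Levenberg–Marquardt failed from every start")

        if self._is_indeterminate(best):
            raise IndeterminateParametersError(
                "the data do not determine log K and ΔH "
                "(no detectable binding signal)")

        # Gauss-Newton polish: JᵀJ and Jᵀr are order-independent sums, so
        # the polished optimum does not depend on dataset ordering
        x = best.x.copy()
        for _ in range(50):
            j = self._jac_uj(x)
            r = self._residuals_uj(x)
            try:
                step = np.linalg.solve(j.T @ j, j.T @ r)
            except np.linalg.LinAlgError:
                break
            x_new = x - step
            if float(self._residuals_uj(x_new) @ self._residuals_uj(x_new)) \
                    > float(r @ r) * (1.0 + 1e-12):
                break
            x = x_new
            if np.all(np.abs(step) <= 1e-13 * (1.0 + np.abs(x))):
                break

        jac = self._jac_uj(x)  # d(residual_uJ)/d(theta)
        jtj = jac.T @ jac

        resid_uj = self._residuals_uj(x)
        u_uj2 = float(resid_uj @ resid_uj)
        dof = self.n_points - self.n_parameters
        s2 = u_uj2 / dof if dof > 0 else np.nan
        cov = s2 * np.linalg.inv(jtj)
        sd = np.sqrt(np.diag(cov))
        corr = float(cov[0, 1] / (sd[0] * sd[1])) if np.all(sd > 0) else np.nan

        params = BindingParameters(log_k=float(x[0]), delta_h=float(x[1]),
                                   temperature=self.temperature)
        return OneSiteBindingResults(
            model=self,
            params=params,
            bse=np.asarray(sd),
            cov_params=cov,
            corr_logk_dh=corr,
            objective_u=u_uj2 / _UJ**2,
            resid=resid_uj / _UJ,  # obs − calc, back in J
            converged=True,
            n_points=self.n_points,
            df_resid=dof,
        )


@dataclass(frozen=True)
class OneSiteBindingResults:
    """Result of a global one-site fit.

    ``bse`` and ``cov_params`` are ordered (log_k, delta_h); ``resid``
    is Q_obs − Q_calc (J) concatenated across datasets in input order.
    """

    model: OneSiteBindingModel = field(repr=False)
    params: BindingParameters
    bse: np.ndarray
    cov_params: np.ndarray = field(repr=False)
    corr_logk_dh: float
    objective_u: float
    resid: np.ndarray = field(repr=False)
    converged: bool
    n_points: int
    df_resid: int

    @property
    def log_k(self) -> UncertainValue:
        return UncertainValue(self.params.log_k, float(self.bse[0]))

    @property
    def delta_h(self) -> UncertainValue:
        """ΔH with its sd, kJ/mol."""
        return UncertainValue(self.params.delta_h, float(self.bse[1]))

    @property
    def derived(self) -> DerivedThermo:
        return derive_thermo(self.params)

    @property
    def delta_s(self) -> UncertainValue:
        """ΔS (J/mol/K) with sd propagated from (log K, ΔH) incl. covariance."""
        t = self.params.temperature
        # dS/dlogK = R ln10, dS/dH = 1000/T (H in kJ/mol)
        grad = np.array([8.314462618 * np.log(10.0), 1000.0 / t])
        var = float(grad @ self.cov_params @ grad)
        return UncertainValue(self.derived.delta_s, np.sqrt(max(var, 0.0)))

    def wiseman_c(self, dataset: int = 0) -> float:
        """c = K·[host] for one dataset's cell concentration."""
        host = self.model.datasets[dataset].schedule.cell_host_molar
        return wiseman_c(self.params.log_k, host)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """t-based confidence intervals, rows (log_k, delta_h)."""
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        est = np.array([self.params.log_k, self.params.delta_h])
        return np.column_stack([est - q * self.bse, est + q * self.bse])

    def to_json_record(self) -> dict:
        rec = self.params.to_json_record()
        rec.update({
            "log_k_sd": float(self.bse[0]),
            "delta_h_sd_kj_per_mol": float(self.bse[1]),
            "delta_s_sd_j_per_mol_k": self.delta_s.sd,
            "log_k_parenthetical": format_parenthetical(self.log_k),
            "delta_h_parenthetical": format_parenthetical(self.delta_h),
            "delta_s_parenthetical": format_parenthetical(self.delta_s),
            "objective_u_j2": self.objective_u,
            "corr_log_k_delta_h": self.corr_logk_dh,
            "wiseman_c": self.wiseman_c(),
            "n_points": self.n_points,
            "n_datasets": len(self.model.datasets),
            "converged": self.converged,
        })
        return rec

    def summary(self) -> str:
        d = self.derived
        ci = self.conf_int()
        lines = [
            "One-site (1:1) global binding fit",
            "=" * 49,
            f"datasets: {len(self.model.datasets)}    points: {self.n_points}"
            f"    dof: {self.df_resid}",
            f"T = {self.params.temperature:.2f} K    "
            f"U = {self.objective_u:.4e} J^2",
            "-" * 49,
            f"log K   = {format_parenthetical(self.log_k):>14}   "
            f"95% CI [{ci[0,0]:.3f}, {ci[0,1]:.3f}]",
            f"dH      = {format_parenthetical(self.delta_h):>14} kJ/mol   "
            f"95% CI [{ci[1,0]:.3f}, {ci[1,1]:.3f}]",
            f"dG      = {d.delta_g:14.2f} kJ/mol",
            f"dS      = {format_parenthetical(self.delta_s):>14} J/(mol K)",
            f"TdS     = {d.t_delta_s:14.2f} kJ/mol",
            f"corr(log K, dH) = {self.corr_logk_dh:+.3f}    "
            f"Wiseman c = {self.wiseman_c():.3g}",
            "=" * 49,
        ]
        return "\n".join(lines)
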