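"""Raw thermogram processing: peak integration and blank subtraction.

A nano-ITC records differential power versus time; each injection
produces a peak that relaxes back to baseline before the next one.  The
gross heat of an injection is the integral of baseline-corrected power
over its inter-injection interval.  The baseline under each interval is
the straight line between the median power in the quiet window just
before the injection and the median in the quiet window just before the
next injection (medians, not means, so a single spiked sample cannot
tilt the baseline).

Sign convention: power is stored so that a positive integrated heat is
exothermic, matching the heat model in :mod:`itcfit.titration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .titration import TitrationCurve

__all__ = ["PowerTrace", "HeatSeries", "integrate_peaks", "subtract_blank"]


@dataclass(frozen=True)
class PowerTrace:
    """Raw thermogram: time (s, strictly increasing), power (W), injection times (s)."""

    time: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    injection_times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        power = np.asarray(self.power, dtype=float)
        inj = np.asarray(self.injection_times, dtype=float)
        if time.ndim != 1 or time.shape != power.shape:
            raise ValueError("time and power must be 1-D arrays of equal length")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if inj.size == 0:
            raise ValueError("at least one injection time required")
        if np.any(np.diff(inj) <= 0):
            raise ValueError("injection times must be strictly increasing")
        if inj[0] < time[0] or inj[-1] > time[-1]:
            raise ValueError("injection times must lie within the trace time range")
        edges = np.concatenate([inj, [time[-1]]])
        for j in range(inj.size):
            n_in = np.count_nonzero((time >= edges[j]) & (time <= edges[j + 1]))
            if n_in < 2:
                raise ValueError(f"injection {j + 1}: fewer than 2 samples in its interval")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "injection_times", inj)


@dataclass(frozen=True)
class HeatSeries:
    """Gross, blank and net per-injection heats (J); net = gross − blank."""

    gross: np.ndarray = field(repr=False)
    blank: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        gross = np.asarray(self.gross, dtype=float)
        blank = np.asarray(self.blank, dtype=float)
        if gross.shape != blank.shape:
            raise ValueError("gross and blank must have equal length")
        object.__setattr__(self, "gross", gross)
        object.__setattr__(self, "blank", blank)

    @property
    def net(self) -> np.ndarray:
        return self.gross - self.blank


def _quiet_median(trace: PowerTrace, window_end: float, window_s: float) -> float:
    """Median power over the quiet window (window_end − window_s, window_end]."""
    mask = (trace.time > window_end - window_s) & (trace.time <= window_end)
    return float(np.median(trace.power[mask]))


def integrate_peaks(trace: PowerTrace, baseline_window_s: float = 10.0) -> np.ndarray:
    """Integrate each injection peak above a piecewise-linear baseline.

    For injection j the baseline anchors are the quiet-window medians
    just before t_j and just before t_{j+1} (or the trace end); the
    gross heat is the trapezoidal integral of power minus that line
    over [t_j, t_{j+1}].  Returns heats in J.
    """
    if baseline_window_s <= 0:
        raise ValueError("baseline_window_s must be > 0")
    inj = trace.injection_times
    spacings = np.diff(np.concatenate([inj, [trace.time[-1]]]))
    for j, dt in enumerate(spacings, start=1):
        if baseline_window_s >= dt:
            raise ValueError(
                f"injection {j}: baseline window {baseline_window_s} s overlaps "
                f"the {dt:g} s interval to the next injection")
    edges = np.concatenate([inj, [trace.time[-1]]])
    anchors = np.array([_quiet_median(trace, t_end, baseline_window_s)
                        for t_end in edges])
    heats = np.empty(inj.size)
    for j in range(inj.size):
        t0, t1 = edges[j], edges[j + 1]
        mask = (trace.time >= t0) & (trace.time <= t1)
        t = trace.time[mask]
        p = trace.power[mask]
        baseline = anchors[j] + (anchors[j + 1] - anchors[j]) * (t - t0) / (t1 - t0)
        heats[j] = np.trapezoid(p - baseline, t)
    return heats


def subtract_blank(gross_run: TitrationCurve, blank_run: TitrationCurve) -> HeatSeries:
    """Injection-by-injection blank correction: net_j = gross_j − blank_j.

    The blank must have been recorded under the identical injection
    schedule (same count and volumes); a mismatch is an error, never an
    interpolation.
    """
    gv = np.asarray(gross_run.schedule.injection_volumes)
    bv = np.asarray(blank_run.schedule.injection_volumes)
    if gv.size != bv.size:
        raise ValueError(
            f"schedule mismatch: {gv.size} vs {bv.size} injections")
    bad = np.nonzero(np.abs(gv - bv) > 1e-12)[0]
    if bad.size:
        j = int(bad[0]) + 1
        raise ValueError(
            f"schedule mismatch at injection {j}: volumes {gv[j-1]:g} vs {bv[j-1]:g} L")
    return HeatSeries(gross=gross_run.heats, blank=blank_run.heats)
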