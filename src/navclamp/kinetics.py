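"""Inactivation time constants and time-to-peak versus voltage.

The falling phase of the fast sodium current is fitted with a single
exponential I(t) = A * exp(-(t - t_peak)/tau) + C from the measured peak to
the end of the test step.  Time-to-peak is the interval from step onset to
the current extremum, refined to sub-sample precision with a 3-point
parabola.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .activation import FitError
from .model import ValidationError
from .traces import Sweep, SweepFamily

__all__ = ["TauFit", "fit_inactivation_tau", "time_to_peak", "tau_voltage_curve"]

MIN_FALLING_SAMPLES = 20


@dataclass
class TauFit:
    tau: float  # ms
    amplitude: float  # pA, signed (inward negative)
    offset: float  # pA
    fit_window: tuple[float, float]  # ms
    residual_rms: float  # pA
    voltage: float  # mV


def _peak_index(sweep: Sweep, step_onset: float, window_ms: float = 10.0) -> int:
    lo, hi = step_onset, min(step_onset + window_ms, sweep.time[-1])
    mask = (sweep.time >= lo) & (sweep.time <= hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError("empty peak search window")
    seg = sweep.current[idx]
    return int(idx[np.argmax(np.abs(seg))])


def fit_inactivation_tau(sweep: Sweep, step_onset: float,
                         step_end: float | None = None) -> TauFit:
    """Single-exponential fit of the falling phase, peak to step end."""
    ip = _peak_index(sweep, step_onset)
    if sweep.current[ip] == 0.0:
        raise ValidationError("no identifiable peak to anchor the falling phase")
    if step_end is None:
        step_end = float(sweep.time[-1])
    mask = (sweep.time >= sweep.time[ip]) & (sweep.time <= step_end)
    t = sweep.time[mask] - sweep.time[ip]
    y = sweep.current[mask]
    if t.size < MIN_FALLING_SAMPLES:
        raise ValidationError(
            f"falling phase holds {t.size} samples; need >= {MIN_FALLING_SAMPLES}")
    c0 = float(np.mean(y[-max(5, t.size // 20):]))
    a0 = float(y[0] - c0)
    if a0 == 0.0:
        raise ValidationError("flat falling phase; nothing to fit")
    # initial tau from the 1/e crossing of the peak-referenced decay
    target = c0 + a0 / np.e
    crossing = np.flatnonzero((y - target) * np.sign(a0) <= 0)
    tau0 = float(t[crossing[0]]) if crossing.size else float(t[-1] / 3)
    tau0 = max(tau0, float(t[1]))

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    lo_tau, hi_tau = 1e-4, 1e4
    try:
        popt, _ = curve_fit(model, t, y, p0=[a0, tau0, c0],
                            bounds=([-np.inf, lo_tau, -np.inf],
                                    [np.inf, hi_tau, np.inf]), maxfev=20000)
    except RuntimeError as e:
        raise FitError(f"inactivation fit did not converge: {e}") from e
    if np.isclose(popt[1], lo_tau) or np.isclose(popt[1], hi_tau):
        warnings.warn("inactivation tau pinned at fit bound", RuntimeWarning)
    resid = y - model(t, *popt)
    return TauFit(
        tau=float(popt[1]), amplitude=float(popt[0]), offset=float(popt[2]),
        fit_window=(float(sweep.time[ip]), float(step_end)),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        voltage=sweep.test_voltage)


def time_to_peak(sweep: Sweep, step_onset: float) -> float:
    """Step onset to current extremum, with 3-point parabolic refinement."""
    ip = _peak_index(sweep, step_onset)
    if sweep.current[ip] == 0.0:
        raise ValidationError("no identifiable peak")
    t_peak = float(sweep.time[ip])
    if 0 < ip < sweep.time.size - 1:
        y0, y1, y2 = np.abs(sweep.current[ip - 1:ip + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # local maximum of |I|; refine inside one sample
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                t_peak += shift * sweep.dt
    return t_peak - step_onset


def tau_voltage_curve(family_processed: dict[float, Sweep], step_onset: float,
                      step_end: float | None = None,
                      ) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Per-voltage inactivation tau and time-to-peak for a processed family.

    Voltages whose falling phase cannot be fitted are omitted with a
    warning.  Returns (tau_points, ttp_points); monotonicity of tau with
    depolarization is reported by the caller, not enforced here.
    """
    if len(family_processed) < 3:
        raise ValidationError("tau-voltage curve needs at least 3 voltages")
    taus: list[tuple[float, float]] = []
    ttps: list[tuple[float, float]] = []
    for v in sorted(family_processed):
        sw = family_processed[v]
        try:
            tf = fit_inactivation_tau(sw, step_onset, step_end)
            taus.append((v, tf.tau))
            ttps.append((v, time_to_peak(sw, step_onset)))
        except (ValidationError, FitError) as e:
            warnings.warn(f"{v} mV omitted from kinetics curve: {e}",
                          RuntimeWarning)
    return taus, ttps
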