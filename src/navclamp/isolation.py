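"""Drug-sensitive current isolation and basic trace measurements.

The TTX-sensitive (TTX-S) component is the point-by-point difference between
the control trace and the trace recorded in TTX; the ProTx II-sensitive
component is obtained analogously.  Peak amplitude, persistent current and
percent inhibition operate on baseline-corrected traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ValidationError
from .traces import Sweep

__all__ = ["subtract_traces", "peak_amplitude", "persistent_current",
           "percent_inhibition", "IsolationResult"]

PEAK_WINDOW_MS = 10.0  # peak search: step onset .. onset + 10 ms
PERSISTENT_AT_MS = 10.0
PERSISTENT_HALF_WINDOW_MS = 0.25


@dataclass
class IsolationResult:
    sensitive_trace: Sweep
    peak_control: float  # pA, signed
    peak_drug: float
    peak_sensitive: float
    persistent_control: float  # pA at 10 ms
    percent_inhibition: float  # clipped to [0, 100]
    percent_inhibition_raw: float


def subtract_traces(control: Sweep, drug: Sweep, label: str = "sensitive") -> Sweep:
    """Point-by-point ``control - drug``; the drug-sensitive component."""
    if control.test_voltage != drug.test_voltage:
        raise ValidationError(
            f"voltage mismatch: control {control.test_voltage} mV vs "
            f"drug {drug.test_voltage} mV")
    if control.time.shape != drug.time.shape or abs(control.dt - drug.dt) > 1e-12:
        raise ValidationError("time base mismatch between control and drug traces")
    out = control.copy_with(current=control.current - drug.current,
                            condition=label)
    out.meta = dict(control.meta)
    return out


def peak_amplitude(sweep: Sweep, step_onset: float,
                   window_ms: float = PEAK_WINDOW_MS) -> tuple[float, float]:
    """Signed extremum of largest magnitude within the search window.

    Returns ``(peak_pA, peak_time_ms)``.  Inward currents are negative.  An
    all-zero window returns (0.0, window start) and flags ``no_peak`` in the
    sweep metadata.
    """
    lo, hi = step_onset, step_onset + window_ms
    if lo < sweep.time[0] or hi > sweep.time[-1] + 1e-9:
        raise ValidationError("peak search window outside the sweep")
    mask = (sweep.time >= lo) & (sweep.time <= hi)
    seg = sweep.current[mask]
    ts = sweep.time[mask]
    idx = int(np.argmax(np.abs(seg)))
    if seg[idx] == 0.0:
        sweep.meta["no_peak"] = True
        return 0.0, float(ts[0])
    return float(seg[idx]), float(ts[idx])


def persistent_current(control: Sweep, step_onset: float,
                       at: float = PERSISTENT_AT_MS,
                       half_window: float = PERSISTENT_HALF_WINDOW_MS) -> float:
    """Slow-inactivating current: mean over ``at`` +/- 0.25 ms after onset."""
    centre = step_onset + at
    step_end = control.meta.get("step_end")
    if step_end is not None and centre > step_end:
        raise ValidationError("persistent-current time beyond the step")
    if centre + half_window > control.time[-1] + 1e-9:
        raise ValidationError("persistent-current window beyond the sweep")
    mask = (control.time >= centre - half_window) & (control.time <= centre + half_window)
    return float(control.current[mask].mean())


def percent_inhibition(peak_control: float, peak_drug: float) -> float:
    """Percent reduction of the control peak magnitude by the drug.

    100 * (|peak_control| - |peak_drug|) / |peak_control|.  May be negative
    if the drug trace is larger (noise); callers report the value clipped to
    [0, 100] with the raw value retained.
    """
    if peak_control == 0.0:
        raise ValidationError("percent inhibition undefined for zero control peak")
    return 100.0 * (abs(peak_control) - abs(peak_drug)) / abs(peak_control)


def isolate(control: Sweep, drug: Sweep, step_onset: float,
            label: str = "sensitive") -> IsolationResult:
    """Full isolation record for one voltage: subtraction plus measurements."""
    sens = subtract_traces(control, drug, label=label)
    pc, _ = peak_amplitude(control, step_onset)
    pd_, _ = peak_amplitude(drug, step_onset)
    ps, _ = peak_amplitude(sens, step_onset)
    pers = persistent_current(control, step_onset)
    raw = percent_inhibition(pc, pd_) if pc != 0 else float("nan")
    return IsolationResult(
        sensitive_trace=sens, peak_control=pc, peak_drug=pd_, peak_sensitive=ps,
        persistent_control=pers,
        percent_inhibition=float(np.clip(raw, 0.0, 100.0)),
        percent_inhibition_raw=raw)
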