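"""Sweep averaging, P/4 leak-subtraction and baseline correction.

These operations precede every measurement: repeats are P/4-corrected
individually, then averaged, then baseline-referenced to the pre-step
holding current.
"""

from __future__ import annotations

import numpy as np

from .model import ValidationError
from .traces import Sweep, SweepFamily

__all__ = ["average_sweeps", "p4_subtract", "baseline_correct", "preprocess_family"]

DEFAULT_BASELINE_MS = 5.0  # final 5 ms before step onset


def _check_compatible(sweeps: list[Sweep]) -> None:
    ref = sweeps[0]
    for sw in sweeps[1:]:
        if sw.test_voltage != ref.test_voltage:
            raise ValidationError(
                f"cannot combine sweeps at {ref.test_voltage} and "
                f"{sw.test_voltage} mV")
        if sw.role != ref.role:
            raise ValidationError("cannot combine sweeps with different roles")
        if sw.time.shape != ref.time.shape or abs(sw.dt - ref.dt) > 1e-12:
            raise ValidationError("cannot combine sweeps with different time bases")


def average_sweeps(sweeps: list[Sweep]) -> Sweep:
    """Pointwise arithmetic mean of repeats of the same protocol step."""
    if not sweeps:
        raise ValidationError("average_sweeps needs at least one sweep")
    _check_compatible(sweeps)
    mean = np.mean([sw.current for sw in sweeps], axis=0)
    out = sweeps[0].copy_with(current=mean, repeat_index=None)
    out.meta = dict(sweeps[0].meta, n_averaged=len(sweeps))
    return out


def p4_subtract(main: Sweep, subsweeps: list[Sweep]) -> Sweep:
    """Remove linear leak/capacitance using four quarter-amplitude subsweeps.

    Each subsweep is referenced to its own pre-step baseline; the sum of the
    four referenced responses is the linear (ohmic + capacitive) template for
    the full step amplitude and is subtracted from the main sweep.  On a
    purely linear cell the corrected step response is zero to numerical
    tolerance.
    """
    if len(subsweeps) != 4:
        raise ValidationError(f"P/4 needs exactly 4 subsweeps, got {len(subsweeps)}")
    for sub in subsweeps:
        if sub.time.shape != main.time.shape or abs(sub.dt - main.dt) > 1e-12:
            raise ValidationError("P/4 subsweep time base does not match main sweep")
        if sub.test_voltage != main.test_voltage:
            raise ValidationError("P/4 subsweep belongs to a different test voltage")
    onset = main.meta.get("step_onset")
    template = np.zeros_like(main.current)
    for sub in subsweeps:
        base = _baseline_mean(sub, onset)
        template += sub.current - base
    out = main.copy_with(current=main.current - template)
    out.meta = dict(main.meta, p4_corrected=True)
    return out


def _baseline_mean(sweep: Sweep, step_onset: float | None,
                   window_ms: float = DEFAULT_BASELINE_MS) -> float:
    onset = step_onset
    if onset is None:
        onset = sweep.meta.get("step_onset")
    if onset is None:
        # fall back: assume the first tenth of the sweep is pre-step
        onset = sweep.time[int(sweep.time.size * 0.1)]
    lo = max(sweep.time[0], onset - window_ms)
    mask = (sweep.time >= lo) & (sweep.time < onset)
    if mask.sum() < 10:
        raise ValidationError("baseline window holds fewer than 10 samples")
    return float(sweep.current[mask].mean())


def baseline_correct(sweep: Sweep, step_onset: float,
                     window_ms: float = DEFAULT_BASELINE_MS) -> Sweep:
    """Subtract the mean of the pre-step window (default final 5 ms)."""
    if window_ms <= 0:
        raise ValidationError("baseline window must have positive length")
    if step_onset - window_ms < sweep.time[0] - 1e-9:
        raise ValidationError("baseline window extends before the sweep start")
    if step_onset > sweep.time[-1]:
        raise ValidationError("step onset beyond the sweep")
    offset = _baseline_mean(sweep, step_onset, window_ms)
    out = sweep.copy_with(current=sweep.current - offset)
    out.meta = dict(sweep.meta, baseline_offset=offset, step_onset=step_onset)
    return out


def preprocess_family(family: SweepFamily, condition: str) -> dict[float, Sweep]:
    """P/4-correct each repeat, average repeats, baseline-correct.

    Returns one processed sweep per test voltage for ``condition``.
    """
    proto = family.protocol
    out: dict[float, Sweep] = {}
    for v in proto.test_voltages:
        mains = family.select(condition=condition, voltage=v, role="main")
        if not mains:
            raise ValidationError(f"no sweeps at {v} mV for condition {condition!r}")
        corrected = []
        for main in mains:
            main = main.copy_with()
            main.meta = dict(main.meta, step_onset=proto.step_onset)
            subs = [sw for sw in family.select(condition=condition, voltage=v,
                                               role="p4_sub")
                    if sw.repeat_index == main.repeat_index]
            if len(subs) == 4:
                main = p4_subtract(main, subs)
            corrected.append(main)
        avg = average_sweeps(corrected)
        window = min(DEFAULT_BASELINE_MS, proto.step_onset)
        out[v] = baseline_correct(avg, proto.step_onset, window)
    return out
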