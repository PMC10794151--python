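"""F/F0 normalization of fluorescence time series and transient AUC.

F0 is the mean of all pre-stimulus frames; the area under the curve
integrates (F/F0 - 1) over a window from stimulus onset, so a flat trace
has zero AUC and the measure is invariant to the raw intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ValidationError

__all__ = ["FluorescenceTrace", "normalize_f_f0", "auc",
           "read_trace", "write_trace"]


@dataclass
class FluorescenceTrace:
    time: np.ndarray  # s
    intensity: np.ndarray  # arbitrary units (or F/F0 once normalized)
    stimulus_onset_index: int
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValidationError("time and intensity must be equal-length 1-D")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not (0 <= self.stimulus_onset_index < self.time.size):
            raise ValidationError("stimulus onset index out of bounds")
        if self.stimulus_onset_index < 2:
            raise ValidationError("need at least 2 pre-onset frames")


def normalize_f_f0(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Divide by the mean pre-onset intensity (F0)."""
    f0 = float(trace.intensity[:trace.stimulus_onset_index].mean())
    if f0 <= 0:
        raise ValidationError("baseline mean must be > 0 for F/F0")
    return FluorescenceTrace(
        time=trace.time, intensity=trace.intensity / f0,
        stimulus_onset_index=trace.stimulus_onset_index, normalized=True,
        meta=dict(trace.meta, f0=f0))


def auc(trace: FluorescenceTrace, duration: float | None = None) -> float:
    """Trapezoidal integral of (F/F0 - 1) from stimulus onset.

    ``duration`` limits the window (seconds from onset); by default the
    integral runs to the end of the trace.
    """
    if not trace.normalized:
        raise ValidationError("AUC expects an F/F0-normalized trace")
    t0 = trace.time[trace.stimulus_onset_index]
    t_end = trace.time[-1] if duration is None else t0 + duration
    if t_end > trace.time[-1] + 1e-9:
        raise ValidationError("AUC window extends beyond the trace")
    mask = (trace.time >= t0) & (trace.time <= t_end + 1e-12)
    return float(np.trapezoid(trace.intensity[mask] - 1.0, trace.time[mask]))


def read_trace(tsv_path, onset_index: int | None = None) -> FluorescenceTrace:
    """Read a two-column (time_s, F) TSV; onset from arg or JSON sidecar."""
    import json
    from pathlib import Path
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    if onset_index is None:
        sidecar = tsv_path.with_suffix(".json")
        if not sidecar.exists():
            raise ValidationError("stimulus onset index not given and no sidecar")
        onset_index = json.loads(sidecar.read_text())["stimulus_onset_index"]
    return FluorescenceTrace(time=df["time_s"].to_numpy(),
                             intensity=df["F"].to_numpy(),
                             stimulus_onset_index=int(onset_index))


def write_trace(trace: FluorescenceTrace, tsv_path) -> None:
    import json
    from pathlib import Path
    tsv_path = Path(tsv_path)
    pd.DataFrame({"time_s": trace.time, "F": trace.intensity}).to_csv(
        tsv_path, sep="\t", index=False)
    tsv_path.with_suffix(".json").write_text(json.dumps(
        {"stimulus_onset_index": trace.stimulus_onset_index,
         "normalized": trace.normalized, **trace.meta}, indent=1))
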