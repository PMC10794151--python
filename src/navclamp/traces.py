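"""Sweep containers and the on-disk sweep-family format.

A recorded or simulated cell is stored as one wide CSV per condition
(column 1 = ``time_ms``, one column per voltage x repeat x role) plus a JSON
sidecar holding the protocol, condition list, membrane capacitance,
provenance and units.  The format round-trips at full float precision.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import StepProtocol, ValidationError

__all__ = ["Sweep", "SweepFamily", "FormatError", "write_family", "read_family"]

_TIME_RTOL = 1e-6


class FormatError(ValueError):
    """Raised when an on-disk family violates the container schema."""


@dataclass
class Sweep:
    """A single sampled current trace with its protocol context."""

    time: np.ndarray  # ms, uniform
    current: np.ndarray  # pA, inward negative
    test_voltage: float  # mV
    condition: str = "control"
    role: str = "main"  # "main" or "p4_sub"
    repeat_index: int | None = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.current.shape:
            raise ValidationError("time and current must be equal-length 1-D arrays")
        if self.time.size < 2:
            raise ValidationError("a sweep needs at least two samples")
        dt = np.diff(self.time)
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.current)):
            raise ValidationError("sweep contains non-finite values")
        if np.any(np.abs(dt - dt[0]) > _TIME_RTOL * max(abs(dt[0]), 1e-12)):
            raise ValidationError("sweep time base is not uniform")
        if self.role not in ("main", "p4_sub"):
            raise ValidationError(f"unknown sweep role {self.role!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def copy_with(self, **kwargs) -> "Sweep":
        out = dataclasses.replace(self, **kwargs)
        return out


@dataclass
class SweepFamily:
    """All sweeps recorded from one cell under a shared protocol."""

    sweeps: list[Sweep]
    protocol: StepProtocol
    cell_id: str = "cell"
    membrane_capacitance: float | None = None  # pF
    provenance: dict = field(default_factory=lambda: {"source": "recorded"})

    def __post_init__(self) -> None:
        allowed = set(self.protocol.test_voltages)
        for sw in self.sweeps:
            if sw.test_voltage not in allowed:
                raise ValidationError(
                    f"sweep voltage {sw.test_voltage} mV not in protocol")
        if self.membrane_capacitance is not None and self.membrane_capacitance <= 0:
            raise ValidationError("membrane capacitance must be > 0 when present")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for sw in self.sweeps:
            if sw.condition not in seen:
                seen.append(sw.condition)
        return seen

    def select(self, condition: str | None = None, voltage: float | None = None,
               role: str | None = None) -> list[Sweep]:
        out = []
        for sw in self.sweeps:
            if condition is not None and sw.condition != condition:
                continue
            if voltage is not None and sw.test_voltage != voltage:
                continue
            if role is not None and sw.role != role:
                continue
            out.append(sw)
        return out


# ---------------------------------------------------------------------------
# on-disk format

_COL_RE = re.compile(r"^V(?P<v>[+-]?\d+(?:\.\d+)?)mV/rep(?P<rep>\d+)/(?P<role>main|p4_sub)(?:/s(?P<sub>\d+))?$")


def _column_name(sw: Sweep) -> str:
    base = f"V{sw.test_voltage:+g}mV/rep{sw.repeat_index or 0}/{sw.role}"
    sub = sw.meta.get("sub_index")
    if sw.role == "p4_sub":
        base += f"/s{sub if sub is not None else 0}"
    return base


def write_family(family: SweepFamily, path: str | Path) -> Path:
    """Write ``family`` as one wide CSV per condition plus a JSON sidecar.

    ``path`` is a directory (created if absent).  Returns the sidecar path.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    csv_files = {}
    for cond in family.conditions:
        sweeps = family.select(condition=cond)
        t = sweeps[0].time
        cols: dict[str, np.ndarray] = {"time_ms": t}
        for sw in sweeps:
            if sw.time.shape != t.shape or abs(sw.dt - sweeps[0].dt) > 1e-12:
                raise ValidationError("all sweeps of a condition must share a time base")
            name = _column_name(sw)
            if name in cols:
                raise ValidationError(f"duplicate sweep column {name!r}")
            cols[name] = sw.current
        fname = f"{family.cell_id}_{cond}.csv"
        pd.DataFrame(cols).to_csv(path / fname, index=False,
                                  float_format="%.17g")
        csv_files[cond] = fname
    sidecar = {
        "format": "navclamp-sweep-family/1",
        "units": {"time": "ms", "current": "pA", "voltage": "mV",
                  "capacitance": "pF"},
        "cell_id": family.cell_id,
        "protocol": dataclasses.asdict(family.protocol),
        "conditions": csv_files,
        "membrane_capacitance": family.membrane_capacitance,
        "provenance": family.provenance,
    }
    sidecar_path = path / f"{family.cell_id}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def read_family(path: str | Path) -> SweepFamily:
    """Read a family written by :func:`write_family`.

    ``path`` may be the sidecar file or the directory containing exactly one
    sidecar.  Sampling uniformity is validated to relative tolerance 1e-6.
    """
    path = Path(path)
    if path.is_dir():
        sidecars = []
        for cand in sorted(path.glob("*.json")):
            try:
                if json.loads(cand.read_text()).get("format") == \
                        "navclamp-sweep-family/1":
                    sidecars.append(cand)
            except json.JSONDecodeError:
                continue
        if len(sidecars) != 1:
            raise FormatError(f"expected exactly one family sidecar in "
                              f"{path}, found {len(sidecars)}")
        path = sidecars[0]
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as e:  # pragma: no cover - defensive
        raise FormatError(f"sidecar {path} is not valid JSON: {e}") from e
    if meta.get("format") != "navclamp-sweep-family/1":
        raise FormatError("unrecognized sidecar format tag")
    proto_kw = dict(meta["protocol"])
    proto_kw["test_voltages"] = tuple(proto_kw["test_voltages"])
    protocol = StepProtocol(**proto_kw)
    sweeps: list[Sweep] = []
    for cond, fname in meta["conditions"].items():
        csv_path = path.parent / fname
        with open(csv_path) as fh:
            header = fh.readline().rstrip("\n").split(",")
        if header[0] != "time_ms":
            raise FormatError(f"{fname}: first column must be time_ms")
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise FormatError(f"{fname}: duplicated column header {dupes}")
        df = pd.read_csv(csv_path, float_precision="round_trip")
        df.columns = header  # undo any parser renaming of odd headers
        t = df["time_ms"].to_numpy()
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise FormatError(f"{fname}: ragged/missing values in columns {bad}")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > _TIME_RTOL * abs(dt[0])):
            raise FormatError(f"{fname}: non-uniform time base in time_ms")
        seen_voltages = set()
        for col in df.columns[1:]:
            m = _COL_RE.match(col)
            if not m:
                raise FormatError(f"{fname}: malformed column header {col!r}")
            v = float(m.group("v"))
            seen_voltages.add(v)
            if v not in protocol.test_voltages:
                raise FormatError(
                    f"{fname}: column {col!r} voltage {v} mV absent from protocol")
            meta_d = {}
            if m.group("sub") is not None:
                meta_d["sub_index"] = int(m.group("sub"))
            sweeps.append(Sweep(
                time=t, current=df[col].to_numpy(), test_voltage=v,
                condition=cond, role=m.group("role"),
                repeat_index=int(m.group("rep")), meta=meta_d))
        missing = set(protocol.test_voltages) - seen_voltages
        if missing:
            raise FormatError(
                f"{fname}: protocol voltage(s) {sorted(missing)} mV have no column")
    return SweepFamily(
        sweeps=sweeps, protocol=protocol, cell_id=meta["cell_id"],
        membrane_capacitance=meta["membrane_capacitance"],
        provenance=meta.get("provenance", {}))
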