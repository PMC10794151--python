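"""Current density, conductance density, channel counts and cohort summary.

The channel-count chain converts a macroscopic current density into an
estimated number of channels using two cited microscopic constants: the
single-channel conductance gamma (pS) and the open probability P_o at the
test voltage.  With a textbook specific membrane capacitance of
1 uF/cm^2 = 0.01 pF/um^2:

    conductance density [pS/pF] = 1000 * (pA/pF) / |V - E_r| [mV]
    channels/pF  = (pS/pF) / (gamma * P_o)
    channels/um2 = channels/pF * 0.01
    channels/cell = channels/um2 * cell area

The default cell area (3500 um^2) is a reconstruction back-solved from the
published per-cell endpoints, not a measurement; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ValidationError

__all__ = ["current_density", "conductance_density", "channel_density",
           "channels_per_cell", "classify_responder", "summarize_cohort",
           "DensityEstimate", "CohortSummary"]

SPECIFIC_CAPACITANCE = 0.01  # pF / um^2 (1 uF / cm^2)
DEFAULT_CELL_AREA = 3500.0  # um^2, reconstruction
RESPONDER_PEAK_PA = 30.0
RESPONDER_TAU_CUTOFF_MS = 5.0


@dataclass
class DensityEstimate:
    current_density: float  # pA/pF
    conductance_density: float  # pS/pF
    e_rev_used: float  # mV
    gamma: float  # pS
    p_open: float
    channels_per_pF: float
    channels_per_um2: float  # unrounded
    channels_per_um2_rounded: float  # 2 decimals
    channels_per_cell: int
    channels_per_cell_unrounded: float
    specific_capacitance: float = SPECIFIC_CAPACITANCE
    cell_area: float = DEFAULT_CELL_AREA


@dataclass
class CohortSummary:
    n_cells: int
    n_responders: int
    responder_fraction_pct: int  # rounded to nearest integer
    mean_sem: dict = field(default_factory=dict)  # responder-only summaries


def current_density(peak: float, c_m: float) -> float:
    """Peak magnitude per unit capacitance, pA/pF."""
    if c_m <= 0:
        raise ValidationError("membrane capacitance must be > 0")
    return abs(peak) / c_m


def conductance_density(cd: float, v_test: float, e_rev: float) -> float:
    """Chord conductance density in pS/pF from a current density in pA/pF."""
    if v_test == e_rev:
        raise ValidationError("driving force is zero: v_test equals e_rev")
    return 1000.0 * cd / abs(v_test - e_rev)


def channel_density(gd: float, gamma: float, p_open: float,
                    specific_capacitance: float = SPECIFIC_CAPACITANCE,
                    ) -> tuple[float, float]:
    """(channels/pF, channels/um^2) from conductance density."""
    if gamma <= 0:
        raise ValidationError("single-channel conductance must be > 0")
    if not (0 < p_open <= 1):
        raise ValidationError("open probability must lie in (0, 1]")
    per_pf = gd / (gamma * p_open)
    return per_pf, per_pf * specific_capacitance


def channels_per_cell(density_um2_rounded: float,
                      cell_area: float = DEFAULT_CELL_AREA) -> int:
    """Channel count from an areal density; uses the 2-decimal density."""
    if density_um2_rounded < 0:
        raise ValidationError("channel density must be >= 0")
    return int(round(density_um2_rounded * cell_area))


def estimate_density(peak: float, c_m: float, v_test: float, e_rev: float,
                     gamma: float, p_open: float,
                     specific_capacitance: float = SPECIFIC_CAPACITANCE,
                     cell_area: float = DEFAULT_CELL_AREA) -> DensityEstimate:
    """Full chain: peak current -> channels per cell."""
    cd = current_density(peak, c_m)
    gd = conductance_density(cd, v_test, e_rev)
    per_pf, per_um2 = channel_density(gd, gamma, p_open, specific_capacitance)
    rounded = round(per_um2, 2)
    return DensityEstimate(
        current_density=cd, conductance_density=gd, e_rev_used=e_rev,
        gamma=gamma, p_open=p_open, channels_per_pF=per_pf,
        channels_per_um2=per_um2, channels_per_um2_rounded=rounded,
        channels_per_cell=channels_per_cell(rounded, cell_area),
        channels_per_cell_unrounded=per_um2 * cell_area,
        specific_capacitance=specific_capacitance, cell_area=cell_area)


def classify_responder(peak: float, tau_at_0mV: float | None,
                       peak_threshold: float = RESPONDER_PEAK_PA,
                       tau_fast_cutoff: float = RESPONDER_TAU_CUTOFF_MS) -> bool:
    """Responder: fast-inactivating current with peak strictly above 30 pA."""
    if tau_at_0mV is None or not math.isfinite(tau_at_0mV):
        return False
    return abs(peak) > peak_threshold and tau_at_0mV <= tau_fast_cutoff


def _mean_sem(values: list[float]) -> dict:
    vals = np.array([v for v in values if v is not None and math.isfinite(v)])
    if vals.size == 0:
        return {"mean": None, "sem": None, "n": 0}
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
    return {"mean": mean, "sem": sem, "n": int(vals.size)}


def summarize_cohort(cell_results: list[dict]) -> CohortSummary:
    """Descriptive cohort summary (no hypothesis tests).

    Each cell record is a dict with at least ``responder`` (bool) and,
    where measured, ``peak_pA`` (magnitude), ``current_density_pA_pF``,
    ``tau_0mV_ms`` and per-drug ``percent_inhibition``.
    """
    if not cell_results:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(cell_results)
    responders = [c for c in cell_results if c.get("responder")]
    frac = int(round(100.0 * len(responders) / n))
    mean_sem = {
        "peak_pA": _mean_sem([c.get("peak_pA") for c in responders]),
        "current_density_pA_pF": _mean_sem(
            [c.get("current_density_pA_pF") for c in responders]),
        "tau_0mV_ms": _mean_sem([c.get("tau_0mV_ms") for c in responders]),
    }
    drugs = sorted({k for c in cell_results
                    for k in c.get("percent_inhibition", {})})
    for d in drugs:
        mean_sem[f"percent_inhibition_{d}"] = _mean_sem(
            [c.get("percent_inhibition", {}).get(d) for c in responders])
    return CohortSummary(n_cells=n, n_responders=len(responders),
                         responder_fraction_pct=frac, mean_sem=mean_sem)
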