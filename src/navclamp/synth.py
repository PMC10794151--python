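"""Cohort, PSM-table and fluorescence fixtures for offline testing.

Everything downstream of a recording rig is exercised with data produced
here: a multi-cell voltage-clamp cohort with a controlled responder count,
a peptide-spectrum-match abundance table with planted screen hits and
single-failure decoys, and fluorescence transients with known amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import default_params
from .ca_flux import FluorescenceTrace
from .model import CONTROL, GatingModelParams, StepProtocol, ValidationError
from .simulate import simulate_family
from .traces import SweepFamily

__all__ = ["generate_cohort", "generate_psm_fixture", "generate_fluorescence",
           "COHORT_PROTOCOL", "CohortCell"]

# Cohort cells are classified from a single 0 mV test step (peak amplitude
# and inactivation tau at 0 mV are the classifier inputs), so the cohort
# protocol records only that voltage with the standard 8-run averaging.
COHORT_PROTOCOL = StepProtocol(
    test_voltages=(0.0,), step_onset=5.0, step_duration=25.0,
    sweep_duration=32.0, p4_enabled=True, n_repeats_per_voltage=8)

CM_RANGE_PF = (25.0, 45.0)  # documented per-cell capacitance range
SLOW_TAU_SCALE = 8.0  # slow-phenotype cells: tau(0 mV) ~ 8 ms > 5 ms cutoff


@dataclass
class CohortCell:
    cell_id: str
    family: SweepFamily
    capacitance: float  # pF
    truth: dict  # generator ground truth for recovery tests


def _noise_free_peak0(params: GatingModelParams) -> float:
    """Peak magnitude of the noise-free control current at 0 mV."""
    from .isolation import peak_amplitude
    from .preprocess import preprocess_family
    fams = simulate_family(COHORT_PROTOCOL, params, [CONTROL], seed=None)
    processed = preprocess_family(fams["control"], "control")
    peak, _ = peak_amplitude(processed[0.0], COHORT_PROTOCOL.step_onset)
    return abs(peak)


def generate_cohort(n_cells: int = 77, n_responders: int = 13,
                    amplitude_range: tuple[float, float] = (40.0, 124.0),
                    seed: int = 0,
                    params: GatingModelParams | None = None) -> list[CohortCell]:
    """Simulate a cohort with a controlled number of responder cells.

    Responder cells carry the calibrated fast-inactivating gating scaled to
    a peak magnitude drawn from ``amplitude_range`` (must sit strictly above
    the 30 pA responder boundary).  Non-responders alternate between a
    low-amplitude phenotype (peak <= ~22 pA, safely under the boundary even
    with noise) and a slow-inactivating phenotype whose tau at 0 mV exceeds
    the 5 ms fast cutoff.  Per-cell capacitance is uniform on 25-45 pF.
    """
    if n_responders > n_cells:
        raise ValidationError("n_responders cannot exceed n_cells")
    if amplitude_range[0] <= 30.0 or amplitude_range[1] <= amplitude_range[0]:
        raise ValidationError(
            "responder amplitude range must sit strictly above the 30 pA "
            "boundary and be increasing")
    params = params or default_params()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0)))
    base_peak_fast = _noise_free_peak0(params)
    slow = params.with_(tau_h_anchors=tuple(
        (v, t * SLOW_TAU_SCALE) for v, t in params.tau_h_anchors))
    base_peak_slow = _noise_free_peak0(slow)

    cells: list[CohortCell] = []
    for i in range(n_cells):
        responder = i < n_responders
        cm = float(rng.uniform(*CM_RANGE_PF))
        if responder:
            target = float(rng.uniform(*amplitude_range))
            scale = target / base_peak_fast
            cell_params = params
        elif i % 2 == 0:
            target = float(rng.uniform(3.0, 22.0))
            scale = target / base_peak_fast
            cell_params = params
        else:
            target = float(rng.uniform(*amplitude_range))
            scale = target / base_peak_slow
            cell_params = slow
        cell_params = cell_params.with_(
            g_nav17=cell_params.g_nav17 * scale,
            g_ttxs_other=cell_params.g_ttxs_other * scale,
            g_ttxr=cell_params.g_ttxr * scale,
            c_m=cm)
        cell_seed = int(rng.integers(0, 2 ** 31 - 1))
        fam = simulate_family(COHORT_PROTOCOL, cell_params, [CONTROL],
                              seed=cell_seed, cell_id=f"cell{i:03d}")["control"]
        cells.append(CohortCell(
            cell_id=f"cell{i:03d}", family=fam, capacitance=cm,
            truth={"responder": responder, "target_peak_pA": target,
                   "phenotype": ("fast" if cell_params is not slow else "slow"),
                   "seed": cell_seed}))
    return cells


# ---------------------------------------------------------------------------
# PSM fixture

def generate_psm_fixture(seed: int = 0) -> pd.DataFrame:
    """Synthetic PSM abundance table for the secretome screen.

    Plants exactly six rows passing the three-criterion filter - including
    HSP70 (30-100 kDa fraction) and midkine (10-30 kDa fraction); the other
    four passer identities are synthetic placeholders - plus decoys that
    each fail exactly one criterion (molecular weight outside both windows,
    enrichment in only one treatment, fold change of exactly 2, or a missing
    secreted annotation).  The seed only jitters decoy counts; the planted
    pass/fail structure is deterministic.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x95)))
    j = lambda lo, hi: int(rng.integers(lo, hi + 1))
    rows = [
        # --- six planted passers -----------------------------------------
        ("P0DMV8", "HSPA1A", 70.0, True, "30-100", 0, j(8, 14), j(6, 12)),
        ("P21741", "MDK", 15.6, True, "10-30", 0, j(5, 9), j(4, 8)),
        ("SYN0001", "SECA", 23.2, True, "10-30", 3, 8, 7),
        ("SYN0002", "SECB", 52.4, True, "30-100", 4, 9, 13),
        ("SYN0003", "SECC", 34.6, True, "30-100", 0, j(3, 6), j(4, 8)),
        ("SYN0004", "SECD", 15.8, True, "10-30", 2, 5, 9),
        # --- decoys, each failing exactly one criterion ------------------
        # wrong MW window (262 kDa), otherwise unique in both & secreted
        ("P02751", "FN1", 262.0, True, "30-100", 0, j(4, 9), j(4, 9)),
        # tiny peptide below both windows
        ("SYN0101", "PEPS", 5.0, True, "10-30", 0, j(3, 6), j(3, 6)),
        # enriched only under PF, not ProTx II
        ("P05121", "SERPINE1", 45.0, True, "30-100", 2, 7, 3),
        # fold change exactly 2.0 under PF (criterion is strictly > 2)
        ("P61769", "B2M", 13.7, True, "10-30", 4, 8, 9),
        # intracellular contaminant: enriched in both but not secreted
        ("P60709", "ACTB", 41.7, False, "30-100", 1, j(5, 9), j(5, 9)),
        ("P04406", "GAPDH", 36.0, False, "30-100", 0, j(4, 8), j(4, 8)),
        # unchanged background protein (vehicle-rich, not enriched)
        ("P02768", "ALB", 69.4, True, "30-100", 30, 31, 29),
    ]
    return pd.DataFrame(rows, columns=[
        "protein_id", "gene", "mw_kda", "secreted", "fraction",
        "psm_vehicle", "psm_pf", "psm_protx"])


# ---------------------------------------------------------------------------
# fluorescence fixture

def generate_fluorescence(baseline_frames: int = 30, amplitude: float = 150.0,
                          f0: float = 100.0, sustained_fraction: float = 0.2,
                          rise_s: float = 6.0, decay_s: float = 40.0,
                          n_frames: int = 150, frame_interval_s: float = 2.0,
                          noise_sd: float = 0.0,
                          seed: int | None = None) -> FluorescenceTrace:
    """Baseline plateau followed by a calcium-like transient.

    The transient shape (exponential rise then decay toward a sustained
    plateau) is normalized so its sampled maximum equals ``amplitude``
    exactly, making the noise-free peak F/F0 equal to 1 + amplitude/f0 by
    construction.  Frames are 2 s apart by default.
    """
    if baseline_frames < 2:
        raise ValidationError("need at least 2 baseline frames")
    if n_frames <= baseline_frames:
        raise ValidationError("n_frames must exceed baseline_frames")
    t = np.arange(n_frames) * frame_interval_s
    f = np.full(n_frames, float(f0))
    s = t[baseline_frames:] - t[baseline_frames]
    shape = (1 - np.exp(-s / rise_s)) * (
        sustained_fraction + (1 - sustained_fraction) * np.exp(-s / decay_s))
    if amplitude != 0 and shape.max() > 0:
        shape = shape / shape.max()
    f[baseline_frames:] += amplitude * shape
    if noise_sd > 0 and seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF1)))
        f = f + rng.normal(0.0, noise_sd, size=n_frames)
    return FluorescenceTrace(time=t, intensity=f,
                             stimulus_onset_index=baseline_frames,
                             meta={"amplitude": amplitude, "f0": f0})
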