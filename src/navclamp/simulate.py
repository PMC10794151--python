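"""Closed-form voltage-clamp current simulator.

Under a rectangular step protocol the command voltage is piecewise constant,
so each first-order gate has an exact exponential solution on every segment.
The simulator evaluates those solutions on the 100 kHz sample grid - there
is no discretization error in the gating, only in where the grid samples the
continuous trace.

Current convention: inward current is negative.  For each channel pool

    I_pool(t) = g_eff * m(t) * h(t) * (V(t) - e_rev_sim)

with gates initialized at steady state for the holding potential and, after
every voltage transition, held at their pre-transition values for the pool's
first-latency before relaxing exponentially toward the new steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .model import (CONTROL, DrugState, GatingModelParams, ProtocolError,
                    StepProtocol, ValidationError)
from .traces import Sweep, SweepFamily

__all__ = ["simulate_sweep", "simulate_family", "sweep_seed"]

_POOLS = ("nav17", "ttxs_other", "ttxr")


def _segments(protocol: StepProtocol, test_voltage: float,
              holding: float | None = None) -> list[tuple[float, float, float]]:
    """(t_start, t_end, V) segments of one sweep."""
    hold = protocol.holding if holding is None else holding
    return [
        (0.0, protocol.step_onset, hold),
        (protocol.step_onset, protocol.step_end, test_voltage),
        (protocol.step_end, protocol.sweep_duration, hold),
    ]


def _gate_segment(t: np.ndarray, t0: float, x0: float, x_inf: float,
                  tau: float, lat: float) -> np.ndarray:
    """Exact gate trajectory on one constant-voltage segment.

    The gate holds ``x0`` for ``lat`` ms after the segment start ``t0`` and
    then relaxes exponentially toward ``x_inf`` with time constant ``tau``.
    """
    s = t - t0 - lat
    out = x_inf + (x0 - x_inf) * np.exp(-np.maximum(s, 0.0) / tau)
    return np.where(s < 0.0, x0, out)


def _pool_current(t: np.ndarray, segments, params: GatingModelParams,
                  g: float, tau_h_scale: float = 1.0) -> np.ndarray:
    """Current of one channel pool over a full sweep (pA)."""
    current = np.zeros_like(t)
    v_prev = segments[0][2]
    m0 = params.m_inf(v_prev)
    h0 = params.h_inf(v_prev)
    for t0, t1, v in segments:
        mask = (t >= t0) & (t < t1) if t1 < segments[-1][1] else (t >= t0)
        lat = params.latency(v) if v != v_prev else 0.0
        tau_m = params.tau_m(v)
        tau_h = params.tau_h(v) * tau_h_scale
        m = _gate_segment(t[mask], t0, m0, params.m_inf(v), tau_m, lat)
        h = _gate_segment(t[mask], t0, h0, params.h_inf(v), tau_h, lat)
        current[mask] = g * m * h * (v - params.e_rev_sim)
        # end-of-segment gate state seeds the next segment
        s = t1 - t0 - lat
        if s <= 0:
            pass  # gates never started relaxing
        else:
            m0 = params.m_inf(v) + (m0 - params.m_inf(v)) * math.exp(-s / tau_m)
            h0 = params.h_inf(v) + (h0 - params.h_inf(v)) * math.exp(-s / tau_h)
        v_prev = v
    return current


def _edge_transients(t: np.ndarray, segments, params: GatingModelParams) -> np.ndarray:
    """Synthetic linear RC edge transient at each voltage transition.

    Amplitude dV/R_s with decay tau = R_s * C_m; linear in dV so the P/4
    protocol cancels it exactly.
    """
    out = np.zeros_like(t)
    tau = params.r_series * params.c_m * 1e-3  # MOhm * pF = us -> ms
    v_prev = segments[0][2]
    for t0, _t1, v in segments:
        dv = v - v_prev
        if dv != 0.0:
            amp = dv / params.r_series * 1e3  # mV / MOhm = nA -> pA
            s = t - t0
            out += np.where(s >= 0, amp * np.exp(-np.maximum(s, 0.0) / tau), 0.0)
        v_prev = v
    return out


def sweep_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-sweep seed: SeedSequence keyed on (master, index)."""
    return np.random.SeedSequence((int(master_seed), int(index)))


def _simulate_trace(params: GatingModelParams, segments,
                    drug: DrugState, rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(segments[-1][1] / params.dt_ms))
    t = np.arange(n) * params.dt_ms
    factors = drug.pool_factors()
    current = params.g_leak * (np.zeros(n) + segments[0][2] - params.e_leak)
    # leak follows the command voltage instantaneously
    for t0, t1, v in segments:
        mask = (t >= t0) & (t < t1) if t1 < segments[-1][1] else (t >= t0)
        current[mask] = params.g_leak * (v - params.e_leak)
    g_map = {"nav17": params.g_nav17, "ttxs_other": params.g_ttxs_other,
             "ttxr": params.g_ttxr}
    for pool in _POOLS:
        g_eff = g_map[pool] * factors[pool]
        if g_eff == 0.0:
            continue
        scale = params.ttxr_tau_h_scale if pool == "ttxr" else 1.0
        current += _pool_current(t, segments, params, g_eff, tau_h_scale=scale)
    if params.cap_transient:
        current += _edge_transients(t, segments, params)
    if params.smooth:
        # Gaussian kernel matched to the 2 kHz low-pass character:
        # sigma_t = 0.1325 / f_c for a -3 dB point at f_c.
        sigma_samples = 0.1325 / params.filter_cutoff * params.sample_rate
        current = gaussian_filter1d(current, sigma_samples, mode="nearest")
    if rng is not None and params.noise_sd > 0:
        current = current + rng.normal(0.0, params.noise_sd, size=n)
    return t, current


def simulate_sweep(test_voltage: float, params: GatingModelParams,
                   drug: DrugState = CONTROL, protocol: StepProtocol | None = None,
                   seed: int | np.random.SeedSequence | None = None,
                   repeat_index: int = 0) -> Sweep:
    """Simulate one main sweep at ``test_voltage``.

    With ``seed`` absent the sweep is noise-free and deterministic.
    """
    protocol = protocol or StepProtocol()
    if not params.covers(test_voltage):
        raise ProtocolError(f"test voltage {test_voltage} mV outside coverage")
    if not math.isfinite(test_voltage):
        raise ProtocolError("non-finite test voltage")
    rng = None if seed is None else np.random.default_rng(seed)
    t, i = _simulate_trace(params, _segments(protocol, test_voltage), drug, rng)
    return Sweep(time=t, current=i, test_voltage=test_voltage,
                 condition=drug.label, role="main", repeat_index=repeat_index)


def _p4_subsweeps(test_voltage: float, params: GatingModelParams,
                  protocol: StepProtocol, drug: DrugState,
                  seeds, repeat_index: int) -> list[Sweep]:
    dv = (test_voltage - protocol.holding) / 4.0
    sub_v = protocol.p4_subholding + dv
    out = []
    for k in range(4):
        rng = None if seeds is None else np.random.default_rng(seeds[k])
        segs = _segments(protocol, sub_v, holding=protocol.p4_subholding)
        t, i = _simulate_trace(params, segs, drug, rng)
        out.append(Sweep(time=t, current=i, test_voltage=test_voltage,
                         condition=drug.label, role="p4_sub",
                         repeat_index=repeat_index, meta={"sub_index": k}))
    return out


def simulate_family(protocol: StepProtocol, params: GatingModelParams,
                    conditions: list[DrugState] | None = None,
                    seed: int | None = None, cell_id: str = "sim",
                    ) -> dict[str, SweepFamily]:
    """Simulate a full sweep family per condition.

    Emits ``n_repeats_per_voltage`` main sweeps per test voltage per
    condition plus four P/4 subsweeps per main sweep when enabled.  Per-sweep
    noise seeds derive deterministically from the master seed and a running
    sweep counter, so the same master seed reproduces the family bit for bit.
    """
    conditions = conditions or [CONTROL]
    out: dict[str, SweepFamily] = {}
    counter = 0
    for drug in conditions:
        sweeps: list[Sweep] = []
        for v in protocol.test_voltages:
            for rep in range(protocol.n_repeats_per_voltage):
                s = None if seed is None else sweep_seed(seed, counter)
                counter += 1
                sweeps.append(simulate_sweep(v, params, drug, protocol,
                                             seed=s, repeat_index=rep))
                if protocol.p4_enabled:
                    if seed is None:
                        sub_seeds = None
                    else:
                        sub_seeds = [sweep_seed(seed, counter + k) for k in range(4)]
                    counter += 4
                    sweeps.extend(_p4_subsweeps(v, params, protocol, drug,
                                                sub_seeds, rep))
        out[drug.label] = SweepFamily(
            sweeps=sweeps, protocol=protocol, cell_id=cell_id,
            membrane_capacitance=params.c_m,
            provenance={"source": "simulated",
                        "truth": {"v_half_m": params.v_half_m,
                                  "k_m": params.k_m,
                                  "e_rev_sim": params.e_rev_sim},
                        "seed": seed, "condition": drug.label})
    return out
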