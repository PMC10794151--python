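"""Core parameter types for the voltage-clamp simulator.

Units follow patch-clamp convention throughout the package: time in ms,
voltage in mV, current in pA, conductance in nS, capacitance in pF.
With these units I = g * (V - E) comes out directly in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Anchors",
    "GatingModelParams",
    "StepProtocol",
    "DrugState",
    "ValidationError",
    "ProtocolError",
]


class ValidationError(ValueError):
    """Raised when a parameter set or input object violates its contract."""


class ProtocolError(ValueError):
    """Raised when a requested voltage or window falls outside the protocol."""


Anchors = Sequence[tuple[float, float]]  # (voltage mV, value) pairs


def _check_anchors(name: str, anchors: Anchors, positive: bool = True) -> None:
    if len(anchors) < 1:
        raise ValidationError(f"{name}: need at least one anchor")
    volts = [v for v, _ in anchors]
    if sorted(volts) != volts or len(set(volts)) != len(volts):
        raise ValidationError(f"{name}: anchor voltages must be strictly increasing")
    for v, x in anchors:
        if not (math.isfinite(v) and math.isfinite(x)):
            raise ValidationError(f"{name}: non-finite anchor ({v}, {x})")
        if positive and x <= 0:
            raise ValidationError(f"{name}: values must be > 0 (got {x} at {v} mV)")
        if not positive and x < 0:
            raise ValidationError(f"{name}: values must be >= 0 (got {x} at {v} mV)")


def interp_anchors(anchors: Anchors, voltage: float, log_space: bool = True) -> float:
    """Interpolate an anchor table at ``voltage``.

    Interpolation is linear in log(value) versus voltage (guaranteeing a
    positive result), clamped to the outermost anchors beyond their range.
    Tables with non-positive entries (latencies may be zero) interpolate
    linearly instead.
    """
    volts = np.array([v for v, _ in anchors], dtype=float)
    vals = np.array([x for _, x in anchors], dtype=float)
    if log_space and np.all(vals > 0):
        return float(np.exp(np.interp(voltage, volts, np.log(vals))))
    return float(np.interp(voltage, volts, vals))


@dataclass(frozen=True)
class GatingModelParams:
    """Ground-truth gating model for the synthetic voltage-clamp simulator.

    The model is Hodgkin-Huxley-like with one first-order activation gate m
    and one first-order inactivation gate h per channel pool:

        m_inf(V) = 1 / (1 + exp((v_half_m - V) / k_m))
        h_inf(V) = 1 / (1 + exp((V - v_half_h) / k_h))

    Gate time constants are tabulated at anchor voltages and interpolated
    log-linearly.  In addition each pool carries a voltage-dependent
    first-latency ``lat_anchors`` (ms): after a voltage change the gates hold
    their pre-step values for the latency before relaxing.  This reproduces
    the empirical observation that the macroscopic current peaks *later* than
    its post-peak decay time constant, which a latency-free first-order
    activation gate cannot do (with m rising as 1 - exp(-t/tau_m) and h
    decaying toward ~0, the peak time tau_m*log(1 + tau_h/tau_m) is strictly
    below tau_h).

    Channel pools:
      * ``g_nav17``      blocked by both TTX and ProTx II,
      * ``g_ttxs_other`` blocked by TTX only,
      * ``g_ttxr``       resistant to both; its inactivation is slowed by
        ``ttxr_tau_h_scale`` so it supplies the persistent (slow-inactivating)
        current measured at 10 ms.
    """

    v_half_m: float = -14.2  # mV, activation midpoint
    k_m: float = 6.1  # mV, activation slope (> 0)
    v_half_h: float = -70.0  # mV, steady-state inactivation midpoint
    k_h: float = 7.0  # mV, inactivation slope (> 0)
    tau_m_anchors: Anchors = ((-20.0, 0.33), (0.0, 0.10), (50.0, 0.03))
    tau_h_anchors: Anchors = ((-20.0, 3.3), (0.0, 1.0), (50.0, 0.3))
    lat_anchors: Anchors = ((-20.0, 1.0), (0.0, 1.15), (50.0, 0.42))
    g_nav17: float = 5.1  # nS
    g_ttxs_other: float = 2.8  # nS
    g_ttxr: float = 3.3  # nS
    g_leak: float = 2.0  # nS
    ttxr_tau_h_scale: float = 36.0  # slow-inactivating TTX-R pool
    e_rev_sim: float = 65.0  # mV, simulated Na reversal (Nernst-like)
    e_leak: float = -90.0  # mV
    c_m: float = 34.0  # pF
    noise_sd: float = 2.0  # pA
    sample_rate: float = 100_000.0  # Hz
    filter_cutoff: float = 2_000.0  # Hz
    smooth: bool = False  # apply the 2 kHz Gaussian kernel
    cap_transient: bool = False  # synthetic linear RC edge transient
    r_series: float = 10.0  # MOhm, only used for the edge transient

    def __post_init__(self) -> None:
        for name in ("k_m", "k_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("g_nav17", "g_ttxs_other", "g_ttxr", "g_leak"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        scalars = (
            self.v_half_m, self.k_m, self.v_half_h, self.k_h, self.g_nav17,
            self.g_ttxs_other, self.g_ttxr, self.g_leak, self.e_rev_sim,
            self.e_leak, self.c_m, self.noise_sd, self.sample_rate,
            self.filter_cutoff, self.ttxr_tau_h_scale,
        )
        if not all(math.isfinite(x) for x in scalars):
            raise ValidationError("non-finite value in gating parameters")
        if self.sample_rate <= 2 * self.filter_cutoff:
            raise ValidationError("sample_rate must exceed 2 x filter_cutoff")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.ttxr_tau_h_scale <= 0:
            raise ValidationError("ttxr_tau_h_scale must be > 0")
        _check_anchors("tau_m_anchors", self.tau_m_anchors)
        _check_anchors("tau_h_anchors", self.tau_h_anchors)
        _check_anchors("lat_anchors", self.lat_anchors, positive=False)

    # -- gate functions ----------------------------------------------------
    def m_inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp((self.v_half_m - v) / self.k_m))

    def h_inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp((v - self.v_half_h) / self.k_h))

    def tau_m(self, v: float) -> float:
        return interp_anchors(self.tau_m_anchors, v)

    def tau_h(self, v: float) -> float:
        return interp_anchors(self.tau_h_anchors, v)

    def latency(self, v: float) -> float:
        return max(0.0, interp_anchors(self.lat_anchors, v, log_space=False))

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def covers(self, voltage: float) -> bool:
        """True if the tau tables cover ``voltage`` after clamping.

        Clamping at the outermost anchors means any finite voltage is
        covered; the check guards the [-60, +50] protocol range explicitly
        so a mis-specified table fails loudly.
        """
        return math.isfinite(voltage)

    def with_(self, **kwargs) -> "GatingModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StepProtocol:
    """A rectangular test-step protocol from a fixed holding potential."""

    holding: float = -90.0  # mV
    test_voltages: tuple[float, ...] = tuple(float(v) for v in range(-60, 51, 10))
    step_onset: float = 5.0  # ms
    step_duration: float = 45.0  # ms
    sweep_duration: float = 55.0  # ms
    p4_enabled: bool = True
    p4_subholding: float = -90.0  # mV
    n_repeats_per_voltage: int = 1

    def __post_init__(self) -> None:
        tv = tuple(float(v) for v in self.test_voltages)
        object.__setattr__(self, "test_voltages", tv)
        if list(tv) != sorted(tv) or len(set(tv)) != len(tv):
            raise ValidationError("test voltages must be strictly increasing")
        if not tv:
            raise ValidationError("need at least one test voltage")
        if not (0 <= self.step_onset < self.step_onset + self.step_duration
                <= self.sweep_duration):
            raise ValidationError("step window must fit inside the sweep")
        if self.n_repeats_per_voltage < 1:
            raise ValidationError("n_repeats_per_voltage must be >= 1")

    @property
    def step_end(self) -> float:
        return self.step_onset + self.step_duration


@dataclass(frozen=True)
class DrugState:
    """Static pharmacological condition.

    ``ttx_block_fraction`` scales down g_nav17 and g_ttxs_other (1 uM TTX
    blocks all Na_v isoforms except Na_v1.5/1.8/1.9); ``protx_block_fraction``
    scales down g_nav17 only (20 nM ProTx II is Na_v1.7-selective).
    """

    ttx_block_fraction: float = 0.0
    protx_block_fraction: float = 0.0
    label: str = "control"

    def __post_init__(self) -> None:
        for name in ("ttx_block_fraction", "protx_block_fraction"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {x}")

    def pool_factors(self) -> dict[str, float]:
        """Multiplicative survival factor for each channel pool."""
        return {
            "nav17": (1 - self.ttx_block_fraction) * (1 - self.protx_block_fraction),
            "ttxs_other": 1 - self.ttx_block_fraction,
            "ttxr": 1.0,
        }


CONTROL = DrugState(0.0, 0.0, "control")
TTX = DrugState(1.0, 0.0, "TTX")
PROTX = DrugState(0.0, 1.0, "ProTxII")
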