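"""Peak I-V curves, chord conductance and the Boltzmann activation fit.

The activation curve is the normalized peak chord conductance

    G(V) = |I_peak(V)| / |V - E_r|,   G/G_max fitted by
    G/G_max(V) = A / (1 + exp((V1/2 - V) / k))

with the amplitude A constrained near 1.  Two reversal-potential
conventions are supported: "simulation" mode uses the simulator's (or an
estimated) reversal, "published" mode carries the reported reversal constant
verbatim so downstream conductance/density arithmetic reproduces a
published derivation chain exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .model import ValidationError
from .traces import SweepFamily

__all__ = ["IVCurve", "BoltzmannFit", "FitError", "build_iv",
           "estimate_reversal", "nernst_potential", "conductance_curve",
           "fit_boltzmann", "activation_threshold", "boltzmann"]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge."""


@dataclass
class IVCurve:
    """Peak current versus test voltage for one condition."""

    points: list[tuple[float, float]]  # (V mV, signed peak pA), sorted by V
    condition: str = "control"
    n_cells_averaged: int = 1

    def __post_init__(self) -> None:
        volts = [v for v, _ in self.points]
        if sorted(volts) != volts or len(set(volts)) != len(volts):
            raise ValidationError("I-V voltages must be unique and sorted")

    @property
    def voltages(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    @property
    def peaks(self) -> np.ndarray:
        return np.array([i for _, i in self.points])


@dataclass
class BoltzmannFit:
    v_half: float  # mV
    k: float  # mV, > 0
    amplitude: float  # dimensionless, constrained to [0.8, 1.2]
    residual_rms: float
    covariance: np.ndarray = field(repr=False)
    e_rev_used: float = float("nan")
    k_at_bound: bool = False


def boltzmann(v, v_half: float, k: float, amplitude: float = 1.0):
    return amplitude / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


def build_iv(processed: dict[float, "Sweep"], step_onset: float,
             condition: str = "control") -> IVCurve:
    """One (V, peak) point per test voltage of a preprocessed family."""
    from .isolation import peak_amplitude
    pts = []
    for v in sorted(processed):
        peak, _t = peak_amplitude(processed[v], step_onset)
        pts.append((float(v), peak))
    return IVCurve(points=pts, condition=condition)


def build_iv_from_family(family: SweepFamily, condition: str) -> IVCurve:
    from .preprocess import preprocess_family
    processed = preprocess_family(family, condition)
    return build_iv(processed, family.protocol.step_onset, condition)


def estimate_reversal(iv: IVCurve, n_tail_points: int = 3) -> float:
    """Extrapolate the reversal potential from the depolarized I-V limb.

    Fits a straight line through the ``n_tail_points`` most-depolarized
    points and returns its zero crossing.
    """
    if len(iv.points) < n_tail_points:
        raise ValidationError(
            f"need at least {n_tail_points} I-V points, have {len(iv.points)}")
    v = iv.voltages[-n_tail_points:]
    i = iv.peaks[-n_tail_points:]
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise ValidationError("flat I-V tail: reversal extrapolation undefined")
    return float(-intercept / slope)


def nernst_potential(c_out: float, c_in: float, temperature: float = 294.0) -> float:
    """Nernst equilibrium potential in mV for a monovalent cation."""
    if c_out <= 0 or c_in <= 0:
        raise ValidationError("concentrations must be > 0")
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY * np.log(c_out / c_in)


def conductance_curve(iv: IVCurve, e_rev: float,
                      min_driving_force: float = 5.0) -> list[tuple[float, float]]:
    """Normalized peak chord conductance G/G_max.

    Points with driving force |V - e_rev| below ``min_driving_force`` are
    excluded (the chord conductance diverges there).
    """
    pts = [(v, abs(i) / abs(v - e_rev)) for v, i in iv.points
           if abs(v - e_rev) >= min_driving_force]
    if not pts:
        raise ValidationError("all I-V points fall inside the excluded "
                              "driving-force band around e_rev")
    gmax = max(g for _, g in pts)
    if gmax == 0:
        return [(v, 0.0) for v, _ in pts]
    return [(v, g / gmax) for v, g in pts]


def fit_boltzmann(gnorm: list[tuple[float, float]],
                  e_rev_used: float = float("nan")) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized conductance curve."""
    if len(gnorm) < 4:
        raise ValidationError("Boltzmann fit needs at least 4 points")
    v = np.array([p[0] for p in gnorm])
    g = np.array([p[1] for p in gnorm])
    if g.max() <= g.min():
        raise ValidationError("conductance curve is flat; no inflection to fit")
    # initial guesses: half-maximum crossing and 10-90% rise width
    half_idx = int(np.argmin(np.abs(g - 0.5)))
    v0 = float(v[half_idx])
    above = v[g >= 0.9]
    below = v[g <= 0.1]
    if above.size and below.size:
        k0 = max(0.5, float(above.min() - below.max()) / 4.4)  # 10-90% ~ 4.4 k
    else:
        k0 = 6.0
    try:
        popt, pcov = curve_fit(
            boltzmann, v, g, p0=[v0, k0, 1.0],
            bounds=([-120.0, 0.05, 0.8], [80.0, 60.0, 1.2]), maxfev=20000)
    except RuntimeError as e:
        raise FitError(f"Boltzmann fit did not converge: {e}") from e
    resid = g - boltzmann(v, *popt)
    k_at_bound = bool(np.isclose(popt[1], 0.05) or np.isclose(popt[1], 60.0))
    return BoltzmannFit(
        v_half=float(popt[0]), k=float(popt[1]), amplitude=float(popt[2]),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))), covariance=pcov,
        e_rev_used=e_rev_used, k_at_bound=k_at_bound)


def activation_threshold(iv: IVCurve, criterion_pA: float = 5.0) -> float | None:
    """Most hyperpolarized test voltage whose peak magnitude reaches criterion."""
    for v, i in iv.points:
        if abs(i) >= criterion_pA and (criterion_pA > 0 or i != 0):
            return float(v)
    return None
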