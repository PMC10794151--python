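"""I-V construction, chord conductance, Boltzmann fit, reversal handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navclamp.activation import (IVCurve, activation_threshold, boltzmann,
                                 conductance_curve, estimate_reversal,
                                 fit_boltzmann, nernst_potential)
from navclamp.model import ValidationError

GRID = [float(v) for v in range(-60, 51, 10)]


def test_build_iv_of_calibrated_family(pipeline):
    """12 points; most-negative current at 0 mV."""
    assert len(pipeline.iv_points) == 12
    v_at_max = max(pipeline.iv_points, key=lambda p: abs(p[1]))[0]
    assert v_at_max == 0.0


def test_missing_voltage_raises(params):
    from navclamp.model import CONTROL, StepProtocol
    from navclamp.preprocess import preprocess_family
    from navclamp.simulate import simulate_family
    proto = StepProtocol()
    fam = simulate_family(proto, params, [CONTROL], seed=None)["control"]
    fam.sweeps = [s for s in fam.sweeps if s.test_voltage != 10.0]
    with pytest.raises(ValidationError, match="10"):
        preprocess_family(fam, "control")


def test_estimate_reversal_recovers_simulator_truth(params, pipeline):
    iv = IVCurve(points=pipeline.iv_points, condition="TTX-S")
    assert estimate_reversal(iv) == pytest.approx(params.e_rev_sim, abs=3.0)


def test_estimate_reversal_two_point_line():
    iv = IVCurve(points=[(20.0, -40.0), (30.0, -30.0), (40.0, -20.0),
                         (50.0, -10.0)])
    assert estimate_reversal(iv, n_tail_points=2) == pytest.approx(60.0)


def test_estimate_reversal_needs_enough_points():
    with pytest.raises(ValidationError):
        estimate_reversal(IVCurve(points=[(0.0, -10.0), (10.0, -5.0)]))


def test_nernst_values():
    assert nernst_potential(145, 10, 294.0) == pytest.approx(67.8, abs=0.1)
    assert nernst_potential(10, 10) == 0.0
    assert nernst_potential(10, 145, 294.0) == pytest.approx(-67.8, abs=0.1)
    with pytest.raises(ValidationError):
        nernst_potential(-1, 10)


def test_chord_conductance_printed_inputs():
    """|{-87 pA}| at 0 mV against E_r = -60.6 mV is 1.436 nS before norm."""
    iv = IVCurve(points=[(-10.0, -60.0), (0.0, -87.0), (10.0, -80.0),
                         (20.0, -60.0)])
    g0 = abs(-87.0) / abs(0.0 - (-60.6))
    assert g0 == pytest.approx(1.436, abs=0.001)
    curve = dict(conductance_curve(iv, e_rev=-60.6))
    assert curve[0.0] == pytest.approx(g0 / max(
        abs(i) / abs(v + 60.6) for v, i in iv.points), rel=1e-12)


def test_ohmic_iv_gives_flat_normalized_conductance():
    e_rev = 65.0
    iv = IVCurve(points=[(v, -2.0 * (e_rev - v)) for v in GRID])
    curve = conductance_curve(iv, e_rev)
    assert all(g == pytest.approx(1.0) for _, g in curve)


def test_excluded_band():
    iv = IVCurve(points=[(-2.0, -5.0), (0.0, -6.0), (2.0, -4.0)])
    with pytest.raises(ValidationError):
        conductance_curve(iv, e_rev=0.0)


def test_boltzmann_selfconsistency_and_midpoint():
    g = [(v, float(boltzmann(v, -14.2, 6.1))) for v in GRID]
    fit = fit_boltzmann(g)
    assert fit.v_half == pytest.approx(-14.2, abs=1e-6)
    assert fit.k == pytest.approx(6.1, abs=1e-6)
    assert boltzmann(-14.2, -14.2, 6.1) == pytest.approx(0.5)
    # predicted activation at 0 mV for the published parameters
    assert boltzmann(0.0, -14.2, 6.1) == pytest.approx(0.911, abs=0.001)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-30, 30))
def test_boltzmann_translation_covariance(shift):
    base = [(v, float(boltzmann(v, -14.2, 6.1))) for v in GRID]
    shifted = [(v + shift, g) for v, g in base]
    f0 = fit_boltzmann(base)
    f1 = fit_boltzmann(shifted)
    assert f1.v_half - f0.v_half == pytest.approx(shift, abs=1e-4)
    assert f1.k == pytest.approx(f0.k, abs=1e-4)


def test_boltzmann_needs_enough_points():
    with pytest.raises(ValidationError):
        fit_boltzmann([(-20.0, 0.1), (0.0, 0.5), (20.0, 0.9)])


def test_activation_threshold(pipeline):
    """5 pA criterion on the calibrated noise-free family: -40 mV."""
    iv = IVCurve(points=pipeline.iv_points)
    assert activation_threshold(iv) == -40.0
    assert activation_threshold(IVCurve(points=[(v, 0.0) for v in GRID])) is None
    tiny = IVCurve(points=[(-60.0, 0.0), (-50.0, -0.01), (-40.0, -3.0)])
    assert activation_threshold(tiny, criterion_pA=0.0) == -50.0
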