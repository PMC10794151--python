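"""Averaging, P/4 leak removal and baseline correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navclamp.model import CONTROL, GatingModelParams, StepProtocol, ValidationError
from navclamp.preprocess import average_sweeps, baseline_correct, p4_subtract
from navclamp.simulate import simulate_family, simulate_sweep
from navclamp.traces import Sweep


def _sweep(current, v=0.0, dt=0.01, **kw):
    t = np.arange(len(current)) * dt
    return Sweep(time=t, current=np.asarray(current, float), test_voltage=v, **kw)


def test_average_identical_sweeps_is_identity(params):
    sw = simulate_sweep(0.0, params)
    avg = average_sweeps([sw] * 8)
    np.testing.assert_allclose(avg.current, sw.current, rtol=1e-14)
    assert avg.meta["n_averaged"] == 8


def test_average_reduces_noise_like_sqrt_n():
    rng = np.random.default_rng(11)
    sigma, n_pts, n_sw = 2.0, 10_000, 8
    sweeps = [_sweep(rng.normal(0, sigma, n_pts)) for _ in range(n_sw)]
    resid = average_sweeps(sweeps).current
    assert resid.std() == pytest.approx(sigma / np.sqrt(n_sw), rel=0.10)


def test_average_rejects_mixed_voltages():
    with pytest.raises(ValidationError):
        average_sweeps([_sweep(np.zeros(100), v=0.0),
                        _sweep(np.zeros(100), v=10.0)])


def test_average_is_linear():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=(2, 500))
    a = 3.7
    lhs = average_sweeps([_sweep(a * x), _sweep(a * y)]).current
    rhs = a * average_sweeps([_sweep(x), _sweep(y)]).current
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(g_leak=st.floats(0.1, 20.0))
def test_p4_removes_pure_leak_exactly(g_leak):
    """On a leak-only cell the P/4-corrected step response is ~0."""
    p = GatingModelParams(g_nav17=0, g_ttxs_other=0, g_ttxr=0,
                          g_leak=g_leak, noise_sd=0)
    proto = StepProtocol(test_voltages=(0.0,), p4_enabled=True)
    fam = simulate_family(proto, p, [CONTROL], seed=None)["control"]
    main = fam.select(role="main")[0]
    subs = fam.select(role="p4_sub")
    corrected = p4_subtract(main, subs)
    corrected = baseline_correct(corrected, proto.step_onset)
    assert np.abs(corrected.current).max() < 0.01


def test_p4_with_capacitive_transient(params):
    """The synthetic RC edge transient is linear in dV, so P/4 removes it."""
    p = params.with_(g_nav17=0, g_ttxs_other=0, g_ttxr=0, cap_transient=True)
    proto = StepProtocol(test_voltages=(10.0,), p4_enabled=True)
    fam = simulate_family(proto, p, [CONTROL], seed=None)["control"]
    corrected = p4_subtract(fam.select(role="main")[0], fam.select(role="p4_sub"))
    corrected = baseline_correct(corrected, proto.step_onset)
    assert np.abs(corrected.current).max() < 0.01


def test_p4_preserves_channel_current(params):
    """Channels + leak, corrected, matches a no-leak channels-only run."""
    proto = StepProtocol(test_voltages=(0.0,), p4_enabled=True)
    fam = simulate_family(proto, params, [CONTROL], seed=None)["control"]
    corrected = baseline_correct(
        p4_subtract(fam.select(role="main")[0], fam.select(role="p4_sub")),
        proto.step_onset)
    clean = simulate_sweep(0.0, params.with_(g_leak=0.0), CONTROL, proto)
    clean = baseline_correct(clean, proto.step_onset)
    # channels respond (weakly, ~1 pA) to the quarter pulses; the P/4
    # template therefore carries a small nonlinear contamination
    np.testing.assert_allclose(corrected.current, clean.current, atol=1.0)


def test_p4_needs_exactly_four_subsweeps(params):
    proto = StepProtocol(test_voltages=(0.0,), p4_enabled=True)
    fam = simulate_family(proto, params, [CONTROL], seed=None)["control"]
    with pytest.raises(ValidationError, match="4"):
        p4_subtract(fam.select(role="main")[0], fam.select(role="p4_sub")[:3])


def test_baseline_constant_trace_to_zero():
    sw = _sweep(np.full(2000, -5.0))
    out = baseline_correct(sw, step_onset=10.0)
    assert np.all(out.current == 0.0)
    assert out.meta["baseline_offset"] == -5.0


def test_baseline_zero_trace_unchanged():
    sw = _sweep(np.zeros(2000))
    np.testing.assert_array_equal(
        baseline_correct(sw, step_onset=10.0).current, sw.current)


def test_baseline_window_must_precede_sweep_start():
    sw = _sweep(np.zeros(200))  # 2 ms of data
    with pytest.raises(ValidationError):
        baseline_correct(sw, step_onset=1.0, window_ms=5.0)
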