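"""Drug subtraction, peak/persistent measurement, percent inhibition."""

import numpy as np
import pytest

from navclamp.isolation import (peak_amplitude, percent_inhibition,
                                persistent_current, subtract_traces)
from navclamp.model import (CONTROL, TTX, DrugState, GatingModelParams,
                            StepProtocol, ValidationError)
from navclamp.preprocess import baseline_correct, preprocess_family
from navclamp.simulate import simulate_family, simulate_sweep
from navclamp.traces import Sweep


def _sweep(current, v=0.0, dt=0.01):
    return Sweep(time=np.arange(len(current)) * dt,
                 current=np.asarray(current, float), test_voltage=v)


def test_identical_traces_subtract_to_zero(params):
    sw = simulate_sweep(0.0, params)
    assert np.all(subtract_traces(sw, sw).current == 0.0)


def test_full_block_recovers_pool_current(params):
    """control - TTX(1.0) equals the TTX-S pools simulated alone."""
    proto = StepProtocol(p4_enabled=False)
    ctrl = simulate_sweep(0.0, params, CONTROL, proto)
    ttx = simulate_sweep(0.0, params, TTX, proto)
    sens = subtract_traces(ctrl, ttx)
    pools = simulate_sweep(0.0, params.with_(g_ttxr=0, g_leak=0), CONTROL, proto)
    np.testing.assert_allclose(sens.current, pools.current, atol=1e-9)


def test_subtraction_antisymmetric(params):
    a = simulate_sweep(0.0, params, seed=1)
    b = simulate_sweep(0.0, params, seed=2)
    np.testing.assert_array_equal(subtract_traces(a, b).current,
                                  -subtract_traces(b, a).current)


def test_voltage_mismatch_rejected(params):
    a = simulate_sweep(0.0, params)
    b = simulate_sweep(10.0, params)
    with pytest.raises(ValidationError):
        subtract_traces(a, b)


def test_peak_of_double_exponential_matches_analytic_argmax():
    """-A exp(-t/tau_d)(1 - exp(-t/tau_r)) peaks at tau_r log(1+tau_d/tau_r)."""
    tau_d, tau_r, dt = 2.0, 0.5, 0.01
    t = np.arange(0, 30, dt)
    tr = -80.0 * np.exp(-t / tau_d) * (1 - np.exp(-t / tau_r))
    sw = _sweep(tr)
    peak, t_peak = peak_amplitude(sw, step_onset=0.0)
    t_star = tau_r * np.log(1 + tau_d / tau_r)
    assert abs(t_peak - t_star) <= dt
    assert peak < 0


def test_all_zero_trace_flags_no_peak():
    sw = _sweep(np.zeros(3000))
    peak, t_peak = peak_amplitude(sw, step_onset=1.0)
    assert peak == 0.0 and t_peak == pytest.approx(1.0, abs=0.01)
    assert sw.meta.get("no_peak") is True


def test_pure_noise_peak_below_responder_boundary():
    rng = np.random.default_rng(0)
    sw = _sweep(rng.normal(0, 2.0, 3000))
    peak, _ = peak_amplitude(sw, step_onset=1.0)
    assert abs(peak) < 30.0


def test_persistent_fast_only_is_tiny(params):
    """With tau_h ~1 ms everywhere, nothing survives to 10 ms (< 1% of peak)."""
    p = params.with_(g_ttxr=0.0, g_leak=0.0,
                     tau_h_anchors=((-20.0, 1.0), (0.0, 1.0), (50.0, 1.0)))
    proto = StepProtocol(p4_enabled=False)
    sw = baseline_correct(simulate_sweep(0.0, p, CONTROL, proto), proto.step_onset)
    peak, _ = peak_amplitude(sw, proto.step_onset)
    pers = persistent_current(sw, proto.step_onset)
    assert abs(pers) < 0.01 * abs(peak)


def test_persistent_non_inactivating_pool_is_ohmic(params):
    """A fully activated, non-inactivating pool gives g*(V - E_rev) at 10 ms."""
    g_p = 1.5  # nS
    p = params.with_(g_nav17=0, g_ttxs_other=0, g_leak=0, g_ttxr=g_p,
                     ttxr_tau_h_scale=1e6, v_half_m=-60.0,
                     v_half_h=1e3)  # h_inf ~ 1 everywhere
    proto = StepProtocol(p4_enabled=False)
    sw = baseline_correct(simulate_sweep(0.0, p, CONTROL, proto), proto.step_onset)
    pers = persistent_current(sw, proto.step_onset)
    assert pers == pytest.approx(g_p * (0.0 - p.e_rev_sim), rel=0.02)


def test_persistent_beyond_step_rejected(params):
    proto = StepProtocol(step_duration=8.0, sweep_duration=15.0)
    sw = simulate_sweep(0.0, params, protocol=proto)
    sw.meta["step_end"] = proto.step_end
    with pytest.raises(ValidationError):
        persistent_current(sw, proto.step_onset, at=10.0)


def test_percent_inhibition_printed_amplitudes():
    """Total 141 pA reduced to 54 pA by TTX: 61.7% inhibition."""
    assert percent_inhibition(-141.0, -54.0) == pytest.approx(61.7, abs=0.05)


def test_percent_inhibition_edges():
    assert percent_inhibition(-100.0, -100.0) == 0.0
    assert percent_inhibition(-100.0, 0.0) == 100.0
    with pytest.raises(ValidationError):
        percent_inhibition(0.0, -10.0)


@pytest.mark.parametrize("f", [0.2, 0.5, 0.9])
def test_blocking_fraction_maps_to_inhibition(params, f):
    """Blocking fraction f of every channel pool inhibits the peak by 100f%."""
    p = params.with_(g_ttxr=0.0, g_leak=0.0)
    proto = StepProtocol(test_voltages=(0.0,), p4_enabled=False)
    fam_c = simulate_family(proto, p, [CONTROL], seed=None)["control"]
    fam_d = simulate_family(proto, p, [DrugState(f, 0.0, "drug")],
                            seed=None)["drug"]
    c = preprocess_family(fam_c, "control")[0.0]
    d = preprocess_family(fam_d, "drug")[0.0]
    pc, _ = peak_amplitude(c, proto.step_onset)
    pd_, _ = peak_amplitude(d, proto.step_onset)
    assert percent_inhibition(pc, pd_) == pytest.approx(100 * f, abs=0.5)
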