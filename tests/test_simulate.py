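"""Simulator contracts: linearity, determinism, gate bounds, convergence."""

import numpy as np
import pytest

from navclamp.model import (CONTROL, TTX, DrugState, GatingModelParams,
                            StepProtocol, ValidationError)
from navclamp.simulate import _gate_segment, simulate_family, simulate_sweep


@pytest.fixture
def quiet():
    """Noise-free parameter set with no channels and no leak."""
    return GatingModelParams(g_nav17=0, g_ttxs_other=0, g_ttxr=0, g_leak=0,
                             noise_sd=0)


def test_no_conductance_gives_zero_trace(quiet):
    sw = simulate_sweep(0.0, quiet)
    assert np.all(sw.current == 0.0)


def test_step_to_holding_is_constant(params):
    proto = StepProtocol(test_voltages=(-90.0,), holding=-90.0)
    sw = simulate_sweep(-90.0, params, protocol=proto)
    assert np.allclose(sw.current, sw.current[0])


def test_calibrated_peak_time_at_0mV(params):
    """The default cell peaks 1.4 ms after step onset at 0 mV."""
    from navclamp.kinetics import time_to_peak
    from navclamp.preprocess import baseline_correct
    proto = StepProtocol()
    sw = baseline_correct(simulate_sweep(0.0, params, protocol=proto),
                          proto.step_onset)
    assert time_to_peak(sw, proto.step_onset) == pytest.approx(1.4, abs=0.05)


def test_same_master_seed_is_bit_identical(params):
    proto = StepProtocol(test_voltages=(0.0,), n_repeats_per_voltage=2)
    a = simulate_family(proto, params, [CONTROL], seed=7)["control"]
    b = simulate_family(proto, params, [CONTROL], seed=7)["control"]
    for sa, sb in zip(a.sweeps, b.sweeps):
        assert np.array_equal(sa.current, sb.current)
    c = simulate_family(proto, params, [CONTROL], seed=8)["control"]
    assert not np.array_equal(a.sweeps[0].current, c.sweeps[0].current)


def test_family_counts():
    p = GatingModelParams(noise_sd=0)
    proto = StepProtocol(n_repeats_per_voltage=8, p4_enabled=False)
    fam = simulate_family(proto, p, [CONTROL], seed=None)["control"]
    assert len(fam.sweeps) == 12 * 8
    proto4 = StepProtocol(n_repeats_per_voltage=1, p4_enabled=True)
    fam4 = simulate_family(proto4, p, [CONTROL], seed=None)["control"]
    assert len(fam4.select(role="main")) == 12
    assert len(fam4.select(role="p4_sub")) == 48


def test_pharmacological_additivity(params):
    """control - saturating TTX equals the two TTX-S pools simulated alone."""
    proto = StepProtocol(p4_enabled=False)
    ctrl = simulate_sweep(0.0, params, CONTROL, proto)
    ttx = simulate_sweep(0.0, params, TTX, proto)
    pools_only = params.with_(g_ttxr=0.0, g_leak=0.0)
    direct = simulate_sweep(0.0, pools_only, CONTROL, proto)
    np.testing.assert_allclose(ctrl.current - ttx.current, direct.current,
                               atol=1e-9)


def test_partial_block_scales_pools(params):
    proto = StepProtocol(p4_enabled=False)
    half = simulate_sweep(0.0, params.with_(g_ttxr=0, g_leak=0),
                          DrugState(0.5, 0.0, "halfTTX"), proto)
    full = simulate_sweep(0.0, params.with_(g_ttxr=0, g_leak=0), CONTROL, proto)
    np.testing.assert_allclose(half.current, 0.5 * full.current, atol=1e-9)


def test_gate_bounds_random_segments():
    rng = np.random.default_rng(42)
    t = np.linspace(0, 20, 2001)
    for _ in range(200):
        x0, x_inf = rng.uniform(0, 1, 2)
        tau = rng.uniform(0.01, 50)
        lat = rng.uniform(0, 3)
        g = _gate_segment(t, 0.0, x0, x_inf, tau, lat)
        assert np.all(g >= 0.0) and np.all(g <= 1.0)


def test_gates_bounded_on_simulated_sweep(params):
    """Current never exceeds the all-gates-open bound at any voltage."""
    for v in (-60.0, -20.0, 0.0, 50.0):
        sw = simulate_sweep(v, params.with_(g_leak=0))
        g_tot = params.g_nav17 + params.g_ttxs_other + params.g_ttxr
        bound = g_tot * max(abs(v - params.e_rev_sim),
                            abs(params.e_rev_sim - (-90.0))) + 1e-9
        assert np.all(np.abs(sw.current) <= bound)


def test_grid_convergence(params):
    """Doubling the sample rate moves the sampled peak by < 0.1%."""
    fine = params.with_(sample_rate=200_000.0)
    for v in (-20.0, 0.0, 50.0):
        a = simulate_sweep(v, params)
        b = simulate_sweep(v, fine)
        pa = np.abs(a.current).max()
        pb = np.abs(b.current).max()
        assert abs(pa - pb) / pb < 1e-3


def test_invalid_inputs():
    with pytest.raises(ValidationError):
        GatingModelParams(k_m=-1)
    with pytest.raises(ValidationError):
        GatingModelParams(tau_h_anchors=((0.0, -1.0),))
    with pytest.raises(ValidationError):
        GatingModelParams(sample_rate=3000.0, filter_cutoff=2000.0)
    with pytest.raises(ValidationError):
        DrugState(ttx_block_fraction=1.5)
    with pytest.raises(ValidationError):
        StepProtocol(test_voltages=(0.0, -10.0))
    with pytest.raises(Exception):
        simulate_sweep(float("nan"), GatingModelParams())
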