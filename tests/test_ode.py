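"""Deterministic simulation: trajectories, steady states, dose-response
metrics, strength sweeps, hysteresis and de-induction."""

import numpy as np
import pytest

from digisim.model import analytic_steady_state_unpaired
from digisim.ode import (
    DegenerateCurveError,
    DoseResponseCurve,
    deinduction,
    dose_response,
    hysteresis_scan,
    repression_sweep,
    response_metrics,
    simulate_ode,
    steady_state,
)
from digisim.params import (
    InducerProtocol,
    ModelParams,
    SystemState,
    bistable_example_params,
)

from conftest import random_params


def test_simulate_ode_all_rates_zero_stays_zero():
    p = ModelParams(alpha_R=0.0, beta_R=0.0, alpha_S=0.0)
    tc = simulate_ode(p, InducerProtocol.constant(100.0), np.linspace(1, 100, 25))
    assert np.all(tc.states == 0.0)


def test_simulate_ode_reaches_unpaired_steady_state(unpaired):
    """Long integration with k_pair=0 lands on the closed form."""
    tf = 80.0
    tc = simulate_ode(unpaired, InducerProtocol.constant(tf), np.array([3000.0]))
    expected = analytic_steady_state_unpaired(unpaired, tf).vector()
    np.testing.assert_allclose(tc.states[-1], expected, rtol=1e-6)


def test_simulate_ode_monotone_rise_to_plateau(baseline):
    """Step induction: G rises monotonically until within 1% of its plateau."""
    grid = np.linspace(1.0, 2000.0, 400)
    tc = simulate_ode(baseline, InducerProtocol.constant(500.0), grid)
    G = tc.species("G")
    plateau = G[-1]
    rising = G < 0.99 * plateau
    assert np.all(np.diff(G[rising]) > 0)


def test_simulate_ode_applies_protocol_segments(baseline):
    """After inducer removal the mRNA falls back toward its basal level."""
    proto = InducerProtocol.step_off(500.0, 100.0)
    grid = np.array([50.0, 99.0, 160.0, 400.0])
    tc = simulate_ode(baseline, proto, grid)
    mR = tc.species("mR")
    assert mR[1] > 10.0  # fully induced just before removal
    assert mR[-1] < 0.1  # collapsed after removal


def test_steady_state_matches_closed_form(unpaired):
    for tf in (0.0, 20.0, 300.0):
        ss = steady_state(unpaired, tf)
        np.testing.assert_allclose(
            ss.vector(),
            analytic_steady_state_unpaired(unpaired, tf).vector(),
            rtol=1e-8, atol=1e-12,
        )


def test_steady_state_fully_off_fixed_point():
    p = ModelParams(beta_R=0.0)
    ss = steady_state(p, 0.0)
    assert ss.mR == ss.R == ss.G == pytest.approx(0.0, abs=1e-9)
    assert ss.mS == pytest.approx(p.alpha_S / p.delta_mS, rel=1e-9)


def test_steady_state_idempotent(baseline):
    s1 = steady_state(baseline, 60.0)
    s2 = steady_state(baseline, 60.0, init=s1)
    np.testing.assert_allclose(s1.vector(), s2.vector(), rtol=1e-9, atol=1e-9)


def test_steady_state_requires_positive_decay():
    with pytest.raises(Exception):
        steady_state(ModelParams(delta_G=0.0, mu=0.0), 10.0)


def test_dose_response_single_dose_consistency(baseline):
    d = np.array([50.0])
    curve = dose_response(baseline, d)
    direct = steady_state(baseline, 50.0)
    np.testing.assert_allclose(
        curve.steady[0].vector(), direct.vector(), rtol=1e-8
    )


def test_dose_response_unpaired_matches_closed_form_everywhere(sweep_doses):
    p = ModelParams(alpha_S=0.0, k_pair=0.0)
    curve = dose_response(p, sweep_doses)
    for d, st in zip(curve.doses, curve.steady):
        np.testing.assert_allclose(
            st.vector(),
            analytic_steady_state_unpaired(p, d).vector(),
            rtol=1e-6, atol=1e-10,
        )


def test_dose_response_monotone_at_baseline(baseline, sweep_doses):
    curve = dose_response(baseline, sweep_doses)
    mr = curve.readout("mR")
    assert np.all(np.diff(mr) > -1e-9 * mr.max())


def test_response_metrics_recovers_ideal_hill():
    doses = np.concatenate([[0.0], np.logspace(-1, 3, 300)])
    off, on, ec50, h = 1.0, 100.0, 10.0, 4.0
    a = (doses / ec50) ** h
    y = off + (on - off) * a / (1 + a)
    states = [SystemState(tf_a=d, mR=v) for d, v in zip(doses, y)]
    curve = DoseResponseCurve(doses, states, np.ones(doses.size, bool))
    m = response_metrics(curve)
    assert m.ec50 == pytest.approx(ec50, rel=0.01)
    assert m.effective_hill == pytest.approx(h, rel=0.01)
    assert m.off_level == pytest.approx(off)
    assert m.fold_change == pytest.approx(on / off, rel=1e-6)


def test_response_metrics_degenerate_curve_raises():
    doses = np.array([0.0, 1.0, 2.0])
    states = [SystemState(mR=5.0) for _ in doses]
    curve = DoseResponseCurve(doses, states, np.ones(3, bool))
    with pytest.raises(DegenerateCurveError):
        response_metrics(curve)


def test_response_metrics_step_curve_width_below_spacing():
    doses = np.linspace(0.0, 10.0, 11)
    y = np.where(doses < 5.0, 0.0, 1.0)
    states = [SystemState(tf_a=d, mR=v) for d, v in zip(doses, y)]
    curve = DoseResponseCurve(doses, states, np.ones(doses.size, bool))
    m = response_metrics(curve)
    assert m.transition_width <= 1.0 + 1e-12


def test_repression_sweep_strength_one_reduces_to_dose_response(baseline):
    doses = np.concatenate([[0.0], np.logspace(-1, 3, 15)])
    sw = repression_sweep(baseline, np.array([1.0]), doses)
    ref = dose_response(baseline, doses)
    np.testing.assert_allclose(
        sw.curves[0].readout("mR"), ref.readout("mR"), rtol=1e-8
    )
    assert sw.phase_pairs.shape == (1, doses.size, 2)


def test_repression_sweep_weak_limit_approaches_unpaired(baseline):
    doses = np.concatenate([[0.0], np.logspace(0, 3, 8)])
    sw = repression_sweep(baseline, np.array([1e-4]), doses)
    for d, st in zip(doses, sw.curves[0].steady):
        ref = analytic_steady_state_unpaired(baseline.replace(k_pair=0.0), d)
        np.testing.assert_allclose(st.mR, ref.mR, rtol=0.02)


def test_repression_sweep_off_level_strictly_decreasing(baseline):
    doses = np.concatenate([[0.0], np.logspace(-1, 3, 15)])
    sw = repression_sweep(baseline, np.array([0.3, 1.0, 3.0, 10.0, 30.0]), doses)
    offs = [m.off_level for m in sw.metrics]
    assert all(a > b for a, b in zip(offs, offs[1:]))


def test_hysteresis_absent_without_pairing(sweep_doses, unpaired):
    res = hysteresis_scan(unpaired, sweep_doses)
    assert not res["bistable"]
    assert res["max_branch_gap"] <= 1e-6 * res["dynamic_range"]


def test_hysteresis_detected_for_bistable_example(sweep_doses):
    res = hysteresis_scan(bistable_example_params(), sweep_doses)
    assert res["bistable"]
    assert res["max_branch_gap"] > 1.0  # branches macroscopically separated


def test_deinduction_decay_and_equivalence(baseline):
    tcs = deinduction(baseline, t_on=160.0, t_total=400.0, tf_high=1000.0)
    t = tcs["digitalized"].times
    post = t >= 160.0
    # monotone decay once the residual mRNA is gone (a few mRNA lifetimes)
    post_decay = t >= 160.0 + 15.0
    i_on = int(np.argmin(np.abs(t - 160.0)))
    norm = {}
    for label, tc in tcs.items():
        G = tc.species("G")
        assert np.all(np.diff(G[post_decay]) <= 1e-9 * G.max())
        norm[label] = G[post] / G[i_on]
        # log-slope approaches delta_G in the window where decay dominates
        win = (t >= 180.0) & (t <= 250.0)
        rate = -np.polyfit(t[win], np.log(G[win]), 1)[0]
        assert rate == pytest.approx(baseline.delta_G, rel=0.05)
    gap = np.max(np.abs(norm["digitalized"] - norm["non_digitalized"]))
    assert gap <= 0.02  # constructs de-induce indistinguishably


def test_deinduction_without_loss_terms_is_nondecreasing():
    p = ModelParams(delta_G=0.0, mu=0.0).replace(delta_mR=0.2)
    # keep other decays positive; G has no loss term at all
    tcs = deinduction(p, t_on=50.0, t_total=200.0, tf_high=500.0)
    for tc in tcs.values():
        G = tc.species("G")
        assert np.all(np.diff(G) >= -1e-9 * max(G.max(), 1.0))


def test_deinduction_requires_valid_window(baseline):
    with pytest.raises(ValueError):
        deinduction(baseline, t_on=100.0, t_total=100.0)
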