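"""Stochastic simulator: reaction construction, exactness checks against
analytic stationary laws and the deterministic limit, and one-hit killing."""

import numpy as np
import pytest

from digisim.ode import simulate_ode
from digisim.params import InducerProtocol, ModelParams, SystemState, baseline_params
from digisim.ssa import (
    StochasticConfig,
    build_reactions,
    gillespie,
    one_hit_survival,
    simulate_population,
)


@pytest.fixture(scope="module")
def baseline():
    return baseline_params()


def test_build_reactions_channel_count_and_stoichiometry(baseline):
    reactions, _ = build_reactions(baseline, omega=10.0)
    assert len(reactions) == 9
    pairing = next(r for r in reactions if r.name == "pairing_codegradation")
    np.testing.assert_array_equal(pairing.stoichiometry, [-1, -1, 0, 0])
    with_mu, _ = build_reactions(baseline.replace(mu=0.01), omega=10.0)
    assert len(with_mu) == 13


def test_build_reactions_zero_rates_zero_propensity():
    p = ModelParams(alpha_R=0, beta_R=0, alpha_S=0, k_pair=0, delta_mR=0,
                    delta_mS=0, delta_R=0, delta_G=0, lambda_R=0, lambda_G=0)
    _, prop = build_reactions(p, omega=5.0)
    assert np.all(prop(np.array([7, 3, 10, 2]), tf_a=100.0) == 0.0)


def test_build_reactions_deterministic_limit(baseline):
    """propensity/omega at counts omega*x equals the ODE flux at x."""
    from digisim.model import hill_activation, hill_repression

    omega = 1000.0
    _, prop = build_reactions(baseline, omega)
    x = np.array([3.0, 1.5, 40.0, 20.0])  # nM
    tf = 70.0
    a = prop(x * omega, tf) / omega
    p = baseline
    expected = np.array([
        p.beta_R + p.alpha_R * hill_activation(tf, p.K_TF, p.n_act),
        p.alpha_S * hill_repression(x[2], p.K_R, p.n_rep),
        p.delta_mR * x[0], p.delta_mS * x[1], p.k_pair * x[0] * x[1],
        p.lambda_R * x[0], p.lambda_G * x[0],
        p.delta_R * x[2], p.delta_G * x[3],
    ])
    np.testing.assert_allclose(a, expected, rtol=1e-12)


def test_gillespie_zero_propensity_state_constant():
    p = ModelParams(alpha_R=0, beta_R=0, alpha_S=0, k_pair=0, delta_mR=0,
                    delta_mS=0, delta_R=0, delta_G=0, lambda_R=0, lambda_G=0)
    cfg = StochasticConfig(omega=1.0, n_cells=1, seed=1, t_max=100.0,
                           snapshot_times=(0.0, 50.0, 100.0))
    init = SystemState(mR=4, mS=2, R=9, G=1)
    rec, died, _ = gillespie(p, cfg, InducerProtocol.constant(50.0), 0, init=init)
    assert not died
    for row in rec:
        np.testing.assert_array_equal(row, [4, 2, 9, 1])


def test_gillespie_reproducible_per_cell_stream(baseline):
    cfg = StochasticConfig(omega=1.0, n_cells=2, seed=123, t_max=40.0,
                           snapshot_times=(10.0, 40.0))
    proto = InducerProtocol.constant(80.0)
    a1, _, _ = gillespie(baseline, cfg, proto, cell_index=5)
    a2, _, _ = gillespie(baseline, cfg, proto, cell_index=5)
    np.testing.assert_array_equal(a1, a2)
    b, _, _ = gillespie(baseline, cfg, proto, cell_index=6)
    assert not np.array_equal(a1, b)


def test_gillespie_birth_death_matches_poisson_law():
    """Frozen birth-death of G: stationary mean and variance both a/d."""
    p = ModelParams(alpha_R=0, beta_R=0, alpha_S=0, k_pair=0, delta_mR=0,
                    delta_mS=0, delta_R=0, lambda_R=0, lambda_G=1.0,
                    delta_G=0.5)
    lam = 1.0 * 10 / 0.5  # birth a = lambda_G * mR, death d = delta_G
    cfg = StochasticConfig(omega=1.0, n_cells=2000, seed=7, t_max=60.0,
                           snapshot_times=(60.0,))
    snaps = simulate_population(p, cfg, InducerProtocol.constant(0.0),
                                init=SystemState(mR=10.0))
    G = snaps[0].species("G").astype(float)
    n = G.size
    se_mean = np.sqrt(lam / n)
    se_var = lam * np.sqrt(2.0 / (n - 1))  # approx SE of a Poisson variance
    assert abs(G.mean() - lam) < 3 * se_mean
    assert abs(G.var(ddof=1) - lam) < 3 * se_var


def test_population_single_cell_equals_gillespie(baseline):
    cfg = StochasticConfig(omega=1.0, n_cells=1, seed=3, t_max=30.0,
                           snapshot_times=(0.0, 15.0, 30.0))
    proto = InducerProtocol.constant(100.0)
    snaps = simulate_population(baseline, cfg, proto)
    rec, _, _ = gillespie(baseline, cfg, proto, cell_index=0)
    for j, snap in enumerate(snaps):
        np.testing.assert_array_equal(snap.counts[0], rec[j])


def test_population_mean_tracks_ode_at_large_omega(baseline):
    """omega=1000: population mean G within 3 SE of the ODE trajectory."""
    times = (5.0, 20.0, 60.0)
    cfg = StochasticConfig(omega=1000.0, n_cells=20, seed=11, t_max=60.0,
                           snapshot_times=times)
    snaps = simulate_population(baseline, cfg, InducerProtocol.constant(100.0))
    tc = simulate_ode(baseline, InducerProtocol.constant(100.0),
                      np.array(times))
    for snap, ode_G in zip(snaps, tc.species("G")):
        G = snap.species("G") / cfg.omega
        se = G.std(ddof=1) / np.sqrt(G.size)
        assert abs(G.mean() - ode_G) < 3 * se
        assert G.std(ddof=1) > 0  # non-degenerate noise


def test_deterministic_limit_improves_with_omega(baseline):
    """Max relative deviation of the population mean from the ODE shrinks
    as the system size grows."""
    times = (4.0, 10.0)
    tc = simulate_ode(baseline, InducerProtocol.constant(100.0), np.array(times))
    ode_G = tc.species("G")
    devs = []
    for omega in (100.0, 1000.0, 10000.0):
        cfg = StochasticConfig(omega=omega, n_cells=12, seed=21, t_max=10.0,
                               snapshot_times=times)
        snaps = simulate_population(baseline, cfg, InducerProtocol.constant(100.0))
        dev = max(
            abs(s.species("G").mean() / omega - g) / g
            for s, g in zip(snaps, ode_G)
        )
        devs.append(dev)
    assert devs[0] > devs[1] > devs[2]


def test_one_hit_survival_limits_and_monotonicity(baseline):
    ptox = baseline.replace(lambda_G=0.005)
    cfg = StochasticConfig(omega=1.0, n_cells=200, seed=5, t_max=120.0,
                           snapshot_times=(120.0,))
    doses = np.array([0.0, 20.0, 50.0, 80.0, 200.0, 1000.0])
    # nothing transcribed -> everyone lives
    off = ptox.replace(alpha_R=0.0, beta_R=0.0)
    np.testing.assert_array_equal(one_hit_survival(off, cfg, doses), 1.0)
    surv = one_hit_survival(ptox, cfg, doses)
    assert surv[-1] == 0.0  # saturating induction kills everyone
    assert np.all(np.diff(surv) <= 0.0)
    # an independent seed reproduces the ordering (sampling-error guard)
    cfg2 = StochasticConfig(omega=1.0, n_cells=200, seed=77, t_max=120.0,
                            snapshot_times=(120.0,))
    surv2 = one_hit_survival(ptox, cfg2, doses)
    assert np.all(np.diff(surv2) <= 0.0)
    np.testing.assert_allclose(surv, surv2, atol=0.1)


def test_one_hit_survival_digital_vs_graded(baseline):
    """The digitalized toxin circuit drops sharply near its threshold dose;
    the sRNA-free construct declines gradually from dose zero (relative
    10-90% width of the survival curve is much larger)."""
    ptox = baseline.replace(lambda_G=0.005)
    cfg = StochasticConfig(omega=1.0, n_cells=300, seed=9, t_max=120.0,
                           snapshot_times=(120.0,))
    doses = np.concatenate([[0.0], np.logspace(0, 3, 10)])

    def rel_width(s):
        hi, lo = s[0], s[-1]
        rng = hi - lo
        d90 = np.interp(-(lo + 0.9 * rng), -s, doses)
        d10 = np.interp(-(lo + 0.1 * rng), -s, doses)
        d50 = np.interp(-(lo + 0.5 * rng), -s, doses)
        return (d10 - d90) / d50

    w_dig = rel_width(one_hit_survival(ptox, cfg, doses))
    w_nd = rel_width(one_hit_survival(ptox.replace(alpha_S=0.0), cfg, doses))
    assert w_dig < w_nd


def test_one_hit_threshold_validation(baseline):
    cfg = StochasticConfig(n_cells=1, t_max=1.0, snapshot_times=(1.0,))
    with pytest.raises(ValueError):
        one_hit_survival(baseline, cfg, np.array([0.0]), threshold=0)


def test_stochastic_config_validation():
    with pytest.raises(ValueError):
        StochasticConfig(omega=0.0)
    with pytest.raises(ValueError):
        StochasticConfig(n_cells=0)
    with pytest.raises(ValueError):
        StochasticConfig(t_max=10.0, snapshot_times=(0.0, 20.0))
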