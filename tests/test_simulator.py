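import numpy as np
import pytest

from sabnet.effects import EffectSpec, ModelEngine, ModelSpec, center_model
from sabnet.sab_simulator import (SimState, choice_probabilities_behavior,
                                  choice_probabilities_network, micro_step,
                                  simulate_period)

from conftest import make_panel, random_setup


def simple_engine(n, net_beta=None, beh_effects=None, rng=None,
                  rates=None, adj=None, z=None):
    rng = rng or np.random.default_rng(0)
    if adj is None:
        adj = (rng.random((n, n)) < 0.2).astype(float)
        np.fill_diagonal(adj, 0)
    if z is None:
        z = rng.integers(0, 4, n).astype(float)
    effects = []
    if net_beta is not None:
        effects.append(EffectSpec("out-degree", "network", beta=net_beta))
    effects.extend(beh_effects or [
        EffectSpec("linear shape", "behavior:smoking", beta=0.0),
        EffectSpec("quadratic shape", "behavior:smoking", beta=0.0)])
    model = ModelSpec(
        effects=effects,
        rates=rates or {"network": [1.0], "behavior:smoking": [1.0]},
        behavior_ranges={"smoking": (0, 3)}, n_periods=1)
    panel = make_panel(adj[None].astype(np.int8),
                       {"smoking": z[None].astype(int)})
    model = center_model(model, panel)
    engine = ModelEngine(model, panel.covariates,
                         np.zeros((1, n), dtype=np.int8))
    state = SimState(adj=adj.copy(), z={"smoking": z.copy()},
                     active=np.ones(n, dtype=bool))
    return engine, state


def test_network_choice_uniform_when_betas_zero():
    engine, state = simple_engine(5, net_beta=0.0)
    p, _ = choice_probabilities_network(0, state, engine)
    assert np.allclose(p[p > 0], 1 / 5)  # keep + 4 toggles
    assert p.sum() == pytest.approx(1.0)


def test_network_choice_density_closed_form():
    # empty 3-actor network, only an out-degree effect beta = -2:
    # p(keep) : p(add tie to j) = 1 : exp(-2) for each of the 2 candidates
    engine, state = simple_engine(3, net_beta=-2.0,
                                  adj=np.zeros((3, 3)),
                                  z=np.zeros(3))
    p, _ = choice_probabilities_network(0, state, engine)
    denom = 1 + 2 * np.exp(-2.0)
    assert p[0] == pytest.approx(1 / denom)
    assert p[2] == pytest.approx(np.exp(-2.0) / denom)


def test_network_choice_excludes_inactive_targets():
    engine, state = simple_engine(5, net_beta=0.0)
    state.active[3] = False
    p, _ = choice_probabilities_network(0, state, engine)
    assert p[1 + 3] == 0.0
    assert p.sum() == pytest.approx(1.0)


def test_behavior_choice_uniform_interior():
    engine, state = simple_engine(4)
    state.z["smoking"][:] = 2.0  # interior of 0-3
    p, _ = choice_probabilities_behavior(0, "smoking", state, engine)
    assert np.allclose(p, 1 / 3)


def test_behavior_choice_boundary_moves_blocked():
    engine, state = simple_engine(4)
    state.z["smoking"][0] = 0.0
    p, _ = choice_probabilities_behavior(0, "smoking", state, engine)
    assert p[0] == 0.0
    state.z["smoking"][1] = 3.0
    p, _ = choice_probabilities_behavior(1, "smoking", state, engine)
    assert p[2] == 0.0


def test_linear_shape_odds_independent_of_level():
    # a single linear-shape effect beta=1: odds(+1 vs stay) = e at any
    # interior level (centering cancels in differences)
    engine, state = simple_engine(
        4, beh_effects=[
            EffectSpec("linear shape", "behavior:smoking", beta=1.0),
            EffectSpec("quadratic shape", "behavior:smoking", beta=0.0)],
        rates={"behavior:smoking": [1.0]})
    for level in (1.0, 2.0):
        state.z["smoking"][0] = level
        p, _ = choice_probabilities_behavior(0, "smoking", state, engine)
        assert p[2] / p[1] == pytest.approx(np.e)


def test_choice_probabilities_match_brute_force_normalization():
    rng = np.random.default_rng(5)
    engine, state = random_setup(5, rng)
    from sabnet.effects import objective
    for i in range(5):
        p, _ = choice_probabilities_network(i, state, engine)
        base = objective(i, "network", state, engine)
        weights = [1.0]
        for j in range(5):
            if j == i:
                continue
            alt = state.copy()
            alt.adj[i, j] = 1 - alt.adj[i, j]
            alt.outdeg = alt.adj.sum(axis=1)
            alt.indeg = alt.adj.sum(axis=0)
            weights.append(np.exp(objective(i, "network", alt, engine) - base))
        weights = np.array(weights)
        expect = weights / weights.sum()
        got = np.concatenate(([p[0]], p[1:][np.arange(5) != i]))
        assert np.allclose(got, expect)


def test_network_only_rates_leave_behaviors_fixed():
    engine, state = simple_engine(6, net_beta=-1.0,
                                  rates={"network": [3.0]})
    end, _ = simulate_period(state, engine, 0, np.random.default_rng(1))
    assert np.array_equal(end.z["smoking"], state.z["smoking"])


def test_opportunity_rate_matches_exponential_clock():
    lam = 2.0
    engine, state = simple_engine(10, net_beta=0.0,
                                  rates={"network": [lam],
                                         "behavior:smoking": [1.0]})
    rng = np.random.default_rng(8)
    reps = 300
    counts = np.zeros(reps)
    for r in range(reps):
        _, rec = simulate_period(state, engine, 0, rng)
        counts[r] = rec.event_counts.get("network", 0)
    per_actor = counts / 10
    mc_se = per_actor.std(ddof=1) / np.sqrt(reps)
    assert abs(per_actor.mean() - lam) < 3 * mc_se + 1e-9


def test_simulation_is_bit_reproducible():
    engine, state = simple_engine(8, net_beta=-0.5)
    end1, _ = simulate_period(state, engine, 0, np.random.default_rng(42))
    end2, _ = simulate_period(state, engine, 0, np.random.default_rng(42))
    assert np.array_equal(end1.adj, end2.adj)
    assert np.array_equal(end1.z["smoking"], end2.z["smoking"])


def test_vanishing_rates_leave_state_unchanged():
    engine, state = simple_engine(6, net_beta=-1.0,
                                  rates={"network": [1e-9],
                                         "behavior:smoking": [1e-9]})
    end, rec = simulate_period(state, engine, 0, np.random.default_rng(3))
    assert np.array_equal(end.adj, state.adj)
    assert np.array_equal(end.z["smoking"], state.z["smoking"])
    assert rec.n_steps == 0


def test_behaviors_stay_in_range_under_heavy_churn():
    engine, state = simple_engine(
        6, beh_effects=[
            EffectSpec("linear shape", "behavior:smoking", beta=1.5),
            EffectSpec("quadratic shape", "behavior:smoking", beta=0.5)],
        rates={"behavior:smoking": [30.0]})
    rng = np.random.default_rng(4)
    for _ in range(30):
        end, _ = simulate_period(state, engine, 0, rng)
        assert end.z["smoking"].min() >= 0 and end.z["smoking"].max() <= 3


def test_zero_beta_density_drifts_to_half():
    # with no preferences the tie process is symmetric: long-run density 1/2
    n = 6
    engine, state = simple_engine(n, net_beta=0.0,
                                  adj=np.zeros((n, n)),
                                  z=np.zeros(n),
                                  rates={"network": [120.0]})
    rng = np.random.default_rng(9)
    dens = []
    for _ in range(40):
        end, _ = simulate_period(state, engine, 0, rng)
        dens.append(end.adj.sum() / (n * (n - 1)))
    assert abs(np.mean(dens) - 0.5) < 0.05


def test_tie_change_grows_with_rate():
    rng = np.random.default_rng(10)
    means = []
    for lam in (0.5, 2.0, 8.0):
        engine, state = simple_engine(8, net_beta=-0.5,
                                      rates={"network": [lam]})
        dists = []
        for _ in range(40):
            end, _ = simulate_period(state, engine, 0, rng)
            dists.append(np.abs(end.adj - state.adj).sum())
        means.append(np.mean(dists))
    assert means[0] < means[1] < means[2]


def test_micro_step_requires_active_actors():
    from sabnet.sab_simulator import NoActiveActorsError
    engine, state = simple_engine(4, net_beta=0.0)
    state.active[:] = False
    with pytest.raises(NoActiveActorsError):
        micro_step(state, engine, {"network": 1.0}, np.random.default_rng(0))


def test_structural_zero_schedule_respected_in_forward_run():
    from sabnet.sab_simulator import simulate_forward
    from sabnet.synthetic_data import PanelConfig, generate_panel, \
        recovery_model
    panel, truth = generate_panel(recovery_model(), PanelConfig(n_actors=30),
                                  rng=6)
    engine = ModelEngine(truth["model"], panel.covariates,
                         panel.limited_nomination)
    states = simulate_forward(panel, engine, np.random.default_rng(2))
    graduated = panel.structural_zero[2]
    final = states[-1]
    assert not final.adj[graduated, :].any()
    assert not final.adj[:, graduated].any()
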