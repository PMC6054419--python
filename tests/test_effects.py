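import numpy as np
import pytest

from sabnet.effects import (EffectSpec, ModelSpecError, UnknownEffectError,
                            behavior_statistic, network_statistic, objective,
                            similarity)
from sabnet.sab_simulator import choice_probabilities_behavior

from conftest import full_roster_model, random_setup
from oracles import brute_behavior_stat, brute_network_stat

NETWORK_PLAIN = ["out-degree", "reciprocity", "transitive triplets",
                 "3-cycles", "out-degree popularity", "in-degree popularity",
                 "out-out sqrt assortativity", "in-in sqrt assortativity"]


def test_similarity_kernel():
    assert similarity(2, 2, 3) == 1.0
    assert similarity(2, 0, 3) == pytest.approx(1 / 3)
    assert similarity(0, 3, 3) == 0.0
    with pytest.raises(ValueError):
        similarity(0, 1, 0)


def test_effect_spec_guards():
    with pytest.raises(UnknownEffectError):
        EffectSpec("degree", "network")
    with pytest.raises(ModelSpecError):
        EffectSpec("reciprocity", "network", phase="creation")
    with pytest.raises(ModelSpecError):
        EffectSpec("covariate similarity", "network")  # needs attribute_ref


def test_network_statistics_match_brute_force():
    rng = np.random.default_rng(11)
    for trial in range(6):
        n = int(rng.integers(4, 8))
        engine, state = random_setup(n, rng)
        model = engine.model
        grade = engine._cov["grade"]
        for i in range(n):
            for name in NETWORK_PLAIN:
                got = network_statistic(name, engine, state, i)
                want = brute_network_stat(name, state.adj, i)
                assert got == pytest.approx(want), (name, i)
            got = network_statistic("covariate similarity", engine, state, i,
                                    attribute_ref="grade")
            want = brute_network_stat(
                "covariate similarity", state.adj, i, values=grade,
                value_range=model.covariate_ranges["grade"],
                sim_mean=model.similarity_means["grade"])
            assert got == pytest.approx(want)
            got = network_statistic("behavior similarity", engine, state, i,
                                    attribute_ref="smoking")
            want = brute_network_stat(
                "behavior similarity", state.adj, i,
                values=state.z["smoking"], value_range=3.0,
                sim_mean=model.similarity_means["smoking"])
            assert got == pytest.approx(want)
            got = network_statistic("limited nomination ego", engine, state, i)
            want = brute_network_stat(
                "limited nomination ego", state.adj, i,
                limited=engine.limited_nomination[state.period])
            assert got == pytest.approx(want)


def test_behavior_statistics_match_brute_force():
    rng = np.random.default_rng(13)
    for trial in range(6):
        n = int(rng.integers(4, 8))
        engine, state = random_setup(n, rng)
        model = engine.model
        z = state.z["smoking"]
        other = state.z["marijuana"]
        kw = dict(z_mean=model.behavior_means["smoking"], value_range=3.0,
                  sim_mean=model.similarity_means["smoking"],
                  cov=engine._cov["depressive_symptoms"],
                  cov_mean=model.covariate_means["depressive_symptoms"],
                  other=other, other_mean=model.behavior_means["marijuana"])
        for i in range(n):
            for name in ["linear shape", "quadratic shape", "in-degree",
                         "peer influence", "covariate main", "other behavior",
                         "friends using other substance"]:
                got = behavior_statistic(name, "smoking", engine, state, i)
                want = brute_behavior_stat(name, state.adj, z, i, **kw)
                assert got == pytest.approx(want), (name, i)


def test_isolate_has_zero_peer_influence():
    rng = np.random.default_rng(3)
    engine, state = random_setup(5, rng)
    state.adj[2, :] = 0.0
    state.outdeg[2] = 0.0
    assert behavior_statistic("peer influence", "smoking", engine, state,
                              2) == 0.0


def test_network_deltas_match_full_recompute():
    """Incremental toggle deltas equal recompute-after-toggle differences."""
    rng = np.random.default_rng(17)
    for trial in range(5):
        n = int(rng.integers(4, 8))
        engine, state = random_setup(n, rng)
        for i in range(n):
            deltas = engine.network_delta_matrix(state, i)
            for j in range(n):
                if j == i:
                    continue
                flipped = state.copy()
                flipped.adj[i, j] = 1.0 - flipped.adj[i, j]
                flipped.outdeg = flipped.adj.sum(axis=1)
                flipped.indeg = flipped.adj.sum(axis=0)
                for k in range(len(engine.net_effects)):
                    want = (engine.network_actor_statistic(k, flipped, i)
                            - engine.network_actor_statistic(k, state, i))
                    assert deltas[k, j] == pytest.approx(want, abs=1e-9), (
                        engine.net_effects[k].name, i, j)


def test_behavior_deltas_match_full_recompute():
    rng = np.random.default_rng(19)
    for trial in range(5):
        n = int(rng.integers(4, 8))
        engine, state = random_setup(n, rng)
        for i in range(n):
            deltas = engine.behavior_delta_matrix(state, i, "smoking")
            for col, dz in ((0, -1.0), (1, +1.0)):
                moved = state.copy()
                moved.z["smoking"][i] += dz
                for k in range(len(engine.beh_effects["smoking"])):
                    want = (engine.behavior_actor_statistic(
                                "smoking", k, moved, i)
                            - engine.behavior_actor_statistic(
                                "smoking", k, state, i))
                    assert deltas[k, col] == pytest.approx(want, abs=1e-9), (
                        engine.beh_effects["smoking"][k].name, i, dz)


def test_network_totals_equal_sum_of_actor_statistics():
    rng = np.random.default_rng(23)
    engine, state = random_setup(7, rng)
    totals = engine.network_totals(state)
    for k in range(len(engine.net_effects)):
        want = sum(engine.network_actor_statistic(k, state, i)
                   for i in range(7) if state.active[i])
        assert totals[k] == pytest.approx(want)
    beh_totals = engine.behavior_totals(state, "smoking")
    for k in range(len(engine.beh_effects["smoking"])):
        want = sum(engine.behavior_actor_statistic("smoking", k, state, i)
                   for i in range(7) if state.active[i])
        assert beh_totals[k] == pytest.approx(want)


def test_objective_is_linear_in_beta():
    rng = np.random.default_rng(29)
    engine, state = random_setup(6, rng)
    model = engine.model
    b1 = rng.normal(size=len(model.effects))
    b2 = rng.normal(size=len(model.effects))
    def value(betas, dependent):
        model.set_betas(betas)
        engine.sync_betas()
        return objective(1, dependent, state, engine)
    for dep in ("network", "behavior:smoking"):
        v1 = value(b1, dep)
        v2 = value(b2, dep)
        v12 = value(b1 + b2, dep)
        assert v12 == pytest.approx(v1 + v2)


def test_all_zero_betas_give_zero_objective():
    rng = np.random.default_rng(31)
    engine, state = random_setup(5, rng)
    engine.model.set_betas(np.zeros(len(engine.model.effects)))
    engine.sync_betas()
    assert objective(0, "network", state, engine) == 0.0


def test_creation_endowment_gating_consistency():
    """Equal creation and endowment coefficients reproduce the evaluation
    model's choice probabilities exactly."""
    rng = np.random.default_rng(37)
    from conftest import make_panel
    from sabnet.effects import ModelEngine, ModelSpec, center_model

    n = 6
    adj = (rng.random((n, n)) < 0.3).astype(float)
    np.fill_diagonal(adj, 0)
    z = {"smoking": rng.integers(0, 4, n).astype(float),
         "marijuana": rng.integers(0, 3, n).astype(float)}

    def build(phases):
        effects = [EffectSpec("linear shape", "behavior:smoking", beta=-0.5),
                   EffectSpec("quadratic shape", "behavior:smoking", beta=0.3)]
        for phase, beta in phases:
            effects.append(EffectSpec(
                "other behavior", "behavior:smoking",
                attribute_ref="marijuana", phase=phase, beta=beta))
        model = ModelSpec(
            effects=effects, rates={"behavior:smoking": [1.0]},
            behavior_ranges={"smoking": (0, 3), "marijuana": (0, 2)},
            n_periods=1)
        panel = make_panel(adj[None].astype(np.int8),
                           {s: v[None].astype(int) for s, v in z.items()})
        model = center_model(model, panel)
        return ModelEngine(model, panel.covariates,
                           np.zeros((1, n), dtype=np.int8))

    eval_engine = build([("evaluation", 0.7)])
    split_engine = build([("creation", 0.7), ("endowment", 0.7)])
    from sabnet.sab_simulator import SimState
    state = SimState(adj=adj.copy(), z={s: v.copy() for s, v in z.items()},
                     active=np.ones(n, dtype=bool))
    for i in range(n):
        p_eval, _ = choice_probabilities_behavior(i, "smoking", state,
                                                  eval_engine)
        p_split, _ = choice_probabilities_behavior(i, "smoking", state,
                                                   split_engine)
        assert np.allclose(p_eval, p_split)


def test_creation_effect_ignored_in_decrease_context():
    rng = np.random.default_rng(41)
    engine, state = random_setup(6, rng)
    model = engine.model
    spec = model.effect("behavior:smoking", "other behavior", "marijuana")
    spec.phase = "creation"
    engine.sync_betas()
    base = objective(0, "behavior:smoking", state, engine,
                     phase_context="decrease")
    spec.beta += 5.0
    engine.sync_betas()
    assert objective(0, "behavior:smoking", state, engine,
                     phase_context="decrease") == pytest.approx(base)
    # ... but it does move the increase-context objective
    up = objective(0, "behavior:smoking", state, engine,
                   phase_context="increase")
    spec.beta -= 5.0
    engine.sync_betas()
    up0 = objective(0, "behavior:smoking", state, engine,
                    phase_context="increase")
    zt = state.z["smoking"][0] - model.behavior_means["smoking"]
    if zt != 0:
        assert up != pytest.approx(up0)
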