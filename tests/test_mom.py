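import numpy as np
import pytest

from sabnet.effects import EffectSpec, ModelEngine, ModelSpec, center_model
from sabnet.mom_estimator import (CollinearityError, MomSettings,
                                  ParameterIndex, UndefinedDiagnosticError,
                                  convergence_diagnostics, estimate_mom,
                                  odds_multiplier, score_type_test,
                                  standard_errors, target_statistics)
from sabnet.panel_io import SchoolPanel
from sabnet.synthetic_data import (InitialStateConfig, PanelConfig,
                                   generate_panel)

from conftest import make_panel


def network_only_model(beta_density=-1.5, beta_recip=1.2, extra=None,
                       n_periods=1):
    effects = [EffectSpec("out-degree", "network", beta=beta_density),
               EffectSpec("reciprocity", "network", beta=beta_recip)]
    effects.extend(extra or [])
    return ModelSpec(effects=effects,
                     rates={"network": [3.0] * n_periods},
                     behavior_ranges={"smoking": (0, 3)},
                     n_periods=n_periods)


def small_network_panel(seed=5, n=25, **model_kw):
    model = network_only_model(**model_kw)
    cfg = PanelConfig(
        n_actors=n, graduate_top_grade=False,
        initial=InitialStateConfig(
            behavior_probs={"smoking": (0.7, 0.15, 0.05, 0.1)}))
    panel, truth = generate_panel(model, cfg, rng=seed)
    return panel, truth, model


def test_target_statistics_tiny_examples(tiny_panel):
    model = ModelSpec(
        effects=[EffectSpec("out-degree", "network", beta=0.0),
                 EffectSpec("linear shape", "behavior:smoking"),
                 EffectSpec("quadratic shape", "behavior:smoking")],
        rates={"network": [1.0, 1.0], "behavior:smoking": [1.0, 1.0]},
        behavior_ranges={"smoking": (0, 3)}, n_periods=2)
    tv = target_statistics(tiny_panel, model)
    labels = dict(zip(tv.labels, tv.values))
    # density target = sum of ties at both end waves (2 + 2)
    assert labels["network | out-degree"] == 4
    # network rate targets = Hamming distances per period
    # (period 1: a->c dropped and b->a added)
    assert labels["rate | network | period 1"] == 2
    assert labels["rate | network | period 2"] == 0
    # smoking changes: wave1->2 {0,1,0}; wave2->3 {1,0,1}
    assert labels["rate | behavior:smoking | period 1"] == 1
    assert labels["rate | behavior:smoking | period 2"] == 2


def test_target_statistics_invariant_to_actor_relabeling():
    panel, truth, _ = small_network_panel()
    model = truth["model"]
    tv = target_statistics(panel, model)
    perm = np.random.default_rng(0).permutation(panel.n_actors)
    shuffled = SchoolPanel(
        actor_ids=[panel.actor_ids[i] for i in perm],
        networks=panel.networks[:, perm][:, :, perm],
        behaviors={s: z[:, perm] for s, z in panel.behaviors.items()},
        covariates=panel.covariates.iloc[perm],
        structural_zero=panel.structural_zero[:, perm],
        limited_nomination=panel.limited_nomination[:, perm],
        behavior_ranges=panel.behavior_ranges,
    )
    tv2 = target_statistics(shuffled, model)
    assert np.allclose(tv.values, tv2.values)


def test_convergence_diagnostics_hand_examples():
    # single statistic with deviations {1, 3}: mean 2, sd sqrt(2)
    stats = np.array([[1.0], [3.0]])
    tconv, overall = convergence_diagnostics(stats, np.zeros(1))
    assert tconv[0] == pytest.approx(np.sqrt(2))
    assert overall == pytest.approx(np.sqrt(2))
    # perfectly matched simulations (with noise) center near zero
    rng = np.random.default_rng(0)
    stats = rng.normal(5.0, 1.0, size=(4000, 2))
    tconv, overall = convergence_diagnostics(stats, np.array([5.0, 5.0]))
    assert np.all(np.abs(tconv) < 0.1)
    assert overall < 0.15


def test_convergence_diagnostics_diagonal_closed_form():
    rng = np.random.default_rng(1)
    dev = rng.normal([0.5, -0.3], [1.0, 2.0], size=(500, 2))
    tconv, overall = convergence_diagnostics(dev, np.zeros(2))
    # with (empirically) independent statistics the overall ratio reduces to
    # the Euclidean norm of the per-parameter ratios
    sigma = np.cov(dev, rowvar=False)
    dbar = dev.mean(axis=0)
    expect = np.sqrt(dbar @ np.linalg.inv(sigma) @ dbar)
    assert overall == pytest.approx(expect)
    assert np.hypot(*tconv) == pytest.approx(expect, rel=0.1)


def test_convergence_diagnostics_zero_sd_is_undefined():
    stats = np.ones((5, 2))
    with pytest.raises(UndefinedDiagnosticError):
        convergence_diagnostics(stats, np.zeros(2))


def test_standard_errors_identity_and_scaling():
    rng = np.random.default_rng(2)
    stats = rng.standard_normal((20000, 2))
    se = standard_errors(stats, np.eye(2))
    assert np.allclose(se, 1.0, atol=0.05)
    se2 = standard_errors(2.0 * stats, np.eye(2))
    assert np.allclose(se2 / se, 2.0, atol=0.05)
    with pytest.raises(CollinearityError):
        standard_errors(stats, np.zeros((2, 2)))


@pytest.mark.parametrize("beta, mult, pct", [
    (0.22, 1.25, 25),
    (0.0, 1.0, 0),
    (0.48, 1.62, 62),
    (-0.5, 0.61, -39),
])
def test_odds_multiplier(beta, mult, pct):
    assert odds_multiplier(beta) == (mult, pct)


def test_score_and_finite_difference_derivatives_agree():
    """The likelihood-ratio derivative matrix matches a common-random-number
    finite-difference estimate on a small network-only model."""
    from sabnet.mom_estimator import (_cross_cov, _derivative_fd,
                                      _simulate_batch)
    panel, truth, _ = small_network_panel(seed=3, n=15)
    model = truth["model"]
    idx = ParameterIndex(model)
    engine = ModelEngine(model, panel.covariates, panel.limited_nomination)
    rng = np.random.default_rng(0)
    stats, scores = _simulate_batch(panel, engine, idx, rng, 800, True)
    d_score = _cross_cov(stats, scores)
    settings = MomSettings(phase1_n=800, fd_epsilon=0.4)
    d_fd = _derivative_fd(panel, model, idx, idx.theta_from_model(model),
                          settings, seed=99)
    # diagonal (own-parameter) sensitivities: same sign and magnitude
    for k in range(idx.p):
        assert np.sign(d_score[k, k]) == np.sign(d_fd[k, k])
        assert d_fd[k, k] == pytest.approx(d_score[k, k], rel=0.5, abs=0.6)


def test_estimate_recovers_network_model():
    panel, truth, model = small_network_panel(seed=11, n=30)
    settings = MomSettings(phase1_n=20, phase2_subphases=4, phase2_iters=60,
                           phase3_n=150, seed=5)
    res = estimate_mom(panel, truth["model"], settings)
    assert abs(res.beta("network", "out-degree") - (-1.5)) < \
        3 * res.se_of("network", "out-degree")
    assert abs(res.beta("network", "reciprocity") - 1.2) < \
        3 * res.se_of("network", "reciprocity")
    assert np.max(np.abs(res.tconv)) < 0.5


def test_estimation_is_deterministic_given_seed():
    panel, truth, _ = small_network_panel(seed=7, n=20)
    settings = MomSettings(phase1_n=10, phase2_subphases=2, phase2_iters=15,
                           phase3_n=20, seed=3)
    r1 = estimate_mom(panel, truth["model"], settings)
    r2 = estimate_mom(panel, truth["model"], settings)
    assert np.array_equal(r1.theta, r2.theta)
    assert np.array_equal(r1.se, r2.se)


def test_duplicated_effect_raises_collinearity_error():
    extra = [EffectSpec("reciprocity", "network", beta=0.0)]
    panel, truth, _ = small_network_panel(seed=9, n=20, extra=extra)
    settings = MomSettings(phase1_n=10, phase2_subphases=1, phase2_iters=5,
                           phase3_n=15, seed=1)
    with pytest.raises(CollinearityError):
        estimate_mom(panel, truth["model"], settings)


def test_score_type_test_flags_omitted_strong_effect():
    panel, truth, _ = small_network_panel(seed=13, n=25, beta_recip=1.5)
    fitted = truth["model"].copy()
    fitted.effects = [e for e in fitted.effects if e.name != "reciprocity"]
    # refit nothing: evaluate at the generating values of the reduced model
    candidate = EffectSpec("reciprocity", "network", beta=0.0)
    stat = score_type_test(panel, fitted, candidate, n_sims=60, seed=2)
    # reciprocity was generated positive but simulated at zero: the simulated
    # statistic undershoots the target, so the deviation is negative and large
    assert stat < -2.0


def test_score_type_test_rejects_duplicate_candidate():
    panel, truth, _ = small_network_panel(seed=13, n=20)
    candidate = EffectSpec("reciprocity", "network", beta=0.0)
    with pytest.raises(ValueError):
        score_type_test(panel, truth["model"], candidate, n_sims=5, seed=0)
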