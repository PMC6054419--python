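import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from sabnet.effects import EffectSpec, ModelEngine, ModelSpec, center_model
from sabnet.panel_io import SchoolPanel
from sabnet.sab_simulator import SimState

hyp_settings.register_profile("ci", derandomize=True, max_examples=60)
hyp_settings.load_profile("ci")


def make_panel(networks, behaviors, covariates=None, structural_zero=None,
               limited=None, ranges=None):
    """Hand-built panel from raw arrays (ids a, b, c, ...)."""
    networks = np.asarray(networks, dtype=np.int8)
    n = networks.shape[1]
    waves = networks.shape[0]
    ids = [chr(ord("a") + k) for k in range(n)]
    if covariates is None:
        covariates = pd.DataFrame({
            "gender": ([0, 1] * n)[:n],
            "grade": ([10, 10, 11, 11, 12, 12] * n)[:n],
            "parental_education": ([1, 2, 3, 4] * n)[:n],
            "depressive_symptoms": np.linspace(-0.5, 0.5, n),
            "parental_support": np.zeros(n),
            "parental_monitoring": np.zeros(n),
        }, index=pd.Index(ids, name="actor_id"))
    if structural_zero is None:
        structural_zero = np.zeros((waves, n), dtype=bool)
    if limited is None:
        limited = np.zeros((waves - 1, n), dtype=np.int8)
    ranges = ranges or {s: {"smoking": (0, 3), "drinking": (0, 4),
                            "marijuana": (0, 2)}[s] for s in behaviors}
    return SchoolPanel(
        actor_ids=ids,
        networks=networks,
        behaviors={s: np.asarray(z, dtype=np.int64)
                   for s, z in behaviors.items()},
        covariates=covariates,
        structural_zero=np.asarray(structural_zero, dtype=bool),
        limited_nomination=np.asarray(limited, dtype=np.int8),
        behavior_ranges=ranges,
    )


@pytest.fixture
def tiny_panel():
    """3 actors, 3 waves: a->b stable, b->a appears, a->c disappears."""
    nets = [
        [[0, 1, 1], [0, 0, 0], [0, 0, 0]],
        [[0, 1, 0], [1, 0, 0], [0, 0, 0]],
        [[0, 1, 0], [1, 0, 0], [0, 0, 0]],
    ]
    behaviors = {
        "smoking": [[0, 1, 3], [0, 2, 3], [1, 2, 2]],
        "marijuana": [[0, 0, 2], [0, 1, 2], [0, 1, 1]],
    }
    return make_panel(nets, behaviors)


def full_roster_model(n_periods=2):
    """A model touching every effect in both rosters (smoking equation)."""
    effects = [
        EffectSpec("out-degree", "network", beta=-1.5),
        EffectSpec("reciprocity", "network", beta=1.0),
        EffectSpec("transitive triplets", "network", beta=0.3),
        EffectSpec("3-cycles", "network", beta=-0.2),
        EffectSpec("out-degree popularity", "network", beta=-0.1),
        EffectSpec("in-degree popularity", "network", beta=0.1),
        EffectSpec("out-out sqrt assortativity", "network", beta=-0.1),
        EffectSpec("in-in sqrt assortativity", "network", beta=0.2),
        EffectSpec("covariate similarity", "network",
                   attribute_ref="grade", beta=0.5),
        EffectSpec("behavior similarity", "network",
                   attribute_ref="smoking", beta=0.4),
        EffectSpec("limited nomination ego", "network", beta=-0.8),
        EffectSpec("linear shape", "behavior:smoking", beta=-1.0),
        EffectSpec("quadratic shape", "behavior:smoking", beta=0.5),
        EffectSpec("in-degree", "behavior:smoking", beta=0.05),
        EffectSpec("peer influence", "behavior:smoking", beta=1.0),
        EffectSpec("covariate main", "behavior:smoking",
                   attribute_ref="depressive_symptoms", beta=0.2),
        EffectSpec("other behavior", "behavior:smoking",
                   attribute_ref="marijuana", beta=0.3),
        EffectSpec("friends using other substance", "behavior:smoking",
                   attribute_ref="marijuana", beta=0.1),
        EffectSpec("linear shape", "behavior:marijuana", beta=-0.8),
        EffectSpec("quadratic shape", "behavior:marijuana", beta=0.6),
    ]
    return ModelSpec(
        effects=effects,
        rates={"network": [3.0] * n_periods,
               "behavior:smoking": [2.0] * n_periods,
               "behavior:marijuana": [1.5] * n_periods},
        behavior_ranges={"smoking": (0, 3), "marijuana": (0, 2)},
        n_periods=n_periods,
    )


def random_setup(n, rng, p_tie=0.15, limited_codes=True):
    """Random engine + state over the full effect roster, for oracle tests."""
    from sabnet.synthetic_data import generate_covariates

    cov = generate_covariates(n, rng=rng)
    adj = (rng.random((n, n)) < p_tie).astype(float)
    np.fill_diagonal(adj, 0.0)
    z = {"smoking": rng.integers(0, 4, n).astype(float),
         "marijuana": rng.integers(0, 3, n).astype(float)}
    model = full_roster_model()
    panel = make_panel(adj[None].astype(np.int8),
                       {s: v[None].astype(int) for s, v in z.items()},
                       covariates=cov)
    model = center_model(model, panel)
    limited = (rng.integers(-1, 2, (2, n)).astype(np.int8)
               if limited_codes else np.zeros((2, n), dtype=np.int8))
    engine = ModelEngine(model, cov, limited)
    state = SimState(adj=adj, z=z, active=np.ones(n, dtype=bool), period=0)
    return engine, state

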