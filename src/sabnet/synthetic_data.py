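"""Synthetic three-wave school panels with known ground truth.

The real school panels this package targets are restricted-access, so every
stage is exercised on synthetic schools that emulate their structure: actors
across grades with gender, parental-education and psychosocial-score
covariates; a sparse directed friendship network grown with grade/gender
homophily and a reciprocity bias, out-degrees capped at 10 (five female plus
five male nominations); ordinal substance-use behaviors drawn from realistic
wave-1 marginals (about 69% never-smokers, 44% never-drinkers, 83%
marijuana never-users in the suburban-school default); graduation of the top
grade before the last wave (structural zeros); and a small fraction of
limited-nomination codes.

Waves 2 and 3 are produced by the forward simulator under a known model, so
parameter-recovery experiments have an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .effects import EffectSpec, ModelEngine, ModelSpec, center_model
from .panel_io import DEFAULT_BEHAVIOR_RANGES, SchoolPanel
from .sab_simulator import SimState, restrict_to_active, simulate_period


class ConfigError(ValueError):
    pass


@dataclass
class CovariateConfig:
    """Marginals for the covariate roster (suburban-school defaults)."""

    p_female: float = 0.475
    grade_probs: Mapping[int, float] = field(
        default_factory=lambda: {10: 0.3723, 11: 0.3343, 12: 0.2934})
    parental_education_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.2167, 2: 0.3062, 3: 0.2879, 4: 0.1892})
    #: score name -> (mean, sd); drawn normal then affinely matched.
    score_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "depressive_symptoms": (0.14, 0.53),
            "parental_support": (-0.05, 0.30),
            "parental_monitoring": (-0.01, 0.12),
        })

    def validate(self) -> None:
        if not 0 <= self.p_female <= 1:
            raise ConfigError("p_female must be in [0, 1]")
        for name, probs in (("grade_probs", self.grade_probs),
                            ("parental_education_probs",
                             self.parental_education_probs)):
            if not probs or any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} must be nonnegative and nonempty")
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1")
        for name, (_, sd) in self.score_moments.items():
            if sd <= 0:
                raise ConfigError(f"{name}: sd must be positive")


@dataclass
class InitialStateConfig:
    """Wave-1 behavior marginals and network-growth parameters."""

    behavior_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "smoking": (0.686, 0.1754, 0.0491, 0.0895),
            "drinking": (0.4403, 0.2654, 0.0859, 0.0666, 0.1419),
            "marijuana": (0.8305, 0.0776, 0.0918),
        })
    mean_out_degree: float = 2.7
    max_out_degree: int = 10
    grade_homophily: float = 2.0
    gender_homophily: float = 0.7
    # log-weight bonus for reciprocating an existing nomination; ~3.5 puts
    # the wave-1 reciprocity index near 0.3, as observed in school panels
    reciprocity_bias: float = 3.5

    def validate(self) -> None:
        for sub, probs in self.behavior_probs.items():
            # printed survey marginals carry rounding error; allow ~0.1%
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-3:
                raise ConfigError(f"behavior_probs[{sub}] must sum to 1")
        if self.mean_out_degree <= 0:
            raise ConfigError("mean_out_degree must be positive")
        if not 0 < self.max_out_degree:
            raise ConfigError("max_out_degree must be positive")


@dataclass
class PanelConfig:
    n_actors: int = 100
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    initial: InitialStateConfig = field(default_factory=InitialStateConfig)
    graduate_top_grade: bool = True
    #: fraction of actors newly limited per transition, and fraction of the
    #: previously limited who return to full nominations.
    limited_fraction: tuple[float, float] = (0.035, 0.5)
    period_spans: tuple[float, float] = (8.8, 10.9)


def generate_covariates(n: int, config: CovariateConfig | None = None,
                        rng: np.random.Generator | int | None = None
                        ) -> pd.DataFrame:
    """Draw an actor covariate table with the configured marginals."""
    if n < 2:
        raise ConfigError("need at least 2 actors")
    config = config or CovariateConfig()
    config.validate()
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    ids = [f"a{k + 1:04d}" for k in range(n)]
    grades = list(config.grade_probs)
    edu = list(config.parental_education_probs)
    table = {
        "gender": rng.binomial(1, config.p_female, size=n),
        "grade": rng.choice(grades, size=n,
                            p=list(config.grade_probs.values())),
        "parental_education": rng.choice(
            edu, size=n, p=list(config.parental_education_probs.values())),
    }
    for name, (mean, sd) in config.score_moments.items():
        table[name] = mean + sd * rng.standard_normal(n)
    return pd.DataFrame(table, index=pd.Index(ids, name="actor_id"))


def generate_initial_state(covariates: pd.DataFrame,
                           config: InitialStateConfig | None = None,
                           rng: np.random.Generator | int | None = None
                           ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Wave-1 network and behaviors.

    The network grows sequentially: each actor draws an out-degree (Poisson
    around the configured mean, capped) and nominates distinct targets with
    preference weights exp(homophily terms + reciprocity bonus for peers who
    already nominated them).
    """
    config = config or InitialStateConfig()
    config.validate()
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    n = len(covariates)
    grade = covariates["grade"].to_numpy()
    gender = covariates["gender"].to_numpy()

    adj = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    for i in order:
        d = int(min(rng.poisson(config.mean_out_degree),
                    config.max_out_degree, n - 1))
        if d == 0:
            continue
        logw = (config.grade_homophily * (grade == grade[i])
                + config.gender_homophily * (gender == gender[i])
                + config.reciprocity_bias * (adj[:, i] == 1))
        w = np.exp(logw)
        w[i] = 0.0
        targets = rng.choice(n, size=d, replace=False, p=w / w.sum())
        adj[i, targets] = 1

    behaviors = {
        sub: rng.choice(len(probs), size=n,
                        p=np.asarray(probs) / np.sum(probs))
        for sub, probs in config.behavior_probs.items()
    }
    return adj, behaviors


def generate_panel(true_model: ModelSpec, config: PanelConfig | None = None,
                   rng: np.random.Generator | int | None = None
                   ) -> tuple[SchoolPanel, dict]:
    """Generate a full three-wave panel by simulating a known model forward.

    Returns the panel and a truth record holding the generating model (with
    centering constants fixed from the wave-1 state), the configuration and
    the generator state used, enabling exact parameter-recovery experiments.
    """
    config = config or PanelConfig()
    seed_note = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    true_model.validate()

    covariates = generate_covariates(config.n_actors, config.covariates, rng)
    init_cfg = config.initial
    needed = set(true_model.behavior_ranges)
    missing = needed - set(init_cfg.behavior_probs)
    if missing:
        raise ConfigError(f"no initial marginals for {sorted(missing)}")
    adj1, behav1 = generate_initial_state(covariates, init_cfg, rng)
    behav1 = {s: behav1[s] for s in true_model.behavior_ranges}

    n = config.n_actors
    n_waves = true_model.n_periods + 1
    structural_zero = np.zeros((n_waves, n), dtype=bool)
    if config.graduate_top_grade:
        top = covariates["grade"].to_numpy() == covariates["grade"].max()
        structural_zero[n_waves - 1] = top

    limited = np.zeros((true_model.n_periods, n), dtype=np.int8)
    new_frac, recover_frac = config.limited_fraction
    currently_limited = np.zeros(n, dtype=bool)
    for p in range(true_model.n_periods):
        newly = (~currently_limited) & (rng.random(n) < new_frac)
        recovered = currently_limited & (rng.random(n) < recover_frac)
        limited[p, newly] = -1
        limited[p, recovered] = 1
        currently_limited = (currently_limited | newly) & ~recovered

    # Fix centering constants from the wave-1 state, then simulate forward.
    seed_panel = SchoolPanel(
        actor_ids=list(covariates.index),
        networks=adj1[None].copy(),
        behaviors={s: z[None].astype(np.int64) for s, z in behav1.items()},
        covariates=covariates,
        structural_zero=np.zeros((1, n), dtype=bool),
        limited_nomination=np.zeros((0, n), dtype=np.int8),
        behavior_ranges=dict(true_model.behavior_ranges),
    )
    model = center_model(true_model, seed_panel)
    engine = ModelEngine(model, covariates, limited)

    networks = np.zeros((n_waves, n, n), dtype=np.int8)
    behaviors = {s: np.zeros((n_waves, n), dtype=np.int64) for s in behav1}
    networks[0] = adj1
    for s, z in behav1.items():
        behaviors[s][0] = z

    state = SimState(adj=adj1.astype(float),
                     z={s: z.astype(float) for s, z in behav1.items()},
                     active=np.ones(n, dtype=bool))
    for m in range(true_model.n_periods):
        state.active = ~(structural_zero[m] | structural_zero[m + 1])
        restrict_to_active(state)
        state, _ = simulate_period(state, engine, m, rng)
        networks[m + 1] = state.adj.astype(np.int8)
        for s in behaviors:
            behaviors[s][m + 1] = state.z[s].astype(np.int64)

    panel = SchoolPanel(
        actor_ids=list(covariates.index),
        networks=networks,
        behaviors=behaviors,
        covariates=covariates,
        structural_zero=structural_zero,
        limited_nomination=limited,
        behavior_ranges=dict(true_model.behavior_ranges),
        period_spans=list(config.period_spans),
    )
    truth = {"model": model, "config": config, "seed": seed_note}
    return panel, truth


# ---------------------------------------------------------------------------
# Study-condition model presets


def recovery_model() -> ModelSpec:
    """Generating model for the parameter-recovery experiments: a network
    co-evolving with smoking and marijuana use, including one selection
    effect, peer influence, one cross-substance effect and a null (zero)
    3-cycles effect for calibration checks."""
    effects = [
        EffectSpec("out-degree", "network", beta=-2.2),
        EffectSpec("reciprocity", "network", beta=1.6),
        EffectSpec("transitive triplets", "network", beta=0.4),
        EffectSpec("3-cycles", "network", beta=0.0),
        EffectSpec("behavior similarity", "network",
                   attribute_ref="smoking", beta=0.6),
        # shape coefficients of the magnitude typical for these ordinal
        # scales, keeping category distributions roughly stationary
        EffectSpec("linear shape", "behavior:smoking", beta=-2.0),
        EffectSpec("quadratic shape", "behavior:smoking", beta=0.7),
        EffectSpec("peer influence", "behavior:smoking", beta=1.5),
        EffectSpec("other behavior", "behavior:smoking",
                   attribute_ref="marijuana", beta=0.4),
        EffectSpec("linear shape", "behavior:marijuana", beta=-2.0),
        EffectSpec("quadratic shape", "behavior:marijuana", beta=1.0),
    ]
    return ModelSpec(
        effects=effects,
        rates={"network": [4.0, 4.0],
               "behavior:smoking": [3.0, 3.0],
               "behavior:marijuana": [2.5, 2.5]},
        behavior_ranges={"smoking": (0, 3), "marijuana": (0, 2)},
        n_periods=2,
    )


def counterfactual_model() -> ModelSpec:
    """Generating model for the counterfactual experiments: all three
    substances, positive marijuana-to-smoking/drinking cross effects,
    positive within-substance peer influence, and selection effects."""
    effects = [
        EffectSpec("out-degree", "network", beta=-2.2),
        EffectSpec("reciprocity", "network", beta=1.6),
        EffectSpec("transitive triplets", "network", beta=0.35),
        EffectSpec("behavior similarity", "network",
                   attribute_ref="smoking", beta=0.3),
        EffectSpec("behavior similarity", "network",
                   attribute_ref="drinking", beta=0.3),
        EffectSpec("behavior similarity", "network",
                   attribute_ref="marijuana", beta=0.5),
        # shapes hold the category distributions roughly stationary at a
        # mixed (high-use-school) profile, so cross-substance and influence
        # effects have users to act on
        EffectSpec("linear shape", "behavior:smoking", beta=-1.6),
        EffectSpec("quadratic shape", "behavior:smoking", beta=0.73),
        EffectSpec("peer influence", "behavior:smoking", beta=0.8),
        EffectSpec("other behavior", "behavior:smoking",
                   attribute_ref="marijuana", beta=0.8),
        EffectSpec("linear shape", "behavior:drinking", beta=-1.0),
        EffectSpec("quadratic shape", "behavior:drinking", beta=0.27),
        EffectSpec("peer influence", "behavior:drinking", beta=0.6),
        EffectSpec("other behavior", "behavior:drinking",
                   attribute_ref="marijuana", beta=0.8),
        EffectSpec("linear shape", "behavior:marijuana", beta=-1.5),
        EffectSpec("quadratic shape", "behavior:marijuana", beta=1.13),
        EffectSpec("peer influence", "behavior:marijuana", beta=1.2),
    ]
    return ModelSpec(
        effects=effects,
        rates={"network": [4.0, 4.0],
               "behavior:smoking": [2.5, 2.5],
               "behavior:drinking": [2.5, 2.5],
               "behavior:marijuana": [2.0, 2.0]},
        behavior_ranges=dict(DEFAULT_BEHAVIOR_RANGES),
        n_periods=2,
    )


def generate_reconstruction_records(n: int,
                                    rng: np.random.Generator | int | None = None,
                                    scenario_probs: Mapping[str, float] | None = None):
    """Synthetic retrospective marijuana items (onset age, age at wave 1,
    lifetime and past-30-day counts) with a configurable scenario mix.

    The default mix puts about 62% of respondents in the never-tried branch,
    2% with onset after wave 1, 1% with a zero lifetime/past-month
    difference, 15% averaging under one use per month, 16% light and 5%
    heavy users — a suburban-school-like profile.
    """
    from .marijuana_reconstruction import ReconstructionRecord

    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    probs = dict(scenario_probs or {
        "never_tried": 0.62, "onset_after_t1": 0.02, "zero_diff": 0.01,
        "monthly_lt1": 0.15, "monthly_1_10": 0.16, "monthly_gt10": 0.05,
    })
    names = list(probs)
    weights = np.array([probs[s] for s in names], dtype=float)
    weights /= weights.sum()
    records = []
    for _ in range(n):
        scenario = names[int(rng.choice(len(names), p=weights))]
        s1 = int(rng.integers(12, 19))
        h32 = int(rng.integers(0, 10))
        if scenario == "never_tried":
            rec = ReconstructionRecord(0, s1, 0, 0)
        elif scenario == "onset_after_t1":
            rec = ReconstructionRecord(s1 + 1, s1, h32 + rng.integers(1, 5),
                                       h32)
        elif scenario == "zero_diff":
            count = h32 + int(rng.integers(1, 5))
            rec = ReconstructionRecord(int(rng.integers(10, s1 + 1)), s1,
                                       count, count)
        else:
            onset = int(rng.integers(10, s1 + 1))
            if scenario == "monthly_lt1":
                diff = int(rng.integers(1, 5))        # mean < 1 per month
            elif scenario == "monthly_1_10":
                diff = int(rng.integers(5, 51))       # 1 <= mean <= 10
            else:
                diff = int(rng.integers(51, 400))     # mean > 10
            rec = ReconstructionRecord(onset, s1, h32 + diff, h32)
        records.append(rec)
    return records
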