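"""Zero-out-one-effect counterfactual simulation experiment.

Given a fitted (or supplied) model, a scenario names a group of coefficients
to set to zero — the cross-substance effects of marijuana use on smoking
and/or drinking, the within-substance peer influence effects, or the peer
selection effects — and the system is simulated forward many times from the
wave-1 state across both periods.  The summary is the distribution of each
substance's categories at the end of the runs (mean percent +/- Monte Carlo
sd over replicates), compared across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import EffectSpec, ModelEngine, ModelSpec
from .panel_io import SchoolPanel
from .sab_simulator import simulate_forward

SCENARIO_NAMES: tuple[str, ...] = (
    "none", "mtos", "mtod", "mtosd", "infs", "infd", "infm",
    "selm", "selall", "all",
)


class UnknownScenarioError(ValueError):
    pass


def _marijuana_to(substance: str):
    def match(e: EffectSpec) -> bool:
        return (e.dependent == f"behavior:{substance}"
                and e.name == "other behavior"
                and e.attribute_ref == "marijuana")
    return match


def _influence(substance: str):
    def match(e: EffectSpec) -> bool:
        return (e.dependent == f"behavior:{substance}"
                and e.name == "peer influence")
    return match


def _selection(substances: tuple[str, ...]):
    def match(e: EffectSpec) -> bool:
        return (e.dependent == "network" and e.name == "behavior similarity"
                and e.attribute_ref in substances)
    return match


_GROUPS = {
    "mtos": [_marijuana_to("smoking")],
    "mtod": [_marijuana_to("drinking")],
    "mtosd": [_marijuana_to("smoking"), _marijuana_to("drinking")],
    "infs": [_influence("smoking")],
    "infd": [_influence("drinking")],
    "infm": [_influence("marijuana")],
    "selm": [_selection(("marijuana",))],
    "selall": [_selection(("smoking", "drinking", "marijuana"))],
}
_GROUPS["all"] = [m for name in ("mtosd", "infs", "infd", "infm", "selall")
                  for m in _GROUPS[name]]


@dataclass
class ScenarioSpec:
    name: str
    zeroed_effect_keys: list[tuple] = field(default_factory=list)

    @classmethod
    def resolve(cls, name: str, model: ModelSpec) -> "ScenarioSpec":
        if name not in SCENARIO_NAMES:
            raise UnknownScenarioError(
                f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
        keys = []
        for matcher in _GROUPS.get(name, []):
            keys.extend(e.key() for e in model.effects if matcher(e))
        return cls(name=name, zeroed_effect_keys=sorted(set(keys)))


def zero_out(model: ModelSpec, scenario: str) -> ModelSpec:
    """Copy the model with the scenario's coefficients set to zero.

    All phases (evaluation, creation, endowment) of a matched effect are
    zeroed.  Scenario ``none`` returns an identical copy; ``all`` zeroes the
    union of every listed group (idempotent set semantics).
    """
    spec = ScenarioSpec.resolve(scenario, model)
    out = model.copy()
    keys = set(spec.zeroed_effect_keys)
    for e in out.effects:
        if e.key() in keys:
            e.beta = 0.0
    return out


@dataclass
class DistributionSummary:
    """Per-substance category percentages (mean +/- MC sd over replicates)."""

    scenario: str
    reps: int
    seed: int | None
    mean_pct: dict[str, np.ndarray]
    sd_pct: dict[str, np.ndarray]

    def categories(self, substance: str) -> list[int]:
        return list(range(len(self.mean_pct[substance])))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sub, means in self.mean_pct.items():
            for cat, (mean, sd) in enumerate(zip(means, self.sd_pct[sub])):
                rows.append({"scenario": self.scenario, "substance": sub,
                             "category": cat, "mean_pct": mean, "sd_pct": sd,
                             "reps": self.reps})
        cols = ["scenario", "substance", "category", "mean_pct", "sd_pct",
                "reps"]
        return pd.DataFrame(rows, columns=cols)


def run_counterfactual(panel: SchoolPanel, model: ModelSpec, scenario: str,
                       reps: int = 1000,
                       rng: np.random.Generator | int | None = None
                       ) -> DistributionSummary:
    """Simulate a scenario forward ``reps`` times and summarize end states.

    Each replicate chains period simulations from the observed (or synthetic)
    wave-1 state through all periods, honoring the structural-zero schedule;
    category percentages are computed over the actors active in the final
    period.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cf_model = zero_out(model, scenario)
    engine = ModelEngine(cf_model, panel.covariates, panel.limited_nomination)

    n_cats = {s: hi - lo + 1 for s, (lo, hi) in model.behavior_ranges.items()}
    pcts = {s: np.empty((reps, n_cats[s])) for s in model.substances}
    final_active = panel.active_mask(panel.n_periods - 1)
    for r in range(reps):
        end = simulate_forward(panel, engine, rng)[-1]
        for sub in model.substances:
            vals = end.z[sub][final_active]
            lo, _ = model.behavior_ranges[sub]
            counts = np.bincount((vals - lo).astype(int),
                                 minlength=n_cats[sub])
            pcts[sub][r] = 100.0 * counts / len(vals)
    return DistributionSummary(
        scenario=scenario,
        reps=reps,
        seed=seed,
        mean_pct={s: p.mean(axis=0) for s, p in pcts.items()},
        sd_pct={s: p.std(axis=0, ddof=1) if reps > 1 else np.zeros(p.shape[1])
                for s, p in pcts.items()},
    )


def compare_scenarios(baseline: DistributionSummary,
                      alternatives: list[DistributionSummary]) -> pd.DataFrame:
    """Per-category percentage-point differences from the baseline scenario,
    with Monte Carlo standard errors of the differences."""
    rows = []
    for alt in alternatives:
        if set(alt.mean_pct) != set(baseline.mean_pct):
            raise ValueError("mismatched substances between summaries")
        for sub in baseline.mean_pct:
            if len(alt.mean_pct[sub]) != len(baseline.mean_pct[sub]):
                raise ValueError(f"mismatched categories for {sub}")
            se_b = baseline.sd_pct[sub] / np.sqrt(baseline.reps)
            se_a = alt.sd_pct[sub] / np.sqrt(alt.reps)
            delta = alt.mean_pct[sub] - baseline.mean_pct[sub]
            se = np.sqrt(se_a ** 2 + se_b ** 2)
            for cat in range(len(delta)):
                rows.append({
                    "scenario": alt.scenario, "substance": sub,
                    "category": cat, "delta_pp": delta[cat],
                    "mc_se": se[cat],
                })
    return pd.DataFrame(rows,
                        columns=["scenario", "substance", "category",
                                 "delta_pp", "mc_se"])


def plot_summaries(summaries: list[DistributionSummary], path=None):
    """Grouped bar chart of category distributions per scenario (one panel
    per substance).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    substances = list(summaries[0].mean_pct)
    fig, axes = plt.subplots(len(substances), 1,
                             figsize=(8, 2.6 * len(substances)), sharex=False)
    if len(substances) == 1:
        axes = [axes]
    width = 0.8 / len(summaries)
    for ax, sub in zip(axes, substances):
        n_cat = len(summaries[0].mean_pct[sub])
        x = np.arange(n_cat)
        for k, summ in enumerate(summaries):
            ax.bar(x + k * width, summ.mean_pct[sub], width,
                   yerr=summ.sd_pct[sub], label=summ.scenario, capsize=2)
        ax.set_title(sub)
        ax.set_ylabel("% of actors")
        ax.set_xticks(x + 0.4 - width / 2, [str(c) for c in range(n_cat)])
    axes[0].legend(fontsize=7, ncol=min(len(summaries), 5))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
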