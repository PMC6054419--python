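"""Effect statistics and actor objective functions.

A stochastic actor-based (SAB) model drives each actor's myopic choices by a
linear objective  f_i(state) = sum_k beta_k * s_ik(state)  built from named
*effects*: endogenous network statistics (reciprocity, transitive triplets,
degree assortativity, ...), homophily/selection terms on covariates and
behaviors, and behavior-equation terms (shape, peer influence, cross-substance
main effects, ...).

Behavior-equation effects carry a *phase*: ``evaluation`` terms enter every
choice, ``creation`` terms only upward moves (initiation), and ``endowment``
terms only downward moves (cessation) — the decomposition used to separate
uptake from maintenance processes.

Conventions (documented in docs/methods.md): behaviors and covariates are
mean-centered; similarity kernels are centered by the observed mean similarity;
degree-popularity effects use raw degrees while assortativity effects use
square-root degrees.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NETWORK_EFFECTS: tuple[str, ...] = (
    "out-degree",
    "reciprocity",
    "transitive triplets",
    "3-cycles",
    "out-degree popularity",
    "in-degree popularity",
    "out-out sqrt assortativity",
    "in-in sqrt assortativity",
    "covariate similarity",
    "behavior similarity",
    "limited nomination ego",
)

BEHAVIOR_EFFECTS: tuple[str, ...] = (
    "linear shape",
    "quadratic shape",
    "in-degree",
    "peer influence",
    "covariate main",
    "other behavior",
    "friends using other substance",
)

PHASES: tuple[str, ...] = ("evaluation", "creation", "endowment")

#: Effects whose definition references another variable via ``attribute_ref``.
_NEEDS_ATTRIBUTE = {
    "covariate similarity", "behavior similarity",
    "covariate main", "other behavior", "friends using other substance",
}


class UnknownEffectError(ValueError):
    pass


class ModelSpecError(ValueError):
    pass


def similarity(v_i: float, v_j: float, value_range: float) -> float:
    """Similarity kernel 1 - |v_i - v_j| / range, in [0, 1].

    The range is the span of the variable's scale (e.g. 3 for smoking coded
    0-3), so identical values score 1 and opposite scale extremes score 0.
    """
    if value_range <= 0:
        raise ValueError(f"value range must be positive, got {value_range}")
    return 1.0 - abs(v_i - v_j) / value_range


@dataclass
class EffectSpec:
    """One named effect: statistic + dependent variable + phase + coefficient."""

    name: str
    dependent: str  # "network" or "behavior:<substance>"
    phase: str = "evaluation"
    attribute_ref: str | None = None
    beta: float = 0.0

    def __post_init__(self) -> None:
        is_network = self.dependent == "network"
        roster = NETWORK_EFFECTS if is_network else BEHAVIOR_EFFECTS
        if self.name not in roster:
            raise UnknownEffectError(
                f"unknown {'network' if is_network else 'behavior'} effect "
                f"{self.name!r}")
        if self.phase not in PHASES:
            raise ModelSpecError(f"unknown phase {self.phase!r}")
        if is_network and self.phase != "evaluation":
            raise ModelSpecError(
                "creation/endowment phases apply to behavior effects only")
        if self.name in _NEEDS_ATTRIBUTE and self.attribute_ref is None:
            raise ModelSpecError(f"effect {self.name!r} needs attribute_ref")

    @property
    def substance(self) -> str | None:
        if self.dependent.startswith("behavior:"):
            return self.dependent.split(":", 1)[1]
        return None

    def key(self) -> tuple:
        return (self.dependent, self.name, self.attribute_ref, self.phase)

    def label(self) -> str:
        parts = [self.dependent, self.name]
        if self.attribute_ref:
            parts.append(self.attribute_ref)
        if self.phase != "evaluation":
            parts.append(self.phase)
        return " | ".join(parts)


@dataclass
class ModelSpec:
    """A full parameterized SAB model: effects plus per-period change rates."""

    effects: list[EffectSpec]
    rates: dict[str, list[float]]  # dependent -> one positive rate per period
    behavior_ranges: dict[str, tuple[int, int]]
    n_periods: int = 2
    # Centering constants; filled by ``center_model`` (or by the generator).
    behavior_means: dict[str, float] = field(default_factory=dict)
    covariate_means: dict[str, float] = field(default_factory=dict)
    covariate_ranges: dict[str, float] = field(default_factory=dict)
    similarity_means: dict[str, float] = field(default_factory=dict)

    @property
    def substances(self) -> list[str]:
        return list(self.behavior_ranges)

    @property
    def dependents(self) -> list[str]:
        return list(self.rates)

    def validate(self) -> None:
        for dep, per_period in self.rates.items():
            if len(per_period) != self.n_periods:
                raise ModelSpecError(
                    f"rate for {dep!r} needs {self.n_periods} periods")
            if any(r <= 0 for r in per_period):
                raise ModelSpecError(f"rates must be positive ({dep!r})")
        for sub in self.substances:
            shapes = {e.name for e in self.effects
                      if e.dependent == f"behavior:{sub}"
                      and e.name in ("linear shape", "quadratic shape")}
            if f"behavior:{sub}" in self.rates and shapes != {
                    "linear shape", "quadratic shape"}:
                raise ModelSpecError(
                    f"{sub}: modeled behaviors need one linear and one "
                    "quadratic shape effect")
        for e in self.effects:
            ref = e.attribute_ref
            if e.name in ("behavior similarity", "other behavior",
                          "friends using other substance"):
                if ref not in self.behavior_ranges:
                    raise ModelSpecError(
                        f"{e.label()}: unknown substance {ref!r}")

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def effect(self, dependent: str, name: str,
               attribute_ref: str | None = None,
               phase: str = "evaluation") -> EffectSpec:
        for e in self.effects:
            if (e.dependent, e.name, e.phase) == (dependent, name, phase) and (
                    attribute_ref is None or e.attribute_ref == attribute_ref):
                return e
        raise KeyError((dependent, name, attribute_ref, phase))

    def betas(self) -> np.ndarray:
        return np.array([e.beta for e in self.effects], dtype=float)

    def set_betas(self, values: Sequence[float]) -> None:
        for e, b in zip(self.effects, values, strict=True):
            e.beta = float(b)


def behavior_range_width(model: ModelSpec, substance: str) -> float:
    lo, hi = model.behavior_ranges[substance]
    return float(hi - lo)


def center_model(model: ModelSpec, panel) -> ModelSpec:
    """Fill the model's centering constants from an observed panel.

    Behavior means are grand means over actors and waves (structural-zero
    actor-waves excluded); covariate means/ranges come from the covariate
    table; similarity means average the similarity kernel over all ordered
    actor pairs (and waves, for behaviors).  Constants already present are
    left untouched, so a generating model can be re-used verbatim in
    estimation.
    """
    model = model.copy()
    present = ~panel.structural_zero  # (W, n)
    for sub in model.substances:
        if sub not in model.behavior_means:
            z = panel.behaviors[sub]
            model.behavior_means[sub] = float(z[present].mean())
    needed_cov = {e.attribute_ref for e in model.effects
                  if e.name in ("covariate similarity", "covariate main")}
    for name in needed_cov:
        vals = panel.covariates[name].to_numpy(dtype=float)
        model.covariate_means.setdefault(name, float(vals.mean()))
        model.covariate_ranges.setdefault(
            name, float(vals.max() - vals.min()) or 1.0)
    for e in model.effects:
        if e.name == "covariate similarity":
            name = e.attribute_ref
            if name in model.similarity_means:
                continue
            vals = panel.covariates[name].to_numpy(dtype=float)
            rng = model.covariate_ranges[name]
            model.similarity_means[name] = _mean_pair_similarity(vals[None, :], rng)
        elif e.name in ("behavior similarity", "peer influence"):
            sub = e.attribute_ref if e.name == "behavior similarity" else e.substance
            if sub in model.similarity_means:
                continue
            z = panel.behaviors[sub].astype(float)
            rng = behavior_range_width(model, sub)
            model.similarity_means[sub] = _mean_pair_similarity(z, rng)
    return model


def _mean_pair_similarity(values: np.ndarray, value_range: float) -> float:
    """Mean of the similarity kernel over ordered pairs, averaged over rows."""
    total, count = 0.0, 0
    for row in values:
        diff = np.abs(row[:, None] - row[None, :])
        n = len(row)
        off = ~np.eye(n, dtype=bool)
        total += (1.0 - diff[off] / value_range).sum()
        count += off.sum()
    return float(total / count)


# ---------------------------------------------------------------------------
# Compiled engine


_NET_CODE = {name: k for k, name in enumerate(NETWORK_EFFECTS)}
_BEH_CODE = {name: k for k, name in enumerate(BEHAVIOR_EFFECTS)}
_PHASE_CODE = {"evaluation": 0, "creation": 1, "endowment": 2}


class ModelEngine:
    """A :class:`ModelSpec` compiled against one school's actor data.

    Resolves attribute references to dense arrays, fixes centering constants,
    and exposes fast statistic/delta evaluation for the simulator and the
    Method-of-Moments estimator.  States passed in must carry ``adj`` (float
    adjacency), ``z`` (substance -> float array), ``active`` (bool mask),
    ``outdeg``/``indeg`` caches and a ``period`` index.
    """

    def __init__(self, model: ModelSpec, covariates: pd.DataFrame,
                 limited_nomination: np.ndarray | None = None) -> None:
        model.validate()
        missing = ({s for s in model.substances if s not in model.behavior_means}
                   | {e.attribute_ref for e in model.effects
                      if e.name in ("covariate similarity", "covariate main")
                      and e.attribute_ref not in model.covariate_means})
        if missing:
            raise ModelSpecError(
                f"model lacks centering constants for {sorted(missing)}; "
                "call center_model first")
        self.model = model
        self.n = len(covariates)
        self.substances = model.substances
        if limited_nomination is None:
            limited_nomination = np.zeros((model.n_periods, self.n), dtype=np.int8)
        self.limited_nomination = np.asarray(limited_nomination, dtype=float)

        self._cov: dict[str, np.ndarray] = {}
        for name in covariates.columns:
            try:
                self._cov[name] = covariates[name].to_numpy(dtype=float)
            except (TypeError, ValueError):
                continue

        # Network-effect table: (code, aux vector or scalar params)
        self.net_effects: list[EffectSpec] = [
            e for e in model.effects if e.dependent == "network"]
        self.net_betas = np.array([e.beta for e in self.net_effects])
        self._net_compiled = [self._compile_network(e) for e in self.net_effects]

        # Behavior-effect tables, per substance.
        self.beh_effects: dict[str, list[EffectSpec]] = {}
        self._beh_compiled: dict[str, list] = {}
        self.beh_betas: dict[str, np.ndarray] = {}
        self.beh_phases: dict[str, np.ndarray] = {}
        for sub in self.substances:
            specs = [e for e in model.effects
                     if e.dependent == f"behavior:{sub}"]
            self.beh_effects[sub] = specs
            self._beh_compiled[sub] = [self._compile_behavior(e, sub)
                                       for e in specs]
            self.beh_betas[sub] = np.array([e.beta for e in specs])
            self.beh_phases[sub] = np.array(
                [_PHASE_CODE[e.phase] for e in specs], dtype=np.int8)

    # -- compilation helpers -------------------------------------------------

    def _centered_cov(self, name: str) -> np.ndarray:
        return self._cov[name] - self.model.covariate_means[name]

    def _compile_network(self, e: EffectSpec):
        code = _NET_CODE[e.name]
        if e.name == "covariate similarity":
            vals = self._cov[e.attribute_ref]
            rng = self.model.covariate_ranges[e.attribute_ref]
            sbar = self.model.similarity_means[e.attribute_ref]
            return (code, vals, rng, sbar)
        if e.name == "behavior similarity":
            sub = e.attribute_ref
            rng = behavior_range_width(self.model, sub)
            sbar = self.model.similarity_means[sub]
            return (code, sub, rng, sbar)
        if e.name == "limited nomination ego":
            return (code,)
        return (code,)

    def _compile_behavior(self, e: EffectSpec, sub: str):
        code = _BEH_CODE[e.name]
        if e.name == "peer influence":
            rng = behavior_range_width(self.model, sub)
            sbar = self.model.similarity_means.get(sub, 0.0)
            return (code, rng, sbar)
        if e.name == "covariate main":
            return (code, self._centered_cov(e.attribute_ref))
        if e.name in ("other behavior", "friends using other substance"):
            other = e.attribute_ref
            return (code, other, self.model.behavior_means[other])
        return (code,)

    def sync_betas(self) -> None:
        """Refresh the cached beta arrays after editing the ModelSpec."""
        self.net_betas = np.array([e.beta for e in self.net_effects])
        for sub in self.substances:
            self.beh_betas[sub] = np.array(
                [e.beta for e in self.beh_effects[sub]])

    # -- network statistics --------------------------------------------------

    def network_actor_statistic(self, spec_idx: int, state, i: int) -> float:
        """Actor i's contribution to one network effect (brute-path free)."""
        comp = self._net_compiled[spec_idx]
        code = comp[0]
        A = state.adj
        r = A[i]
        o, d = state.outdeg, state.indeg
        if code == 0:
            return float(o[i])
        if code == 1:
            return float(r @ A[:, i])
        if code == 2:
            return float(r @ (A @ r))
        if code == 3:
            return float(r @ (A @ A[:, i]))
        if code == 4:
            return float(r @ o)
        if code == 5:
            return float(r @ d)
        if code == 6:
            return float(np.sqrt(o[i]) * (r @ np.sqrt(o)))
        if code == 7:
            return float(np.sqrt(d[i]) * (r @ np.sqrt(d)))
        if code == 8:
            _, vals, rng, sbar = comp
            sim = 1.0 - np.abs(vals[i] - vals) / rng
            return float(r @ (sim - sbar))
        if code == 9:
            _, sub, rng, sbar = comp
            z = state.z[sub]
            sim = 1.0 - np.abs(z[i] - z) / rng
            return float(r @ (sim - sbar))
        if code == 10:
            return float(self.limited_nomination[state.period, i] * o[i])
        raise UnknownEffectError(str(code))

    def network_totals(self, state) -> np.ndarray:
        """Sum of actor statistics over active actors, one entry per effect."""
        out = np.empty(len(self.net_effects))
        A = state.adj
        o, d = state.outdeg, state.indeg
        so, sd = np.sqrt(o), np.sqrt(d)
        for k, comp in enumerate(self._net_compiled):
            code = comp[0]
            if code == 0:
                out[k] = A.sum()
            elif code == 1:
                out[k] = (A * A.T).sum()
            elif code == 2:
                out[k] = ((A.T @ A) * A).sum()
            elif code == 3:
                out[k] = ((A @ A) * A.T).sum()
            elif code == 4:
                out[k] = d @ o
            elif code == 5:
                out[k] = d @ d
            elif code == 6:
                out[k] = so @ A @ so
            elif code == 7:
                out[k] = sd @ A @ sd
            elif code == 8:
                _, vals, rng, sbar = comp
                sim = 1.0 - np.abs(vals[:, None] - vals[None, :]) / rng
                out[k] = (A * (sim - sbar)).sum()
            elif code == 9:
                _, sub, rng, sbar = comp
                z = state.z[sub]
                sim = 1.0 - np.abs(z[:, None] - z[None, :]) / rng
                out[k] = (A * (sim - sbar)).sum()
            elif code == 10:
                out[k] = self.limited_nomination[state.period] @ o
        return out

    def network_delta_matrix(self, state, i: int) -> np.ndarray:
        """(K, n) change in actor i's statistics when toggling the tie i->j.

        Column j holds s_i(after toggling x_ij) - s_i(before); the j = i
        column and inactive columns are meaningless and must be masked by the
        caller.  Computed incrementally; a full-recompute oracle covers this
        in the tests.
        """
        A = state.adj
        n = self.n
        r = A[i]
        o, d = state.outdeg, state.indeg
        sigma = 1.0 - 2.0 * r  # +1 where adding, -1 where removing
        adding = r == 0
        K = len(self._net_compiled)
        out = np.empty((K, n))
        for k, comp in enumerate(self._net_compiled):
            code = comp[0]
            if code == 0:
                out[k] = sigma
            elif code == 1:
                out[k] = sigma * A[:, i]
            elif code == 2:
                out[k] = sigma * (r @ A + A @ r)
            elif code == 3:
                out[k] = sigma * (A @ A[:, i])
            elif code == 4:
                out[k] = sigma * o
            elif code == 5:
                out[k] = sigma * d + adding
            elif code == 6:
                S = r @ np.sqrt(o)
                oi_new = np.sqrt(o[i] + sigma)
                out[k] = oi_new * (S + sigma * np.sqrt(o)) - np.sqrt(o[i]) * S
            elif code == 7:
                rootdi = np.sqrt(d[i])
                out[k] = rootdi * np.where(adding, np.sqrt(d + 1.0), -np.sqrt(d))
            elif code == 8:
                _, vals, rng, sbar = comp
                sim = 1.0 - np.abs(vals[i] - vals) / rng
                out[k] = sigma * (sim - sbar)
            elif code == 9:
                _, sub, rng, sbar = comp
                z = state.z[sub]
                sim = 1.0 - np.abs(z[i] - z) / rng
                out[k] = sigma * (sim - sbar)
            elif code == 10:
                out[k] = sigma * self.limited_nomination[state.period, i]
        return out

    # -- behavior statistics -------------------------------------------------

    def behavior_actor_statistic(self, substance: str, spec_idx: int,
                                 state, i: int) -> float:
        comp = self._beh_compiled[substance][spec_idx]
        code = comp[0]
        z = state.z[substance]
        zt = z[i] - self.model.behavior_means[substance]
        A = state.adj
        if code == 0:
            return float(zt)
        if code == 1:
            return float(zt * zt)
        if code == 2:
            return float(zt * state.indeg[i])
        if code == 3:
            _, rng, sbar = comp
            oi = state.outdeg[i]
            if oi == 0:
                return 0.0
            sim = 1.0 - np.abs(z[i] - z) / rng
            return float((A[i] @ (sim - sbar)) / oi)
        if code == 4:
            return float(zt * comp[1][i])
        if code == 5:
            _, other, wbar = comp
            return float(zt * (state.z[other][i] - wbar))
        if code == 6:
            _, other, _ = comp
            return float(zt * (A[i] @ (state.z[other] >= 1.0)))
        raise UnknownEffectError(str(code))

    def behavior_totals(self, state, substance: str) -> np.ndarray:
        active = state.active
        out = np.empty(len(self._beh_compiled[substance]))
        z = state.z[substance]
        zt = z - self.model.behavior_means[substance]
        A = state.adj
        for k, comp in enumerate(self._beh_compiled[substance]):
            code = comp[0]
            if code == 0:
                out[k] = zt[active].sum()
            elif code == 1:
                out[k] = (zt[active] ** 2).sum()
            elif code == 2:
                out[k] = (zt * state.indeg)[active].sum()
            elif code == 3:
                _, rng, sbar = comp
                sim = 1.0 - np.abs(z[:, None] - z[None, :]) / rng
                per_actor = (A * (sim - sbar)).sum(axis=1)
                oi = state.outdeg
                with np.errstate(invalid="ignore", divide="ignore"):
                    avg = np.where(oi > 0, per_actor / np.maximum(oi, 1), 0.0)
                out[k] = avg[active].sum()
            elif code == 4:
                out[k] = (zt * comp[1])[active].sum()
            elif code == 5:
                _, other, wbar = comp
                out[k] = (zt * (state.z[other] - wbar))[active].sum()
            elif code == 6:
                _, other, _ = comp
                users = (state.z[other] >= 1.0).astype(float)
                out[k] = (zt * (A @ users))[active].sum()
        return out

    def behavior_delta_matrix(self, state, i: int, substance: str) -> np.ndarray:
        """(K, 2) change in actor i's statistics for moves dz = -1 and +1."""
        comps = self._beh_compiled[substance]
        z = state.z[substance]
        zt = z[i] - self.model.behavior_means[substance]
        A = state.adj
        out = np.empty((len(comps), 2))
        for k, comp in enumerate(comps):
            code = comp[0]
            if code == 0:
                out[k] = (-1.0, 1.0)
            elif code == 1:
                out[k] = ((zt - 1) ** 2 - zt ** 2, (zt + 1) ** 2 - zt ** 2)
            elif code == 2:
                di = state.indeg[i]
                out[k] = (-di, di)
            elif code == 3:
                _, rng, sbar = comp
                oi = state.outdeg[i]
                if oi == 0:
                    out[k] = (0.0, 0.0)
                else:
                    base = 1.0 - np.abs(z[i] - z) / rng
                    lo = 1.0 - np.abs(z[i] - 1.0 - z) / rng
                    hi = 1.0 - np.abs(z[i] + 1.0 - z) / rng
                    out[k] = ((A[i] @ (lo - base)) / oi,
                              (A[i] @ (hi - base)) / oi)
            elif code == 4:
                v = comp[1][i]
                out[k] = (-v, v)
            elif code == 5:
                _, other, wbar = comp
                w = state.z[other][i] - wbar
                out[k] = (-w, w)
            elif code == 6:
                _, other, _ = comp
                cnt = A[i] @ (state.z[other] >= 1.0)
                out[k] = (-cnt, cnt)
        return out

    def gated_behavior_deltas(self, state, i: int, substance: str) -> np.ndarray:
        """(K, 3) per-effect statistic changes over moves (-1, 0, +1).

        Creation-phase effects contribute only in the +1 column, endowment
        effects only in the -1 column; evaluation effects in both.
        """
        delta = self.behavior_delta_matrix(state, i, substance)
        phases = self.beh_phases[substance]
        out = np.zeros((delta.shape[0], 3))
        down_ok = phases != 1  # evaluation + endowment
        up_ok = phases != 2    # evaluation + creation
        out[down_ok, 0] = delta[down_ok, 0]
        out[up_ok, 2] = delta[up_ok, 1]
        return out


# ---------------------------------------------------------------------------
# Spec-level convenience operations (thin wrappers used widely in tests)


def network_statistic(name: str, engine: ModelEngine, state, i: int,
                      attribute_ref: str | None = None) -> float:
    """Actor-level network statistic by roster name."""
    for k, e in enumerate(engine.net_effects):
        if e.name == name and (attribute_ref is None
                               or e.attribute_ref == attribute_ref):
            return engine.network_actor_statistic(k, state, i)
    raise UnknownEffectError(f"{name!r} not in compiled model")


def behavior_statistic(name: str, substance: str, engine: ModelEngine,
                       state, i: int, attribute_ref: str | None = None,
                       phase: str | None = None) -> float:
    """Actor-level behavior statistic by roster name."""
    for k, e in enumerate(engine.beh_effects[substance]):
        if e.name == name and (attribute_ref is None
                               or e.attribute_ref == attribute_ref) and (
                phase is None or e.phase == phase):
            return engine.behavior_actor_statistic(substance, k, state, i)
    raise UnknownEffectError(f"{name!r} not in compiled model for {substance}")


def objective(i: int, dependent: str, state, engine: ModelEngine,
              phase_context: str = "evaluation") -> float:
    """Actor i's objective sum(beta_k * s_ik) for one dependent variable.

    ``phase_context`` is ``"increase"`` / ``"decrease"`` for behavior moves
    (gating creation / endowment terms) or ``"evaluation"``.
    """
    if dependent == "network":
        total = 0.0
        for k, e in enumerate(engine.net_effects):
            total += e.beta * engine.network_actor_statistic(k, state, i)
        return total
    sub = dependent.split(":", 1)[1]
    total = 0.0
    for k, e in enumerate(engine.beh_effects[sub]):
        if e.phase == "creation" and phase_context != "increase":
            continue
        if e.phase == "endowment" and phase_context != "decrease":
            continue
        total += e.beta * engine.behavior_actor_statistic(sub, k, state, i)
    return total
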