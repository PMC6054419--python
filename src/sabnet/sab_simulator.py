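"""Forward simulation of the network/behavior co-evolution process.

Between two observation waves the model is a continuous-time Markov chain on
model time [0, 1]: actors receive change opportunities at rate lambda_d per
dependent variable (network, or one substance), and at each opportunity make a
myopic multinomial-logit choice among staying put, toggling one outgoing tie,
or moving one behavior step, with probabilities proportional to
exp(objective difference).

Simulation is *unconditional*: a period ends when the clock reaches 1.0, the
rate parameters absorbing the expected amount of change.  This is also what a
counterfactual forward run needs, where no target wave exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .effects import ModelEngine, ModelSpec


class NoActiveActorsError(RuntimeError):
    pass


@dataclass
class SimState:
    """One evolving network + behavior configuration inside a period."""

    adj: np.ndarray                 # (n, n) float 0/1
    z: dict[str, np.ndarray]        # substance -> (n,) float
    active: np.ndarray              # (n,) bool
    clock: float = 0.0
    period: int = 0
    outdeg: np.ndarray = field(default=None, repr=False)  # type: ignore
    indeg: np.ndarray = field(default=None, repr=False)   # type: ignore

    def __post_init__(self) -> None:
        if self.outdeg is None:
            self.outdeg = self.adj.sum(axis=1)
        if self.indeg is None:
            self.indeg = self.adj.sum(axis=0)

    def copy(self) -> "SimState":
        return SimState(
            adj=self.adj.copy(),
            z={s: v.copy() for s, v in self.z.items()},
            active=self.active.copy(),
            clock=self.clock,
            period=self.period,
            outdeg=self.outdeg.copy(),
            indeg=self.indeg.copy(),
        )

    @classmethod
    def from_panel(cls, panel, wave: int, period: int | None = None) -> "SimState":
        """Observed state at a wave, restricted to the period's active actors."""
        if period is None:
            period = min(wave, panel.n_periods - 1)
        state = cls(
            adj=panel.networks[wave].astype(float),
            z={s: panel.behaviors[s][wave].astype(float)
               for s in panel.behaviors},
            active=panel.active_mask(period),
            period=period,
        )
        restrict_to_active(state)
        return state


def restrict_to_active(state: SimState) -> SimState:
    """Strip ties incident to inactive actors (composition change)."""
    inactive = ~state.active
    if inactive.any():
        state.adj[inactive, :] = 0.0
        state.adj[:, inactive] = 0.0
        state.outdeg = state.adj.sum(axis=1)
        state.indeg = state.adj.sum(axis=0)
    return state


@dataclass
class PeriodRecord:
    """Per-period bookkeeping: event counts and (optionally) score vectors.

    Scores are the derivatives of the simulated trajectory's log-probability
    with respect to the effect coefficients, used by the Method-of-Moments
    estimator's likelihood-ratio derivative estimate.
    """

    n_active: int
    event_counts: dict[str, int]
    scores: dict[str, np.ndarray] | None = None
    n_steps: int = 0


def period_rates(model: ModelSpec, period: int) -> dict[str, float]:
    return {dep: model.rates[dep][period] for dep in model.rates}


def choice_probabilities_network(i: int, state: SimState,
                                 engine: ModelEngine
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities over {keep, toggle tie to each active j != i}.

    Returns ``(p, deltas)`` where ``p`` has length n+1 (index 0 = keep,
    index 1+j = toggle the tie to actor j; invalid options carry 0) and
    ``deltas`` is the (K, n) per-effect statistic-change matrix.
    """
    deltas = engine.network_delta_matrix(state, i)
    u = engine.net_betas @ deltas if len(engine.net_betas) else np.zeros(engine.n)
    valid = state.active.copy()
    valid[i] = False
    u = np.where(valid, u, -np.inf)
    opts = np.concatenate(([0.0], u))
    m = opts.max()
    p = np.exp(opts - m)
    p /= p.sum()
    return p, deltas


def choice_probabilities_behavior(i: int, substance: str, state: SimState,
                                  engine: ModelEngine
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities over moves (-1, 0, +1) for one substance.

    Moves leaving the declared range get probability 0; creation-phase
    effects enter only the +1 option and endowment effects only the -1
    option.  Returns ``(p, gated_deltas)`` with ``gated_deltas`` of shape
    (K, 3).
    """
    gated = engine.gated_behavior_deltas(state, i, substance)
    betas = engine.beh_betas[substance]
    u = betas @ gated if len(betas) else np.zeros(3)
    lo, hi = engine.model.behavior_ranges[substance]
    zi = state.z[substance][i]
    if zi - 1 < lo:
        u[0] = -np.inf
    if zi + 1 > hi:
        u[2] = -np.inf
    m = u.max()
    p = np.exp(u - m)
    p /= p.sum()
    return p, gated


def micro_step(state: SimState, engine: ModelEngine, rates: dict[str, float],
               rng: np.random.Generator, record: PeriodRecord | None = None
               ) -> SimState:
    """One event of the continuous-time chain (mutates ``state``).

    Advances the clock by an exponential holding time with total rate
    n_active * sum(lambda); if the clock passes 1.0 the period is over and no
    choice is applied.  Otherwise one dependent is picked proportional to its
    rate, one active actor uniformly, and one sampled choice applied.
    """
    active_idx = np.flatnonzero(state.active)
    n_active = len(active_idx)
    if n_active == 0:
        raise NoActiveActorsError("no active actors")
    deps = list(rates)
    lam = np.array([rates[d] for d in deps])
    total = n_active * lam.sum()
    if total <= 0:
        state.clock = 1.0
        return state
    state.clock += rng.exponential(1.0 / total)
    if state.clock >= 1.0:
        state.clock = 1.0
        return state

    dep = deps[_sample(lam / lam.sum(), rng)]
    i = int(active_idx[rng.integers(n_active)])
    if record is not None:
        record.event_counts[dep] = record.event_counts.get(dep, 0) + 1
        record.n_steps += 1

    if dep == "network":
        p, deltas = choice_probabilities_network(i, state, engine)
        choice = _sample(p, rng)
        if record is not None and record.scores is not None:
            expect = deltas @ p[1:]
            chosen = deltas[:, choice - 1] if choice > 0 else 0.0
            record.scores["network"] += chosen - expect
        if choice > 0:
            j = choice - 1
            sigma = 1.0 - 2.0 * state.adj[i, j]
            state.adj[i, j] += sigma
            state.outdeg[i] += sigma
            state.indeg[j] += sigma
    else:
        sub = dep.split(":", 1)[1]
        p, gated = choice_probabilities_behavior(i, sub, state, engine)
        choice = _sample(p, rng)
        if record is not None and record.scores is not None:
            record.scores[sub] += gated[:, choice] - gated @ p
        dz = float(choice - 1)
        if dz != 0.0:
            state.z[sub][i] += dz
    return state


def _sample(p: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))


def simulate_period(state: SimState, engine: ModelEngine, period: int,
                    rng: np.random.Generator,
                    rates: dict[str, float] | None = None,
                    collect_scores: bool = False
                    ) -> tuple[SimState, PeriodRecord]:
    """Run micro-steps from a period's start state until model time 1.0.

    The input state is not mutated.  Returns the end-of-period state and a
    :class:`PeriodRecord` with event counts (and score vectors when
    ``collect_scores``).
    """
    state = state.copy()
    state.period = period
    state.clock = 0.0
    if rates is None:
        rates = period_rates(engine.model, period)
    scores = None
    if collect_scores:
        scores = {"network": np.zeros(len(engine.net_effects))}
        for sub in engine.substances:
            scores[sub] = np.zeros(len(engine.beh_effects[sub]))
    record = PeriodRecord(n_active=int(state.active.sum()),
                          event_counts={}, scores=scores)
    while state.clock < 1.0:
        micro_step(state, engine, rates, rng, record)
    return state, record


def simulate_forward(panel, engine: ModelEngine, rng: np.random.Generator,
                     start_wave: int = 0) -> list[SimState]:
    """Chain simulate_period across all remaining periods from an observed
    wave, carrying the simulated state forward and honoring the
    structural-zero schedule (graduates drop out when their period starts)."""
    states = []
    state = SimState.from_panel(panel, start_wave, period=start_wave)
    for period in range(start_wave, panel.n_periods):
        state.active = panel.active_mask(period)
        restrict_to_active(state)
        state, _ = simulate_period(state, engine, period, rng)
        states.append(state)
    return states
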