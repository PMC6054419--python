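"""Method-of-Moments estimation via Robbins-Monro stochastic approximation.

The moment conditions match, for every effect, the expected simulated
statistic at the end of each period (summed over periods) to the statistic of
the observed end-of-period state; for every per-period rate they match the
expected amount of change (tie Hamming distance for the network, sum of
absolute behavior steps per substance) to the observed change.

Estimation runs in three phases:

1. a derivative/scale phase simulating at the starting values to estimate the
   sensitivity matrix D-hat of expected statistics to parameters;
2. Robbins-Monro updates  theta <- theta - a_t * D-hat^-1 (S_sim - s_obs)
   with gains halving per subphase and Polyak averaging at subphase ends;
3. a large simulation set at the final estimate for convergence diagnostics
   (per-parameter t-ratios and the overall maximum convergence ratio, a
   Mahalanobis-type joint criterion) and delta-method standard errors.

D-hat defaults to the score-function (likelihood-ratio) estimator
cov(S, score); a common-random-number finite-difference variant is available
as ``derivative_method="finite_difference"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effects import ModelEngine, ModelSpec, center_model
from .sab_simulator import SimState, simulate_period

#: Convergence thresholds for fully converged fits (per-parameter deviation
#: t-ratio; overall maximum convergence ratio).
TCONV_THRESHOLD = 0.10
OVERALL_THRESHOLD = 0.25


class EstimationError(RuntimeError):
    pass


class DivergedError(EstimationError):
    def __init__(self, message: str, trace: list | None = None) -> None:
        super().__init__(message)
        self.trace = trace or []


class CollinearityError(EstimationError):
    """The derivative matrix is (near-)singular: effects are not separately
    identifiable — e.g. creation and endowment versions of the same term
    estimated jointly."""


class UndefinedDiagnosticError(EstimationError):
    """A simulated statistic has zero variance; t-ratios are undefined."""


@dataclass
class MomSettings:
    """Phase lengths and gains. Defaults are the full-convergence preset;
    :meth:`reduced` is the desk-scale preset used throughout the analyses."""

    phase1_n: int = 40
    phase2_subphases: int = 8
    phase2_iters: int = 250
    phase3_n: int = 1000
    gain: float = 0.3
    derivative_method: str = "score"  # or "finite_difference"
    fd_epsilon: float = 0.2
    seed: int | None = None
    max_step: float = 0.5
    init: str = "heuristic"  # or "model": start from the passed-in values
    #: re-estimate the derivative matrix at the start of each subphase (the
    #: matrix at the crude starting point is a poor global preconditioner)
    refresh_derivative: bool = True
    #: weight on diag(D) in the phase-2 preconditioner: 1.0 updates each
    #: parameter against its own deviation only, which is robust when D is
    #: estimated from few simulations; 0.0 uses the full matrix
    diagonalize: float = 1.0
    #: floor on the preconditioner diagonal, as a fraction of its median
    diag_floor: float = 0.5

    @classmethod
    def reduced(cls, seed: int | None = None) -> "MomSettings":
        return cls(phase1_n=25, phase2_subphases=4, phase2_iters=50,
                   phase3_n=120, seed=seed)


class ParameterIndex:
    """Joint layout of the parameter/statistic vector: effects, then rates."""

    def __init__(self, model: ModelSpec) -> None:
        self.model = model
        self.n_effects = len(model.effects)
        self.net_pos = np.array(
            [k for k, e in enumerate(model.effects) if e.dependent == "network"],
            dtype=int)
        self.beh_pos = {
            sub: np.array([k for k, e in enumerate(model.effects)
                           if e.dependent == f"behavior:{sub}"], dtype=int)
            for sub in model.substances}
        self.rate_keys = [(dep, m) for dep in model.rates
                          for m in range(model.n_periods)]
        self.rate_pos = {key: self.n_effects + j
                         for j, key in enumerate(self.rate_keys)}
        self.p = self.n_effects + len(self.rate_keys)
        self.labels = ([e.label() for e in model.effects]
                       + [f"rate | {dep} | period {m + 1}"
                          for dep, m in self.rate_keys])

    def theta_from_model(self, model: ModelSpec) -> np.ndarray:
        theta = np.empty(self.p)
        theta[:self.n_effects] = model.betas()
        for (dep, m), pos in self.rate_pos.items():
            theta[pos] = model.rates[dep][m]
        return theta

    def apply_theta(self, model: ModelSpec, theta: np.ndarray,
                    engine: ModelEngine | None = None) -> None:
        model.set_betas(theta[:self.n_effects])
        for (dep, m), pos in self.rate_pos.items():
            model.rates[dep][m] = float(theta[pos])
        if engine is not None:
            engine.sync_betas()


@dataclass
class TargetVector:
    values: np.ndarray
    labels: list[str]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EstimationResult:
    """Fitted coefficients, standard errors and convergence diagnostics."""

    model: ModelSpec
    labels: list[str]
    theta: np.ndarray
    se: np.ndarray
    tconv: np.ndarray
    overall_max_convergence_ratio: float
    targets: np.ndarray
    iterations: list[dict] = field(default_factory=list)
    settings: MomSettings | None = None

    @property
    def n_effects(self) -> int:
        return len(self.model.effects)

    def beta(self, dependent: str, name: str, attribute_ref: str | None = None,
             phase: str = "evaluation") -> float:
        for k, e in enumerate(self.model.effects):
            if (e.dependent, e.name, e.phase) == (dependent, name, phase) and (
                    attribute_ref is None or e.attribute_ref == attribute_ref):
                return float(self.theta[k])
        raise KeyError((dependent, name, attribute_ref, phase))

    def se_of(self, dependent: str, name: str,
              attribute_ref: str | None = None,
              phase: str = "evaluation") -> float:
        for k, e in enumerate(self.model.effects):
            if (e.dependent, e.name, e.phase) == (dependent, name, phase) and (
                    attribute_ref is None or e.attribute_ref == attribute_ref):
                return float(self.se[k])
        raise KeyError((dependent, name, attribute_ref, phase))

    @property
    def converged(self) -> bool:
        return bool(np.all(np.abs(self.tconv) < TCONV_THRESHOLD)
                    and self.overall_max_convergence_ratio < OVERALL_THRESHOLD)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.labels,
            "beta": self.theta,
            "se": self.se,
            "tconv": self.tconv,
        })


# ---------------------------------------------------------------------------
# Targets and chain simulation


def _observed_end_state(panel, period: int) -> SimState:
    state = SimState.from_panel(panel, period + 1, period=period)
    state.period = period
    return state


def _accumulate_totals(engine: ModelEngine, index: ParameterIndex,
                       state: SimState, out: np.ndarray) -> None:
    if len(index.net_pos):
        out[index.net_pos] += engine.network_totals(state)
    for sub in engine.substances:
        pos = index.beh_pos[sub]
        if len(pos):
            out[pos] += engine.behavior_totals(state, sub)


def _distances(start: SimState, end: SimState, active: np.ndarray,
               substances) -> dict[str, float]:
    out = {"network": float(np.abs(end.adj - start.adj).sum())}
    for sub in substances:
        out[f"behavior:{sub}"] = float(
            np.abs(end.z[sub] - start.z[sub])[active].sum())
    return out


def target_statistics(panel, model: ModelSpec,
                      index: ParameterIndex | None = None,
                      engine: ModelEngine | None = None) -> TargetVector:
    """Observed moment targets: end-of-period statistics plus change counts."""
    model = center_model(model, panel)
    if index is None:
        index = ParameterIndex(model)
    if engine is None:
        engine = ModelEngine(model, panel.covariates, panel.limited_nomination)
    values = np.zeros(index.p)
    for m in range(panel.n_periods):
        start = SimState.from_panel(panel, m, period=m)
        end = _observed_end_state(panel, m)
        _accumulate_totals(engine, index, end, values)
        dists = _distances(start, end, panel.active_mask(m), model.substances)
        for dep, dist in dists.items():
            if (dep, m) in index.rate_pos:
                values[index.rate_pos[(dep, m)]] = dist
    return TargetVector(values=values, labels=index.labels)


def simulate_chain(panel, engine: ModelEngine, index: ParameterIndex,
                   rng: np.random.Generator, collect_scores: bool = False
                   ) -> tuple[np.ndarray, np.ndarray | None]:
    """One full simulated panel chain; returns (statistics, scores)."""
    stats = np.zeros(index.p)
    scores = np.zeros(index.p) if collect_scores else None
    model = engine.model
    for m in range(panel.n_periods):
        start = SimState.from_panel(panel, m, period=m)
        end, rec = simulate_period(start, engine, m, rng,
                                   collect_scores=collect_scores)
        _accumulate_totals(engine, index, end, stats)
        dists = _distances(start, end, start.active, model.substances)
        for dep, dist in dists.items():
            if (dep, m) in index.rate_pos:
                stats[index.rate_pos[(dep, m)]] = dist
        if collect_scores:
            if len(index.net_pos):
                scores[index.net_pos] += rec.scores["network"]
            for sub in engine.substances:
                pos = index.beh_pos[sub]
                if len(pos):
                    scores[pos] += rec.scores[sub]
            for dep in model.rates:
                key = (dep, m)
                if key in index.rate_pos:
                    lam = model.rates[dep][m]
                    n_events = rec.event_counts.get(dep, 0)
                    scores[index.rate_pos[key]] = (
                        n_events / lam - rec.n_active)
    return stats, scores


def _simulate_batch(panel, engine, index, rng, n, collect_scores):
    stats = np.empty((n, index.p))
    scores = np.empty((n, index.p)) if collect_scores else None
    for r in range(n):
        s, sc = simulate_chain(panel, engine, index, rng, collect_scores)
        stats[r] = s
        if collect_scores:
            scores[r] = sc
    return stats, scores


def _cross_cov(stats: np.ndarray, scores: np.ndarray) -> np.ndarray:
    sc = stats - stats.mean(axis=0)
    zc = scores - scores.mean(axis=0)
    return sc.T @ zc / (len(stats) - 1)


def _derivative_fd(panel, model, index, theta, settings, seed):
    """Finite-difference derivative of expected statistics (common random
    numbers across perturbations)."""
    eps = settings.fd_epsilon
    n = max(10, settings.phase1_n // 2)

    def mean_stats(th):
        work = model.copy()
        engine = ModelEngine(work, panel.covariates, panel.limited_nomination)
        index.apply_theta(work, th, engine)
        engine.model = work
        engine.sync_betas()
        rng = np.random.default_rng(seed)
        stats, _ = _simulate_batch(panel, engine, index, rng, n, False)
        return stats.mean(axis=0)

    base = mean_stats(theta)
    D = np.empty((index.p, index.p))
    for k in range(index.p):
        th = theta.copy()
        th[k] += eps
        D[:, k] = (mean_stats(th) - base) / eps
    return D


def _check_conditioning(D: np.ndarray) -> None:
    # normalize rows/columns so statistic scale does not masquerade as
    # collinearity; dependent columns stay dependent under this scaling
    rn = np.linalg.norm(D, axis=1)
    cn = np.linalg.norm(D, axis=0)
    if np.any(rn == 0) or np.any(cn == 0):
        raise CollinearityError(
            "a statistic or score has zero sensitivity; the effect does not "
            "vary on these data")
    Ds = D / np.sqrt(rn)[:, None] / np.sqrt(cn)[None, :]
    sv = np.linalg.svd(Ds, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > 1e8:
        raise CollinearityError(
            "derivative matrix is near-singular; the requested effects are "
            "not separately identifiable (e.g. joint creation + endowment "
            "terms) — estimate them in separate runs")


def _phase2_preconditioner(D: np.ndarray, diagonalize: float,
                           diag_floor: float = 0.5,
                           n_effects: int | None = None) -> np.ndarray:
    """Inverse of the (partially) diagonalized derivative matrix.

    Effect-coefficient diagonal entries are floored at ``diag_floor`` times
    their block median: each statistic responds positively to its own
    parameter, so small or nonpositive estimates are sampling noise around a
    nearly flat direction, and a generous floor keeps the corresponding
    updates small — otherwise a weakly identified coefficient random-walks
    over a long gain schedule.  Rate parameters are always identified (the
    change statistic responds directly to its rate), so their block only
    guards against nonpositive noise."""
    diag = np.diag(D).copy()
    if n_effects is None:
        n_effects = len(diag)
    eff, rate = diag[:n_effects], diag[n_effects:]
    if len(eff):
        eff_floor = diag_floor * float(np.median(np.abs(eff))) or 1e-6
        diag[:n_effects] = np.maximum(eff, eff_floor)
    if len(rate):
        rate_floor = 0.05 * float(np.median(np.abs(rate))) or 1e-6
        diag[n_effects:] = np.maximum(rate, rate_floor)
    if diagonalize >= 1.0:
        return np.diag(1.0 / diag)
    M = diagonalize * np.diag(diag) + (1.0 - diagonalize) * D
    _check_conditioning(M)
    return np.linalg.inv(M)


def _initial_theta(panel, model: ModelSpec, index: ParameterIndex,
                   targets: TargetVector) -> np.ndarray:
    """Heuristic starting point: coefficients at zero except an out-degree
    term matched to the observed density; rates scaled from observed change."""
    theta = np.zeros(index.p)
    for k, e in enumerate(model.effects):
        if e.dependent == "network" and e.name == "out-degree":
            dens = []
            for w in range(panel.n_waves):
                present = ~panel.structural_zero[w]
                n_act = present.sum()
                dens.append(panel.networks[w][np.ix_(present, present)].sum()
                            / (n_act * (n_act - 1)))
            d = float(np.clip(np.mean(dens), 1e-4, 0.5))
            theta[k] = math.log(d / (1 - d))
    for (dep, m), pos in index.rate_pos.items():
        n_active = int(panel.active_mask(m).sum())
        theta[pos] = max(0.5, 1.7 * targets.values[pos] / max(n_active, 1))
    return theta


def estimate_mom(panel, model: ModelSpec,
                 settings: MomSettings | None = None) -> EstimationResult:
    """Fit a SAB model to an observed panel by simulated Method of Moments.

    The passed model supplies the effect roster and behavior ranges; its
    coefficient values are used as the starting point only when
    ``settings.init == "model"``.  Deterministic given ``settings.seed``.
    """
    settings = settings or MomSettings()
    model = center_model(model, panel)
    model.validate()
    index = ParameterIndex(model)
    targets = target_statistics(panel, model, index=index)

    work = model.copy()
    engine = ModelEngine(work, panel.covariates, panel.limited_nomination)
    if settings.init == "model":
        theta = index.theta_from_model(work)
    else:
        theta = _initial_theta(panel, work, index, targets)
    index.apply_theta(work, theta, engine)

    rng = np.random.default_rng(settings.seed)
    log: list[dict] = []

    if (settings.derivative_method == "score"
            and settings.phase1_n <= index.p):
        raise ValueError(
            f"phase1_n={settings.phase1_n} must exceed the number of "
            f"parameters ({index.p}) for the score-based derivative")

    # Phase 1: derivative estimation at the starting point.
    if settings.derivative_method == "finite_difference":
        sub_seed = int(rng.integers(2 ** 31))
        D = _derivative_fd(panel, work, index, theta, settings, sub_seed)
    else:
        stats1, scores1 = _simulate_batch(
            panel, engine, index, rng, settings.phase1_n, True)
        D = _cross_cov(stats1, scores1)
    # specification-level collinearity (e.g. creation + endowment phases of
    # the same term share a statistic) shows up here as exactly dependent
    # rows, whatever the sample size
    _check_conditioning(D)
    D_inv = _phase2_preconditioner(D, settings.diagonalize,
                                   settings.diag_floor, index.n_effects)
    log.append({"phase": 1, "n": settings.phase1_n,
                "theta": theta.copy()})

    # Phase 2: Robbins-Monro with halving gains and Polyak averaging.
    for sub in range(settings.phase2_subphases):
        a = settings.gain / (2 ** sub)
        if sub > 0 and settings.refresh_derivative and (
                settings.derivative_method != "finite_difference"):
            stats_r, scores_r = _simulate_batch(
                panel, engine, index, rng, settings.phase1_n, True)
            D = _cross_cov(stats_r, scores_r)
            D_inv = _phase2_preconditioner(D, settings.diagonalize,
                                           settings.diag_floor,
                                           index.n_effects)
        trace = []
        for _ in range(settings.phase2_iters):
            stats, _ = simulate_chain(panel, engine, index, rng, False)
            dev = stats - targets.values
            step = np.clip(a * (D_inv @ dev),
                           -settings.max_step, settings.max_step)
            theta = theta - step
            if not np.all(np.isfinite(theta)):
                raise DivergedError(
                    "non-finite parameter update in phase 2", trace=log)
            # bound the search: rates positive, coefficients within a range
            # where choices stay stochastic (a fit parked at the bound is a
            # non-convergent fit, reported as such by its t-ratios)
            theta[:index.n_effects] = np.clip(theta[:index.n_effects],
                                              -10.0, 10.0)
            theta[index.n_effects:] = np.clip(theta[index.n_effects:],
                                              0.05, 30.0)
            index.apply_theta(work, theta, engine)
            trace.append(theta.copy())
        theta = np.mean(trace, axis=0)
        index.apply_theta(work, theta, engine)
        log.append({"phase": 2, "subphase": sub, "gain": a,
                    "n": settings.phase2_iters, "theta": theta.copy()})

    # Phase 3: diagnostics and standard errors at the final estimate.
    stats3, scores3 = _simulate_batch(
        panel, engine, index, rng, settings.phase3_n, True)
    tconv, overall = convergence_diagnostics(stats3, targets.values)
    D3 = _cross_cov(stats3, scores3)
    try:
        _check_conditioning(D3)
        se = standard_errors(stats3, D3)
        se_method = "delta"
    except CollinearityError:
        # the derivative matrix degenerated at the final estimate (typical
        # of a non-convergent fit in a weakly identified direction); fall
        # back to the stable diagonal approximation, which reports honestly
        # large uncertainties along flat directions
        diag = np.abs(np.diag(D3))
        diag = np.maximum(diag, 0.02 * float(np.median(diag)) or 1e-8)
        se = stats3.std(axis=0, ddof=1) / diag
        se_method = "diagonal"
    log.append({"phase": 3, "n": settings.phase3_n, "theta": theta.copy(),
                "se_method": se_method})

    return EstimationResult(
        model=work,
        labels=index.labels,
        theta=theta,
        se=se,
        tconv=tconv,
        overall_max_convergence_ratio=overall,
        targets=targets.values,
        iterations=log,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Diagnostics


def convergence_diagnostics(phase3_stats: np.ndarray, targets: np.ndarray
                            ) -> tuple[np.ndarray, float]:
    """Per-parameter deviation t-ratios and the overall convergence ratio.

    ``tconv_k = mean(dev_k) / sd(dev_k)`` (sd with ddof=1); the overall ratio
    is the Mahalanobis norm sqrt(dbar' Sigma^-1 dbar) of the mean deviations
    in the metric of their covariance.
    """
    stats = np.asarray(phase3_stats, dtype=float)
    if stats.ndim != 2 or len(stats) < 2:
        raise UndefinedDiagnosticError("need at least 2 phase-3 simulations")
    dev = stats - np.asarray(targets, dtype=float)
    sd = dev.std(axis=0, ddof=1)
    if np.any(sd == 0):
        k = int(np.flatnonzero(sd == 0)[0])
        raise UndefinedDiagnosticError(
            f"simulated statistic {k} has zero variance")
    dbar = dev.mean(axis=0)
    tconv = dbar / sd
    sigma = np.cov(dev, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    overall = float(np.sqrt(dbar @ np.linalg.pinv(sigma) @ dbar))
    return tconv, overall


def standard_errors(phase3_stats: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    """Delta-method standard errors sqrt(diag(D^-1 Sigma D^-T))."""
    stats = np.asarray(phase3_stats, dtype=float)
    sigma = np.atleast_2d(np.cov(stats, rowvar=False, ddof=1))
    dhat = np.atleast_2d(np.asarray(dhat, dtype=float))
    try:
        d_inv = np.linalg.inv(dhat)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("singular derivative matrix") from exc
    cov_theta = d_inv @ sigma @ d_inv.T
    return np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))


def score_type_test(panel, fitted_model: ModelSpec, candidate_effect,
                    n_sims: int = 100, seed: int | None = None) -> float:
    """Forward-selection score-type test for one candidate effect.

    Simulates at the fitted coefficients with the candidate's coefficient at
    zero and returns the standardized deviation of the candidate's target
    statistic (mean deviation / sd); large |values| argue for inclusion, and
    the sign matches the sign of the omitted coefficient.
    """
    if any(e.key() == candidate_effect.key() for e in fitted_model.effects):
        raise ValueError("candidate effect already in the fitted model")
    model = fitted_model.copy()
    cand = replace(candidate_effect, beta=0.0)
    model.effects = model.effects + [cand]
    model = center_model(model, panel)
    index = ParameterIndex(model)
    targets = target_statistics(panel, model, index=index)
    engine = ModelEngine(model, panel.covariates, panel.limited_nomination)
    rng = np.random.default_rng(seed)
    stats, _ = _simulate_batch(panel, engine, index, rng, n_sims, False)
    k = len(model.effects) - 1
    dev = stats[:, k] - targets.values[k]
    sd = dev.std(ddof=1)
    if sd == 0:
        raise UndefinedDiagnosticError("candidate statistic has zero variance")
    return float(dev.mean() / sd)


def panel_typicality(panel, model: ModelSpec, n_sims: int = 100,
                     seed: int | None = None) -> float:
    """Largest |t-ratio| of the observed statistics against their expectation
    under the model itself (simulated at the given coefficients).

    For synthetic panels with known truth this screens atypical draws: a
    realization sitting several sd from its own generating expectation has no
    nearby moment root, and estimation on it cannot converge.  Values below
    about 2 mark a typical panel."""
    model = center_model(model, panel)
    index = ParameterIndex(model)
    targets = target_statistics(panel, model, index=index)
    engine = ModelEngine(model, panel.covariates, panel.limited_nomination)
    rng = np.random.default_rng(seed)
    stats, _ = _simulate_batch(panel, engine, index, rng, n_sims, False)
    dev = stats - targets.values
    sd = dev.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise UndefinedDiagnosticError("a statistic has zero variance")
    return float(np.max(np.abs(dev.mean(axis=0) / sd)))


def odds_multiplier(beta: float) -> tuple[float, float]:
    """Odds interpretation of a coefficient: (exp(beta), percent change).

    The multiplier is rounded to 2 decimals and the percent change to the
    nearest integer, the precision used when quoting such effects.
    """
    mult = math.exp(beta)
    return round(mult, 2), round(100.0 * (mult - 1.0))
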