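# Methods

## The model

`sabnet` implements a stochastic actor-based (SAB) model of the co-evolution
of a directed friendship network and up to three ordinal substance-use
behaviors (smoking coded 0–3, drinking 0–4, marijuana 0–2). Between two
observation waves the system is a continuous-time Markov chain on model time
[0, 1]. Each dependent variable d (the network, or one substance) has a
per-period rate parameter λ_d: every actor receives change opportunities for
d as a Poisson process with intensity λ_d, so λ_d is the expected number of
opportunities per actor per period. At a network opportunity the actor
either keeps the current state or toggles one outgoing tie; at a behavior
opportunity the actor moves one category up, down, or stays. The choice is
myopic multinomial logit:

    P(option) ∝ exp( f_i(option) − f_i(current) ),   f_i = Σ_k β_k s_ik,

where the s_ik are named effect statistics. Network effects cover degree
(out-degree/density), reciprocity, transitive triplets, 3-cycles, raw-degree
popularity (out and in), square-root-degree assortativity (out-out and
in-in), covariate and behavior similarity (homophilous selection), and a
limited-nomination ego term driven by the per-transition {−1, 0, +1}
instrument-change codes. Behavior effects cover linear and quadratic shape,
in-degree, peer influence (average centered similarity to nominated friends,
zero for isolates), covariate main effects, cross-substance main effects
("other behavior"), and the count of friends using another substance.

Conventions: behaviors and covariates enter mean-centered (grand mean over
actors and waves); similarity kernels sim(v_i, v_j) = 1 − |v_i − v_j|/range
are centered by the observed mean pairwise similarity. The centering
constants live on the `ModelSpec`, so a generating model can be reused
verbatim in estimation; `center_model` fills any that are missing from the
observed panel. Centering only shifts intercept-like (shape/density) terms;
it cancels in all choice-probability differences.

### Creation and endowment

Behavior effects carry a phase. Evaluation effects act on every move;
creation effects enter only the objective difference of upward moves
(initiation), endowment effects only downward moves (cessation). Setting a
creation β and an endowment β of the same statistic equal to an evaluation β
reproduces the evaluation model's choice probabilities exactly (tested).
Because all phases of one statistic share the same target statistic, a model
containing both phases of the same term is exactly collinear in the moment
equations; such specifications are rejected with a `CollinearityError` and
must be estimated as separate runs.

### Composition change

Structural zeros are a wave-level mask: actors absent at a wave (graduates)
can neither send nor receive ties there. An actor is active in a period iff
present at both endpoint waves; forward runs strip graduates' ties when their
last period starts. Descriptive and target statistics exclude
structural-zero actors at zeroed waves.

## Estimation: simulated Method of Moments

Moment conditions, per period m with start state x(t_m):

* for every effect k: E[ s_k(X(t_{m+1})) ] summed over periods equals the
  statistic of the observed end-of-period states;
* for every rate λ_{d,m}: the expected amount of change (tie Hamming
  distance; Σ_i |Δz_i| per substance, over active actors) equals the
  observed change.

Simulation is unconditional: a period ends at model time 1.0 and the rates
absorb the expected change volume. This is also what counterfactual forward
runs need, where no target wave exists.

The solver is Robbins–Monro stochastic approximation in three phases:

1. **Phase 1** simulates `phase1_n` chains at the starting point (β = 0
   except the out-degree term, initialized at the logit of the observed
   density; rates at 1.7 × observed change per active actor) and estimates
   the sensitivity matrix D = ∂E[S]/∂θ by the score-function
   (likelihood-ratio) identity D = cov(S, score). The per-choice score is
   s(chosen) − E_p[s(options)]; the rate score is n_events/λ − n_active.
2. **Phase 2** iterates θ ← θ − a·D̃⁻¹(S_sim − s_obs) with gains halving
   each subphase and the iterate average (Polyak) taken at subphase ends.
   D̃ is the *diagonal* of D by default, refreshed at each subphase start: a
   full p×p cross-covariance estimated from tens of chains is noise-dominated
   and its inverse scrambles update directions (we observed divergence with
   partial diagonalization at these simulation counts), while the diagonal is
   always the right sign and scale. The cost is slower convergence along
   correlated moment directions, which the long default schedule (8 subphases
   × 250 iterations) absorbs. Effect-coefficient diagonal entries are floored
   at half their block median — a nearly flat direction otherwise turns the
   update into a random walk that drifts over a long schedule — while rate
   entries, always well identified, are floored only against nonpositive
   noise. Steps are clipped at ±0.5 per parameter, coefficients bounded to
   |β| ≤ 10 and rates to [0.05, 30]; a fit parked at a bound is a
   non-convergent fit and says so through its t-ratios.
3. **Phase 3** simulates `phase3_n` chains at the final estimate for
   diagnostics: per-parameter deviation t-ratios tconv_k = mean(dev_k)/sd(dev_k),
   the overall maximum convergence ratio sqrt(d̄ᵀ Σ̂⁻¹ d̄) (the largest
   t-ratio over linear combinations of targets), and delta-method standard
   errors sqrt(diag(D⁻¹ Σ̂ D⁻ᵀ)) with D re-estimated from the phase-3
   scores. Specification-level collinearity (joint creation+endowment
   phases of one term share a target statistic) is rejected at phase 1 with
   a `CollinearityError`; if the phase-3 matrix instead degenerates
   numerically — the signature of a non-convergent fit in a weakly
   identified direction — standard errors fall back to the stable diagonal
   approximation, which reports honestly large uncertainty along flat
   directions.

   Finite-sample caveat: roughly one synthetic 50-actor panel in five is an
   extreme enough realization in the weakly identified behavior subspace
   (joint 2σ+ deviations of shape/influence/cross-effect moments) that the
   moment equations have no interior root; the fit then parks at the bounds
   or leaves those deviations open, and the t-ratios report it. This is the
   expected behavior of this estimator class on small panels, not an error
   state.

A common-random-number finite-difference derivative
(`derivative_method="finite_difference"`) is available and is cross-checked
against the score estimator in the tests; it is not the default because it
costs (p+1)× the simulations per derivative refresh.

Convergence is judged by tconv < 0.10 per parameter and overall ratio < 0.25
at the full schedule. The desk-scale preset `MomSettings.reduced()`
(4 subphases × 50 iterations, 120 phase-3 chains) is used for replication
experiments; at that scale the relaxed thresholds 0.15/0.30 apply, since the
overall ratio has a pure-noise floor of about sqrt(p/phase3_n) even at the
exact root.

The score-type forward-selection test simulates at the fitted values with a
candidate effect's coefficient at zero and returns the standardized deviation
of the candidate's target statistic; its sign matches the sign of the omitted
coefficient.

For synthetic-recovery work, `panel_typicality` screens generated panels
before fitting: it simulates chains at the *generating* coefficients and
returns the largest |t-ratio| of the observed statistics against their
own-model expectation. A panel sitting more than ~2 sd from its generating
expectation is an atypical draw whose moment equations have no nearby root;
fitting it produces the honest non-convergence described above, so recovery
demonstrations skip such draws (the screen uses only the generator, never
the fit).

Odds interpretations are reported as exp(β) rounded to 2 decimals and
100·(exp(β)−1) rounded to the nearest integer.

## Wave-1 marijuana reconstruction

Marijuana items exist only from the second wave onward. The wave-1 category
is rebuilt from four retrospective items (onset age H1TO30, age at wave 1
S1, lifetime count H1TO31, past-30-day count H1TO32): never-triers and
onset-after-wave-1 respondents are certain zeros; a zero lifetime/past-month
difference is treated as a reporting artifact (zero); otherwise the monthly
average m = (H1TO31 − H1TO32)/5 maps m < 1 → 0, 1 ≤ m ≤ 10 → 1 (light),
m > 10 → 2 (heavy). Boundary reading: exactly 1 and exactly 10 are light
("between 1 and 10" inclusive; "above 10" strict) — the source text does not
disambiguate, so this is fixed here and tested. Records reaching the count
branches with m ≥ 1 are flagged uncertain; the sensitivity analysis re-draws
them uniformly from {light, heavy} with a seeded generator.

## Counterfactual experiment

A scenario names a coefficient group to zero: `mtos`/`mtod`/`mtosd`
(marijuana main effect in the smoking/drinking/both equations), `infs`/
`infd`/`infm` (within-substance peer influence), `selm`/`selall` (behavior
similarity selection), `all` (the union), `none` (intact model). All phases
of a matched effect are zeroed; rates are reused, not re-estimated. Each
replicate chains period simulations from the wave-1 state through both
periods (graduates leave on schedule); the summary is the per-substance
category distribution among finally-active actors, mean ± Monte Carlo sd
over replicates.

## Synthetic schools

Real panels of this kind are restricted-access, so the generator emulates
their structure: grades 10–12 (37/33/29%), 47.5% female, parental education
on 1–4, psychosocial scores drawn normal at the reported means/sds
(depressive symptoms 0.14 ± 0.53, parental support −0.05 ± 0.30, parental
monitoring −0.01 ± 0.12); wave-1 behavior categories at suburban-school
marginals (68.6/17.5/4.9/9.0% smoking, etc.); a network grown sequentially
with grade (2.0) and gender (0.7) log-weight homophily, a reciprocity bonus
(1.5), mean out-degree 2.7 capped at 10; top-grade graduation before wave 3;
~3.5% limited-nomination onset per transition. Waves 2 and 3 come from the
forward simulator under a known model, so recovery experiments have exact
ground truth.

Two study-condition models are fixed once:

* `recovery_model` (network + smoking + marijuana): out-degree −2.2,
  reciprocity 1.6, transitive triplets 0.4, 3-cycles 0 (a deliberate null
  for calibration checks), smoking-similarity selection 0.6; smoking linear
  −2.0, quadratic 0.7, peer influence 1.5, marijuana→smoking 0.4; marijuana
  linear −2.0, quadratic 1.0. Rates 4/3/2.5 per period. Shape magnitudes
  are those typical for such ordinal scales and keep the category
  distributions roughly stationary — non-stationary drift toward the scale
  floor destroys the identification of shape and influence terms at
  school sizes of 50.
* `counterfactual_model` (all three substances) additionally holds a mixed,
  high-use-school profile (≈48% never-smokers) stationary, with
  marijuana→smoking/drinking cross effects of 0.8 and peer influences
  0.8/0.6/1.2, so the zero-out scenarios have users to act on.

Experiments run at school size 50 and 10–20 replications; these sizes were
chosen as the package's desk-scale defaults, with the real-school sizes
available through `PanelConfig`.

What the generator does **not** emulate: survey nonresponse and missing-data
imputation (synthetic panels are complete; the validator only flags
missingness-like violations), covariate measurement models (scores are drawn
directly, not built from item-level factor analyses), drinking's
12-month/30-day item crosswalk (a single 0–4 scale throughout), exogenous
covariate dynamics, and a hard 5+5 nomination cap (degrees are governed by
the density and limited-nomination terms instead; the cap applies only to
the wave-1 generator). Passing tests therefore show that the machinery is
correct and calibrated under the model's own assumptions — not that the
model fits any particular real school.

## Numerical choices and degenerate inputs

* Choice probabilities use max-subtracted exponentials; out-of-range
  behavior moves get probability exactly 0.
* Incremental statistic deltas power the simulator; a full-recompute oracle
  covers every effect in the tests.
* Collinearity is detected on a row/column-normalized derivative matrix
  (scaled condition number > 1e8), so statistic scale does not masquerade as
  dependence.
* Diagnostics with a zero-variance simulated statistic raise an
  `UndefinedDiagnosticError` rather than returning infinities; empty
  networks or two-path-free graphs make the descriptive indices raise an
  undefined-statistic error.
* All randomness flows through a single `numpy` Generator per run; every
  stage is bit-reproducible given its seed.

## Known limitations

* Estimation is unconditional MoM only (no conditioning on observed change
  counts, no ML/Bayesian alternatives).
* The diagonal phase-2 preconditioner trades speed for robustness; badly
  collinear effect pairs (e.g. influence with shape terms on small, drifting
  panels) converge slowly and show honest, large standard errors.
* The behavior-similarity selection effect uses the total (sum) similarity
  form; the friends'-average influence variant is not in the default roster.
* Time heterogeneity across periods is not tested, and goodness-of-fit
  auxiliary statistics are out of scope.
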