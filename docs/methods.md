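# Methods

This note records the models, the generator's assumptions, the numerical
choices, and the design decisions behind `rbdkit`, in the spirit of a
statistical software vignette.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Task and behavioral model

The simulated task is the standard two-block Probabilistic Reward Task:
200 trials split into two 100-trial blocks, two stimuli presented
equiprobably (presentation frequencies are not part of the published task
description; 50/50 is the conventional choice), correct identifications
rewarded 20&cent; on an asymmetric 3:1 schedule.  The default reward
targets are 30 rich and 10 lean rewards per block — the convention of the
task's methodological lineage; other variants (e.g. 40:13) are reachable
through `ScheduleConfig`.  The controlled scheduler pre-designates
reward-carrying presentations and holds an owed reward until the next
correct response to the same stimulus, so delivered rewards never exceed
targets and are never given for errors.

Agents are equal-variance Gaussian signal-detection observers.  Evidence
on rich trials is N(+d'/2, 1), on lean trials N(-d'/2, 1); the agent
responds "rich" when evidence exceeds its criterion.  Sign convention:
criteria below zero favor the rich response.  Learning is expressed as a
single block-to-block criterion shift — block 2's criterion is

    c2 = c_start + engagement * (c_opt - c_start)

with `engagement` in [0, 1] and `c_opt` the ideal-observer criterion for
the block payoff.  All published statistics in this design are
block-level, so trial-by-trial criterion updating is out of scope; the
engagement parameter is exactly the latent construct the downstream
classifier tries to recover.  A lapse rate mixes in uniform random
responses.

## Disengagement score

The score embeds the observer in the task economics.  For payoff
structure with stimulus base rates P(s) and expected cents V(s) per
correct response,

    beta* = [P(lean) V(lean)] / [P(rich) V(rich)],   c* = ln(beta*) / d'

maximizes expected value per trial, and

    EV(c) = P(rich) Phi(d'/2 - c) V(rich) + P(lean) Phi(c + d'/2) V(lean) - effort

is exact Gaussian-tail arithmetic (no simulation).  The default score,
method tag `ev_shortfall`, is `EV(c*; d'_hat) - EV(c_hat; d'_hat)` in
cents per trial, with `(d'_hat, c_hat)` estimated from the block's
hit/false-alarm rates under the same all-or-none 0.5 zero-cell
correction as the classical measures.  Properties (all verified by
oracle tests): nonnegative; zero iff `c_hat = c*`; strictly increasing
in `|c_hat - c*|`; invariant to relabeling rich and lean (with the
payoff relabeled accordingly); unchanged by rescaling the reward
magnitude at the optimum (only the gap scales).

Functional forms are pluggable: `register_method(tag, fn)` installs an
alternative score behind the identical interface, and every output row
carries its method tag so scores from different forms are never mixed.
The effort-cost parameter defaults to zero in scoring — it cancels in EV
differences — but is retained because the cost/benefit framing treats
effort as a first-class cost.

Estimated `d'_hat <= 0` (a below-chance or chance block) is floored at
1e-6 for the ideal-observer reference; as d' -> 0 the EV surface
flattens and the shortfall remains finite and continuous.

## Cutoff derivation

The cutoff is a univariate two-class quadratic discriminant on block-2
scores: per-group Gaussian parameters (unbiased n-1 variances, the
control group is small), boundary solving a quadratic in x.  With
unequal variances there are two roots; the operative cutoff is the root
at which the depressed-class posterior takes over as scores increase,
preferring the root above the control mean — the geometry of a
disengaged upper tail.  Ties at the boundary are labeled disengaged
(the `>=` rule).

Priors: the pipeline defaults to **equal priors**.  The empirical
195:40 class frequencies are a case-control sampling artifact, not a
population prior, and because roughly 70% of the depressed mixture is
control-like, frequency priors make the depressed density dominate at
every score — the discriminant then has no real root and no cutoff
exists.  Equal priors reproduce the expected geometry (a cutoff above
both group means).  Empirical or custom priors remain available through
the `priors` argument.

Comparison statistics: Pearson chi-square without continuity correction
(the uncorrected statistic reproduces the published worked examples; the
Yates-corrected variant sits behind a flag); unequal-variance t with the
Cochran–Cox weighted-critical-value approximation primary and
Welch–Satterthwaite reported alongside (the Cochran–Cox p is obtained by
root-finding the level at which |t| equals the weighted critical value);
Wilson score intervals for sensitivity/specificity by default with
Clopper–Pearson behind a flag.

## Outcome model

HAMD-17 at weeks 1, 2, 3, 4, 6, 8 is regressed on the observed week-0
score (covariate), treatment, engagement label, ln(week), and all
treatment x engagement x ln(week) interactions; baseline is excluded
from the response, which also sidesteps ln(0).  The natural log is a
convention — the base only rescales slope coefficients.  Each subject
has a random intercept; residuals follow spatial-power correlation
rho^|dweek| over the real-valued week axis, which handles the unequal
4 -> 6 -> 8 spacing exactly and reduces to lag-1 autoregression on an
evenly spaced grid.

Estimation is REML with the residual variance profiled out, leaving a
2-parameter search over (gamma = intercept-to-residual variance ratio,
rho), transformed to an unconstrained scale (log, atanh).  Starts at
rho in {0, 0.3, 0.6} are all evaluated and the best is polished by
Nelder-Mead (function tolerance 1e-8); subjects sharing a visit-time
pattern are batched so each objective evaluation is a handful of small
Cholesky solves.  The implementation is checked against an independent
oracle: at rho = 0 its REML log-likelihood matches the standard
random-intercept mixed model to < 1e-4, and with both variance
components null it matches the closed-form REML of the fixed-effects
regression.

The moderation test is a large-sample Wald z (reported as chi-square
with 1 df) on the three-way coefficient.  A residual-df t/F variant is
available (`df_method="residual"`); a full Satterthwaite denominator-df
approximation was considered and not implemented — at ~1,100
observations on ~195 subjects the normal and t references are
practically indistinguishable, and the simulation calibration shows the
z test holds its nominal level under the null generator.  Missing visits
are handled by likelihood (missing at random), no imputation.

## Synthetic cohort: what it does and does not emulate

Defaults mirror the reference study's structure: 195 depressed subjects
(a 70/30 engaged/disengaged latent mixture) and 40 controls drawn from
the engaged distribution; engaged agents at engagement 0.85 (sd 0.08),
disengaged at 0.08 (sd 0.06), d' 1.8 (sd 0.25), lapse 0.03;
demographics sampled independently of phenotype with margins resembling
a moderate-to-severe outpatient depression trial (the reference study
found no demographic association with engagement status, and the
independence lets type-I behavior of the comparison suite be checked).
HAMD-17 trajectories: baseline 18.5 (sd 4), per-cell ln(week) slopes
(engaged -3.6 under both arms; disengaged -1.8 placebo / -4.2
sertraline, i.e. a drug effect confined to the disengaged phenotype and
a true three-way coefficient of -2.4 — about a 5-point drug-placebo
separation by week 8), random-intercept sd 3, residual sd 3, rho 0.6
per week, 5% missing visits, scores rounded and clamped to 0–52.

For recovery studies a `WELL_SEPARATED_*` phenotype pair is provided:
engagement 0.97 vs 0.01 with tight spreads at d' = 1.  Separation in
*score space* is governed by the criterion gap |c* - c_start| = ln(3)/d',
so moderate sensitivity — not high sensitivity — is what makes the
phenotypes separable against the estimation noise of a 100-trial block;
at d' near 2 the ideal criterion sits close to neutral and the score
distributions of the two phenotypes genuinely overlap.

What passing tests do **not** show about real data: the generator's
agents are stationary within blocks (no within-block learning, fatigue,
or reaction-time dynamics); demographics are independent of phenotype by
construction; outcome trajectories are exactly log-linear per cell; and
the synthetic RBD scale (cents/trial shortfall) is not the scale of the
published scores, whose derivation appendix is not reproduced here —
published score means and the published cutoff value are therefore
context, not targets.

Two further calibration notes.  First, the baseline covariate is the
*observed* week-0 score, which carries measurement noise; classical
attenuation can bias fixed effects by a few percent, visible as a
small systematic component when coefficient recovery is pushed well
past 200 replicates.  Second, rounding/clamping to the 0–52 scale is a
mild misspecification; the simulation suite shows the three-way test
still holds its level within Monte Carlo error.

## Numerical choices

- Zero-cell correction: +0.5 to all four cells, all-or-none, flagged in
  output.
- QDA degenerate cases raise typed errors: zero within-group variance,
  identical distributions, no real root, no upward posterior crossing.
- Optimizer tolerances: REML function tolerance 1e-8; QDA cutoff
  verified against a 1e5-point grid oracle; EV optimality verified on
  criterion grids over random payoff draws.
- Determinism: every stochastic component draws from
  `numpy.random.default_rng` seeded from the run configuration; child
  seeds are spawned via `SeedSequence`, and the full pipeline is a pure
  function of (config, seed) — byte-identical artifacts across runs.
- Problem sizes in the routine simulation suites (200 replicates for
  calibration; 100–1000 draws for oracle equivalences) balance Monte
  Carlo resolution against a short default test run.

## Known limitations

- The published derivation appendix for the original disengagement score
  is not transcribed; `ev_shortfall` is this package's reference form and
  the registry exists precisely so an exact transcription can be added
  without touching downstream stages.
- Univariate classification only; no covariate-adjusted or multivariate
  discriminant, and no development/validation split bookkeeping.
- No site effects, no informative dropout, no evidence-accumulation
  (drift-diffusion) agents.
- The Cochran–Cox p-value is defined implicitly by its critical-value
  approximation and can differ from the Welch p in small samples; both
  are reported.
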