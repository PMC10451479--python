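# rbdkit

Economic disengagement scoring for the Probabilistic Reward Task (PRT),
with an objective engaged/disengaged cutoff and a longitudinal
treatment-moderation analysis.

## The problem

The PRT is a two-block forced-choice task in which correct identification
of one stimulus (the *rich* stimulus) is rewarded three times more often
than the other (the *lean* stimulus), at 20&cent; per reward.  Healthy
participants develop a response bias toward the rich stimulus; blunted
bias has been linked to depression and anhedonia, but symptom scales
correlate with it inconsistently.  `rbdkit` implements a neuroeconomic
alternative: **Reward Behavior Disengagement (RBD)**, which measures how
far a subject's responding falls short of the *reward-maximizing* policy
given the task's payoff structure, and asks two downstream questions of a
placebo-controlled antidepressant trial:

1. Is there an objective RBD level at which a depressed participant is
   *disengaged* relative to healthy controls?
2. Does that classification moderate the sertraline-vs-placebo difference
   in HAMD-17 trajectories over 8 weeks?

The clinical data this design mirrors are access-restricted, so the
package ships a first-class synthetic cohort generator that emulates
their structure (195 depressed + 40 control subjects, 200 trials in two
blocks, 3:1 reinforcement, HAMD-17 at weeks 0–8 under 1:1
sertraline/placebo randomization, and a two-phenotype depressed mixture).

## The model

Classical signal detection, base-10 PRT conventions:

    log b = 1/2 log10[(RichCorrect x LeanIncorrect) / (RichIncorrect x LeanCorrect)]
    log d = 1/2 log10[(RichCorrect x LeanCorrect) / (RichIncorrect x LeanIncorrect)]

(0.5 added to every cell when any cell is zero).  The economic layer puts
an equal-variance Gaussian observer in front of the payoff structure: an
ideal observer places its criterion at

    c* = ln(beta*) / d',   beta* = [P(lean) V_lean] / [P(rich) V_rich]

where `V_s` is the expected cents from a correct response to stimulus
`s`.  The default disengagement score is the expected-value shortfall

    RBD = EV(c*; d'_hat) - EV(c_hat; d'_hat)   [cents/trial]

evaluated at the block's estimated operating point `(d'_hat, c_hat)`.
It is zero exactly at optimal responding and grows as the criterion
departs from `c*` on either side.  Alternative functional forms can be
registered behind the same interface (`rbdkit.register_method`).

The engaged/disengaged cutoff is the boundary of a univariate two-class
quadratic discriminant (class-specific Gaussians on block-2 RBD, MDD vs
healthy controls): the root of
`log[pi_1 phi_1(x)] = log[pi_2 phi_2(x)]` above the control mean beyond
which the depressed posterior dominates; scores `>=` cutoff are labeled
disengaged.  Moderation is tested with a repeated-measures linear mixed
model: HAMD-17 at weeks 1–8 on baseline score, treatment, engagement
label, ln(week), and all their interactions, with a per-subject random
intercept and a spatial-power residual covariance
`corr = rho^|week_j - week_k|`, fit by REML; the test is a Wald test of
the treatment x engagement x ln(week) coefficient.

## Worked example

```python
import dataclasses
import rbdkit as rk
from rbdkit.io import PipelineConfig

cfg = dataclasses.replace(
    PipelineConfig(), rng_seed=11,
    cohort=dataclasses.replace(rk.CohortConfig(), rng_seed=11),
    out_dir="rbd_demo")
report = rk.run_pipeline(cfg)
```

With the default study conditions (195 MDD / 40 HC, 30% latent
disengaged, seed 11) this prints, via the artifacts in `rbd_demo/`:

```
HC  block-2 RBD: mean 0.053 sd 0.047
MDD block-2 RBD: mean 0.149 sd 0.200
cutoff 0.1329 roots (-0.0388, 0.1329)
disengaged MDD: 59/195 (30.3%)
3-way interaction: chi2 5.31 p 0.0212 coef -1.489 (se 0.646)
rho 0.686 sigma_b 1.60 sigma_e 3.30
```

Reading: depressed subjects forgo more expected reward per trial than
controls (0.149 vs 0.053 cents); the discriminant boundary above the
control mean classifies 30.3% of the depressed group as disengaged
(the latent mixture is 30%); and the classification moderates treatment
response — the disengaged-by-sertraline slope on ln(week) is 1.49
HAMD-17 points steeper than additivity predicts (p = 0.021), i.e. only
disengaged patients separate from placebo.  The same stages are available
from the shell: `rbdkit simulate|score|classify|outcomes|report`, each
with `--config`, `--seed`, `--out`.

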