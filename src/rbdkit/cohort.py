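"""Synthetic PRT cohort and longitudinal outcome generator.

The restricted clinical data behind the disengagement analysis cannot be
redistributed, so this module generates a structurally faithful stand-in:

* PRT sessions from a parametric equal-variance Gaussian signal-detection
  agent.  Each agent has a perceptual sensitivity d', a starting decision
  criterion, a lapse rate, and an *engagement* parameter in [0, 1] giving
  the fraction of the distance from the starting criterion to the
  reward-maximizing criterion that the agent traverses by block 2.  An
  engaged agent (engagement near 1) develops the normative bias toward
  the rich stimulus; a disengaged agent (near 0) does not.
* A controlled reward scheduler honoring the task's 3:1 rich:lean
  reinforcement at 20 cents per reward: a fixed number of presentations
  of each stimulus is designated to carry a reward, and a reward whose
  trial is answered incorrectly stays owed until the next correct
  response to that stimulus.
* A depressed cohort that is a two-phenotype mixture (engaged /
  disengaged, default 30% disengaged) alongside healthy controls drawn
  from the engaged distribution, with demographics sampled independently
  of phenotype.
* HAMD-17 trajectories at weeks 0,1,2,3,4,6,8 under 1:1 randomization to
  sertraline or placebo, generated from a random-intercept model with a
  per-cell improvement slope on log-week and a continuous-time AR
  (spatial power) residual, with the drug-placebo separation confined to
  the disengaged phenotype by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import rbd
from .types import SubjectSession, TrialRecord, VisitRecord, HAMD_MAX

PHENOTYPES = ("engaged", "disengaged")


class ConfigError(ValueError):
    """A simulation configuration is internally impossible."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Task structure: block layout and the asymmetric reward schedule."""

    trials_per_block: int = 100
    blocks: int = 2
    reward_cents: float = 20.0
    target_rich_rewards_per_block: int = 30
    target_lean_rewards_per_block: int = 10
    stimulus_probability_rich: float = 0.5

    def __post_init__(self) -> None:
        exp_rich = self.trials_per_block * self.stimulus_probability_rich
        exp_lean = self.trials_per_block * (1.0 - self.stimulus_probability_rich)
        if self.target_rich_rewards_per_block > exp_rich \
                or self.target_lean_rewards_per_block > exp_lean:
            raise ConfigError(
                "reward targets exceed expected stimulus presentations per block")
        if self.trials_per_block <= 0 or self.blocks <= 0:
            raise ConfigError("trials_per_block and blocks must be positive")

    @property
    def rich_lean_ratio(self) -> float:
        return self.target_rich_rewards_per_block / self.target_lean_rewards_per_block

    def payoff(self) -> rbd.PayoffStructure:
        """The economic structure implied by the schedule (reward probability
        per correct response approximated at perfect accuracy)."""
        exp_rich = self.trials_per_block * self.stimulus_probability_rich
        exp_lean = self.trials_per_block * (1.0 - self.stimulus_probability_rich)
        return rbd.PayoffStructure(
            reward_cents=self.reward_cents,
            p_reward_given_correct_rich=self.target_rich_rewards_per_block / exp_rich,
            p_reward_given_correct_lean=self.target_lean_rewards_per_block / exp_lean,
            stimulus_probability_rich=self.stimulus_probability_rich,
        )


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one signal-detection agent."""

    d_prime: float = 1.8
    criterion_start: float = 0.0
    engagement: float = 0.85
    lapse_rate: float = 0.03
    rt_mean_ms: Optional[float] = None
    rt_sd_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ConfigError("d_prime must be nonnegative")
        if not 0.0 <= self.engagement <= 1.0:
            raise ConfigError("engagement must lie in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ConfigError("lapse_rate must lie in [0, 1]")


@dataclass(frozen=True)
class PhenotypeDist:
    """Gaussian sampling distribution for agent parameters of one phenotype
    (draws are clipped back into the valid parameter ranges)."""

    d_prime_mean: float = 1.8
    d_prime_sd: float = 0.25
    criterion_start_mean: float = 0.0
    criterion_start_sd: float = 0.10
    engagement_mean: float = 0.85
    engagement_sd: float = 0.08
    lapse_mean: float = 0.03
    lapse_sd: float = 0.02

    def draw(self, rng: np.random.Generator) -> AgentParams:
        return AgentParams(
            d_prime=float(np.clip(rng.normal(self.d_prime_mean, self.d_prime_sd),
                                  0.2, 6.0)),
            criterion_start=float(rng.normal(self.criterion_start_mean,
                                             self.criterion_start_sd)),
            engagement=float(np.clip(rng.normal(self.engagement_mean,
                                                self.engagement_sd), 0.0, 1.0)),
            lapse_rate=float(np.clip(rng.normal(self.lapse_mean, self.lapse_sd),
                                     0.0, 0.5)),
        )


ENGAGED_PHENOTYPE = PhenotypeDist()
DISENGAGED_PHENOTYPE = PhenotypeDist(engagement_mean=0.08, engagement_sd=0.06)

#: Well-separated phenotype pair for recovery studies: tight parameter
#: spreads, extreme engagement means, and moderate sensitivity.  At d' = 1
#: the ideal criterion sits at ln(1/3)/d' = -1.1, so the expected-value gap
#: between engaged and disengaged responding is large relative to the
#: estimation noise of a 100-trial block and the phenotypes barely overlap
#: in score space.
WELL_SEPARATED_ENGAGED = PhenotypeDist(
    engagement_mean=0.97, engagement_sd=0.02, d_prime_mean=1.0,
    d_prime_sd=0.08, criterion_start_sd=0.03, lapse_mean=0.005, lapse_sd=0.005)
WELL_SEPARATED_DISENGAGED = PhenotypeDist(
    engagement_mean=0.01, engagement_sd=0.01, d_prime_mean=1.0,
    d_prime_sd=0.08, criterion_start_sd=0.03, lapse_mean=0.005, lapse_sd=0.005)


@dataclass(frozen=True)
class OutcomeGenParams:
    """Generating parameters for the longitudinal HAMD-17 trajectories.

    ``slopes`` maps (phenotype, treatment) to the improvement slope on the
    natural log of week; the disengaged-sertraline cell is steepest by
    default so only disengaged patients show a drug-placebo separation.
    """

    baseline_mean: float = 18.5
    baseline_sd: float = 4.0
    slopes: dict = field(default_factory=lambda: {
        ("engaged", "placebo"): -3.6,
        ("engaged", "sertraline"): -3.6,
        ("disengaged", "placebo"): -1.8,
        ("disengaged", "sertraline"): -4.2,
    })
    random_intercept_sd: float = 3.0
    residual_sd: float = 3.0
    residual_rho: float = 0.6
    missing_visit_probability: float = 0.05
    weeks: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        if not -1.0 < self.residual_rho < 1.0:
            raise ConfigError("|residual_rho| must be < 1")
        if not 0.0 <= self.missing_visit_probability <= 1.0:
            raise ConfigError("missing_visit_probability must lie in [0, 1]")

    def null(self) -> "OutcomeGenParams":
        """Same parameters with every cell sharing the engaged-placebo slope."""
        s = self.slopes[("engaged", "placebo")]
        return OutcomeGenParams(
            baseline_mean=self.baseline_mean, baseline_sd=self.baseline_sd,
            slopes={k: s for k in self.slopes},
            random_intercept_sd=self.random_intercept_sd,
            residual_sd=self.residual_sd, residual_rho=self.residual_rho,
            missing_visit_probability=self.missing_visit_probability,
            weeks=self.weeks)

    @property
    def three_way_coefficient(self) -> float:
        """True treatment x phenotype x log-week interaction (disengaged and
        sertraline coded 1, i.e. the slope difference-in-differences)."""
        s = self.slopes
        return ((s[("disengaged", "sertraline")] - s[("disengaged", "placebo")])
                - (s[("engaged", "sertraline")] - s[("engaged", "placebo")]))


@dataclass(frozen=True)
class CohortConfig:
    n_mdd: int = 195
    n_hc: int = 40
    mdd_disengaged_fraction: float = 0.30
    engaged_dist: PhenotypeDist = ENGAGED_PHENOTYPE
    disengaged_dist: PhenotypeDist = DISENGAGED_PHENOTYPE
    schedule: ScheduleConfig = ScheduleConfig()
    outcome_params: OutcomeGenParams = OutcomeGenParams()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mdd_disengaged_fraction <= 1.0:
            raise ConfigError("mdd_disengaged_fraction must lie in [0, 1]")
        if self.n_mdd < 0 or self.n_hc < 0:
            raise ConfigError("group sizes must be nonnegative")


def _block_criterion(agent: AgentParams, schedule: ScheduleConfig,
                     block: int) -> float:
    if block == 1:
        return agent.criterion_start
    try:
        c_opt = rbd.optimal_criterion(schedule.payoff(), agent.d_prime)
    except rbd.UndefinedCriterionError:
        return agent.criterion_start
    return agent.criterion_start + agent.engagement * (c_opt - agent.criterion_start)


def simulate_session(agent: AgentParams, schedule: ScheduleConfig,
                     seed, subject_id: str = "S0",
                     group: str = "MDD") -> SubjectSession:
    """Simulate one subject's full PRT session.

    Evidence on each trial is N(+d'/2, 1) for rich and N(-d'/2, 1) for
    lean stimuli; the agent responds "rich" when evidence exceeds its
    block criterion, except on lapse trials, where it responds uniformly
    at random.  Rewards are delivered by the controlled scheduler: per
    block, ``target_*_rewards_per_block`` presentations of each stimulus
    are pre-designated to carry a reward, and an owed reward (designated
    trial answered incorrectly) is released at the next correct response
    to the same stimulus.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    for block in range(1, schedule.blocks + 1):
        criterion = _block_criterion(agent, schedule, block)
        n = schedule.trials_per_block
        stimuli = np.where(rng.random(n) < schedule.stimulus_probability_rich,
                           "rich", "lean")
        designated = {"rich": set(), "lean": set()}
        for stim, target in (("rich", schedule.target_rich_rewards_per_block),
                             ("lean", schedule.target_lean_rewards_per_block)):
            idx = np.flatnonzero(stimuli == stim)
            k = min(target, idx.size)
            designated[stim] = set(rng.choice(idx, size=k, replace=False).tolist())
        owed = {"rich": 0, "lean": 0}
        for i in range(n):
            stim = str(stimuli[i])
            mean = agent.d_prime / 2.0 if stim == "rich" else -agent.d_prime / 2.0
            evidence = rng.normal(mean, 1.0)
            if rng.random() < agent.lapse_rate:
                response = "rich" if rng.random() < 0.5 else "lean"
            else:
                response = "rich" if evidence > criterion else "lean"
            correct = response == stim
            rewarded = False
            if i in designated[stim]:
                if correct:
                    rewarded = True
                else:
                    owed[stim] += 1
            elif correct and owed[stim] > 0:
                rewarded = True
                owed[stim] -= 1
            rt = None
            if agent.rt_mean_ms is not None:
                rt = float(max(0.0, rng.normal(agent.rt_mean_ms,
                                               agent.rt_sd_ms or 0.0)))
            trials.append(TrialRecord(
                subject_id=subject_id, group=group, block=block,
                trial_index=i + 1, stimulus=stim, response=response,
                correct=correct, rewarded=rewarded, reaction_time_ms=rt))
    session = SubjectSession(subject_id=subject_id, group=group, trials=trials)
    session.validate()
    return session


def _sample_demographics(rng: np.random.Generator, group: str) -> dict:
    """Baseline covariates with margins resembling a moderate-to-severe
    outpatient depression trial; independent of reward phenotype."""
    age = float(np.clip(rng.normal(37.2, 13.1), 18, 65))
    sex = "female" if rng.random() < (0.662 if group == "MDD" else 0.625) else "male"
    race = rng.choice(["caucasian", "african_american", "asian", "other"],
                      p=[0.64, 0.23, 0.07, 0.06])
    education = rng.choice(
        ["no_high_school", "high_school", "some_college", "college_degree"],
        p=[0.03, 0.25, 0.34, 0.38])
    employment = rng.choice(["full_time", "part_time", "unemployed"],
                            p=[0.28, 0.24, 0.48])
    marital = rng.choice(["married_partnered", "single"], p=[0.21, 0.79])
    income = float(rng.lognormal(mean=7.6, sigma=0.7))
    if group == "MDD":
        hamd = float(np.clip(rng.normal(18.5, 4.0), 14, 40))
        qids = float(np.clip(rng.normal(17.5, 2.2), 15, 27))
        shaps = float(np.clip(rng.normal(32.0, 7.0), 14, 56))
        n_mdes = int(np.clip(round(rng.lognormal(1.6, 1.0)), 1, 99))
        mde_len = float(np.clip(rng.lognormal(2.6, 1.2), 0.5, 240))
    else:
        hamd = float(np.clip(rng.normal(1.5, 1.5), 0, 7))
        qids = float(np.clip(rng.normal(2.0, 1.8), 0, 7))
        shaps = float(np.clip(rng.normal(20.0, 4.0), 14, 40))
        n_mdes = 0
        mde_len = 0.0
    return {
        "age": age, "sex": sex, "race": race, "education": education,
        "employment": employment, "marital_status": marital,
        "income_monthly_usd": income, "hamd17_baseline": hamd,
        "qids_sr": qids, "shaps": shaps, "n_lifetime_mdes": n_mdes,
        "mde_length_months": mde_len,
        "n_comorbidities": int(rng.poisson(1.3)),
    }


def simulate_cohort(config: CohortConfig):
    """Generate the full cohort: PRT sessions plus a demographics table.

    Returns ``(sessions, demographics)``.  The demographics DataFrame has
    one row per subject and carries the latent truth needed by recovery
    tests: ``true_phenotype`` and, within the depressed group, the 1:1
    randomized ``treatment``.
    """
    rng = np.random.default_rng(config.rng_seed)
    seeds = np.random.SeedSequence(config.rng_seed).spawn(
        config.n_mdd + config.n_hc)
    sessions: list[SubjectSession] = []
    rows = []
    treatments = np.array(["sertraline", "placebo"]
                          * ((config.n_mdd + 1) // 2))[:config.n_mdd]
    rng.shuffle(treatments)
    k = 0
    for group, n in (("MDD", config.n_mdd), ("HC", config.n_hc)):
        for j in range(n):
            sid = f"{group}{j + 1:04d}"
            if group == "MDD":
                disengaged = rng.random() < config.mdd_disengaged_fraction
                phenotype = "disengaged" if disengaged else "engaged"
                treatment = treatments[j]
            else:
                phenotype = "engaged"
                treatment = ""
            dist = (config.disengaged_dist if phenotype == "disengaged"
                    else config.engaged_dist)
            agent = dist.draw(rng)
            session = simulate_session(agent, config.schedule, seeds[k],
                                       subject_id=sid, group=group)
            demo = _sample_demographics(rng, group)
            demo.update(subject_id=sid, group=group, true_phenotype=phenotype,
                        treatment=treatment, true_engagement=agent.engagement,
                        true_d_prime=agent.d_prime)
            session.covariates = demo
            sessions.append(session)
            rows.append(demo)
            k += 1
    cols = ["subject_id", "group", "true_phenotype", "treatment",
            "true_engagement", "true_d_prime", "age", "sex", "race",
            "education", "employment", "marital_status", "income_monthly_usd",
            "hamd17_baseline", "qids_sr", "shaps", "n_lifetime_mdes",
            "mde_length_months", "n_comorbidities"]
    demographics = pd.DataFrame(rows)[cols]
    return sessions, demographics


def simulate_outcomes(demographics: pd.DataFrame,
                      params: OutcomeGenParams, seed) -> list[VisitRecord]:
    """Generate HAMD-17 visits for the depressed, treated subjects.

    Each trajectory is baseline + random intercept + cell slope x ln(week)
    + a continuous-time AR residual with correlation rho^|dweek|, rounded
    and clamped to the 0..52 scale.  Post-baseline visits are missing
    completely at random with the configured probability; the week-0
    visit is always retained (it supplies the baseline covariate).
    """
    rng = np.random.default_rng(seed)
    weeks = np.asarray(params.weeks, dtype=float)
    gaps = np.abs(weeks[:, None] - weeks[None, :])
    if params.residual_rho == 0.0:
        corr = np.eye(len(weeks))
    else:
        corr = np.sign(params.residual_rho) ** gaps * np.abs(params.residual_rho) ** gaps
    if params.residual_sd == 0.0:
        chol = np.zeros((len(weeks), len(weeks)))
    else:
        cov = params.residual_sd ** 2 * corr
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(weeks)))
    visits: list[VisitRecord] = []
    mdd = demographics[(demographics["group"] == "MDD")
                       & (demographics["treatment"] != "")]
    for _, row in mdd.iterrows():
        slope = params.slopes[(row["true_phenotype"], row["treatment"])]
        baseline = rng.normal(params.baseline_mean, params.baseline_sd)
        b_i = rng.normal(0.0, params.random_intercept_sd)
        eps = chol @ rng.standard_normal(len(weeks))
        for w, e in zip(weeks, eps):
            trend = slope * math.log(w) if w > 0 else 0.0
            if w > 0 and rng.random() < params.missing_visit_probability:
                continue
            value = int(np.clip(round(baseline + b_i + trend + e), 0, HAMD_MAX))
            visits.append(VisitRecord(subject_id=row["subject_id"], week=float(w),
                                      hamd17=value, treatment=row["treatment"]))
    return visits


def _jsonable(o):
    if hasattr(o, "__dataclass_fields__"):
        o = asdict(o)
    if isinstance(o, dict):
        return {str(k): _jsonable(v)
                for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    return o if isinstance(o, (str, int, float, bool, type(None))) else str(o)


def config_hash(config) -> str:
    """Stable short hash of a configuration dataclass, for run logs."""
    import hashlib
    import json

    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
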