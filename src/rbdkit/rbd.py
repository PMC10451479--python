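"""Reward Behavior Disengagement (RBD): economic scoring of PRT blocks.

The score embeds classical equal-variance Gaussian signal detection in an
ideal-observer economic model.  Given the task payoff structure (reward
magnitude, per-stimulus reward probabilities, stimulus base rates, and an
optional effort cost), an ideal observer places its decision criterion at
the evidence value where the expected payoffs of the two responses are
equal:

    c* = ln(beta*) / d',   beta* = [P(lean) V_lean] / [P(rich) V_rich]

with V_s the expected cents earned by a correct response to stimulus s.
Disengagement is then how far a subject's observed operating point falls
short of that reward-maximizing policy.  The default functional form,
``ev_shortfall``, is the expected-value gap in cents per trial:

    RBD = EV(c* ; d'_hat) - EV(c_hat ; d'_hat)

which is zero exactly at the optimal criterion and increases as the
empirical criterion departs from it on either side.  Alternative
functional forms can be registered under new method tags; every score
row carries its tag so scores from different forms are never mixed.

Sign convention: evidence on rich trials is N(+d'/2, 1), on lean trials
N(-d'/2, 1); the subject responds "rich" when evidence exceeds the
criterion, so criteria below zero favor the rich response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.stats import norm

from .sdt import corrected_cells
from .types import BlockCounts

#: Default per-stimulus reward probabilities: 30 of ~50 rich presentations
#: and 10 of ~50 lean presentations per 100-trial block carry a reward.
DEFAULT_P_REWARD_RICH = 0.6
DEFAULT_P_REWARD_LEAN = 0.2


class DegenerateCountsError(ValueError):
    """A block never presented one of the stimuli; SDT estimation impossible."""


class UndefinedCriterionError(ValueError):
    """d' = 0: every criterion has identical expected value."""


@dataclass(frozen=True)
class PayoffStructure:
    """Economic structure of one PRT block."""

    reward_cents: float = 20.0
    p_reward_given_correct_rich: float = DEFAULT_P_REWARD_RICH
    p_reward_given_correct_lean: float = DEFAULT_P_REWARD_LEAN
    stimulus_probability_rich: float = 0.5
    effort_cost_cents: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_reward_given_correct_rich,
                  self.p_reward_given_correct_lean,
                  self.stimulus_probability_rich):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.reward_cents < 0 or self.effort_cost_cents < 0:
            raise ValueError("negative payoff magnitude")

    @property
    def value_rich(self) -> float:
        """Expected cents from a correct rich response."""
        return self.reward_cents * self.p_reward_given_correct_rich

    @property
    def value_lean(self) -> float:
        return self.reward_cents * self.p_reward_given_correct_lean

    def relabeled(self) -> "PayoffStructure":
        return PayoffStructure(
            reward_cents=self.reward_cents,
            p_reward_given_correct_rich=self.p_reward_given_correct_lean,
            p_reward_given_correct_lean=self.p_reward_given_correct_rich,
            stimulus_probability_rich=1.0 - self.stimulus_probability_rich,
            effort_cost_cents=self.effort_cost_cents,
        )


@dataclass(frozen=True)
class RBDScore:
    subject_id: str
    block: int
    rbd: float
    method_tag: str
    d_prime_hat: float = float("nan")
    criterion_hat: float = float("nan")


def optimal_criterion(payoff: PayoffStructure, d_prime: float) -> float:
    """Criterion maximizing expected cents per trial.

    Raises UndefinedCriterionError at d' = 0, where the evidence carries no
    information and all criteria are equivalent.
    """
    if d_prime <= 0:
        raise UndefinedCriterionError("optimal criterion undefined for d' <= 0")
    p_rich = payoff.stimulus_probability_rich
    num = (1.0 - p_rich) * payoff.value_lean
    den = p_rich * payoff.value_rich
    if num <= 0 or den <= 0:
        raise UndefinedCriterionError(
            "one response has zero expected value; criterion degenerates to +/-inf")
    beta_star = num / den
    return math.log(beta_star) / d_prime


def expected_value(criterion: float, payoff: PayoffStructure,
                   d_prime: float) -> float:
    """Expected cents per trial of a fixed-criterion policy.

    Exact Gaussian-tail arithmetic: P(respond rich | rich) = Phi(d'/2 - c),
    P(respond lean | lean) = Phi(c + d'/2).
    """
    p_rich = payoff.stimulus_probability_rich
    hit = norm.cdf(d_prime / 2.0 - criterion)
    corr_rej = norm.cdf(criterion + d_prime / 2.0)
    ev = (p_rich * hit * payoff.value_rich
          + (1.0 - p_rich) * corr_rej * payoff.value_lean)
    return ev - payoff.effort_cost_cents


def empirical_operating_point(counts: BlockCounts) -> tuple[float, float]:
    """Estimate (d'_hat, c_hat) from a block's hit / false-alarm rates.

    Hit rate = rich trials answered rich; false-alarm rate = lean trials
    answered rich.  Uses the same all-or-none 0.5 zero-cell correction as
    the classical PRT measures.
    """
    rc, ri, lc, li = corrected_cells(counts)[:4]
    n_rich = rc + ri
    n_lean = lc + li
    if counts.rich_correct + counts.rich_incorrect == 0 \
            or counts.lean_correct + counts.lean_incorrect == 0:
        raise DegenerateCountsError(
            f"subject {counts.subject_id} block {counts.block}: "
            "a stimulus was never presented")
    z_hit = norm.ppf(rc / n_rich)
    z_fa = norm.ppf(li / n_lean)
    d_hat = z_hit - z_fa
    c_hat = -0.5 * (z_hit + z_fa)
    return d_hat, c_hat


def ev_shortfall(criterion: float, d_prime: float,
                 payoff: PayoffStructure) -> float:
    """Expected-value gap (cents/trial) between the ideal-observer policy
    and a fixed-criterion policy at the same sensitivity."""
    c_star = optimal_criterion(payoff, d_prime)
    return (expected_value(c_star, payoff, d_prime)
            - expected_value(criterion, payoff, d_prime))


def _ev_shortfall(counts: BlockCounts, payoff: PayoffStructure) -> tuple[float, float, float]:
    d_hat, c_hat = empirical_operating_point(counts)
    # the ideal-observer reference needs a strictly informative channel
    d_ref = max(d_hat, 1e-6)
    return ev_shortfall(c_hat, d_ref, payoff), d_hat, c_hat


_METHODS: dict[str, Callable[[BlockCounts, PayoffStructure], tuple[float, float, float]]] = {
    "ev_shortfall": _ev_shortfall,
}


def register_method(tag: str, fn: Callable[[BlockCounts, PayoffStructure],
                                           tuple[float, float, float]]) -> None:
    """Register an alternative disengagement functional form.

    ``fn(counts, payoff)`` must return ``(rbd, d_prime_hat, criterion_hat)``
    and satisfy the score contract: minimal when the empirical criterion is
    optimal, increasing in |c - c*|, invariant to rich/lean relabeling.
    """
    _METHODS[tag] = fn


def available_methods() -> tuple[str, ...]:
    return tuple(sorted(_METHODS))


def compute_rbd(counts: BlockCounts, payoff: PayoffStructure | None = None,
                method_tag: str = "ev_shortfall") -> RBDScore:
    """Score one block's disengagement from reward-maximizing responding."""
    if payoff is None:
        payoff = PayoffStructure()
    try:
        fn = _METHODS[method_tag]
    except KeyError:
        raise KeyError(
            f"no RBD method registered under tag {method_tag!r}; "
            f"available: {available_methods()}") from None
    rbd, d_hat, c_hat = fn(counts, payoff)
    return RBDScore(subject_id=counts.subject_id, block=counts.block,
                    rbd=rbd, method_tag=method_tag,
                    d_prime_hat=d_hat, criterion_hat=c_hat)
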