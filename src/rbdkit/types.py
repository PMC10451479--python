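"""Core domain types for the PRT disengagement pipeline.

The atomic behavioral datum is a single Probabilistic Reward Task (PRT)
trial; a subject contributes 200 trials in two 100-trial blocks.  The
longitudinal outcome datum is one clinician-rated HAMD-17 score at a
scheduled study week under one of two treatment arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

GROUPS = ("MDD", "HC")
STIMULI = ("rich", "lean")
TREATMENTS = ("sertraline", "placebo")
VISIT_WEEKS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
HAMD_MAX = 52


class SchemaError(ValueError):
    """A file is missing required columns or has an unparseable layout."""


class IntegrityError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One forced-choice PRT trial.

    ``stimulus`` is the presented category ("rich" = the more frequently
    rewarded stimulus), ``response`` the subject's choice.  ``rewarded``
    can only be true on a correct response: the task never rewards errors.
    """

    subject_id: str
    group: str
    block: int
    trial_index: int
    stimulus: str
    response: str
    correct: bool
    rewarded: bool
    reaction_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise IntegrityError(f"unknown group {self.group!r}")
        if self.stimulus not in STIMULI:
            raise IntegrityError(f"non-binary stimulus {self.stimulus!r}")
        if self.response not in STIMULI:
            raise IntegrityError(f"non-binary response {self.response!r}")
        if self.block not in (1, 2):
            raise IntegrityError(f"block must be 1 or 2, got {self.block}")
        if self.correct != (self.response == self.stimulus):
            raise IntegrityError(
                f"correct flag inconsistent with stimulus/response "
                f"(subject {self.subject_id}, block {self.block}, "
                f"trial {self.trial_index})"
            )
        if self.rewarded and not self.correct:
            raise IntegrityError(
                f"rewarded incorrect response (subject {self.subject_id}, "
                f"block {self.block}, trial {self.trial_index})"
            )
        if self.reaction_time_ms is not None and self.reaction_time_ms < 0:
            raise IntegrityError("negative reaction time")


@dataclass
class SubjectSession:
    """All PRT trials of one subject, plus demographic covariates."""

    subject_id: str
    group: str
    trials: list[TrialRecord] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.trials:
            if t.subject_id != self.subject_id:
                raise IntegrityError(
                    f"trial subject {t.subject_id!r} != session {self.subject_id!r}"
                )
        for block in (1, 2):
            idx = [t.trial_index for t in self.trials if t.block == block]
            if len(idx) != len(set(idx)):
                raise IntegrityError(
                    f"duplicate trial index in subject {self.subject_id} block {block}"
                )

    def block_trials(self, block: int) -> list[TrialRecord]:
        return [t for t in self.trials if t.block == block]


@dataclass(frozen=True)
class VisitRecord:
    """One subject-week HAMD-17 observation."""

    subject_id: str
    week: float
    hamd17: int
    treatment: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise IntegrityError(f"unknown treatment {self.treatment!r}")
        if not (0 <= self.hamd17 <= HAMD_MAX):
            raise IntegrityError(f"HAMD-17 out of range: {self.hamd17}")
        if self.week < 0:
            raise IntegrityError(f"negative week {self.week}")


@dataclass(frozen=True)
class BlockCounts:
    """The 2x2 signal-detection tally for one subject-block.

    Cells are stimulus x correctness; ``rich_incorrect`` trials are rich
    presentations answered "lean", i.e. misses of the rich stimulus.
    """

    subject_id: str
    block: int
    rich_correct: int
    rich_incorrect: int
    lean_correct: int
    lean_incorrect: int
    rewards_delivered: int = 0

    def __post_init__(self) -> None:
        cells = (self.rich_correct, self.rich_incorrect,
                 self.lean_correct, self.lean_incorrect)
        if any(c < 0 for c in cells) or self.rewards_delivered < 0:
            raise IntegrityError("negative count")
        if self.rewards_delivered > self.rich_correct + self.lean_correct:
            raise IntegrityError("rewards exceed correct responses")

    @property
    def n_trials(self) -> int:
        return (self.rich_correct + self.rich_incorrect
                + self.lean_correct + self.lean_incorrect)

    def relabeled(self) -> "BlockCounts":
        """Swap the rich/lean stimulus labels (used by symmetry checks)."""
        return BlockCounts(
            subject_id=self.subject_id, block=self.block,
            rich_correct=self.lean_correct, rich_incorrect=self.lean_incorrect,
            lean_correct=self.rich_correct, lean_incorrect=self.rich_incorrect,
            rewards_delivered=self.rewards_delivered,
        )
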