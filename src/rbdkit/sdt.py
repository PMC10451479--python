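"""Classical signal-detection measures for the Probabilistic Reward Task.

Response bias (log b) indexes the systematic preference for the rich
response induced by the 3:1 asymmetric reinforcement; discriminability
(log d) indexes perceptual accuracy independent of that preference.  Both
follow the base-10 logarithmic convention of the PRT literature:

    log b = 1/2 * log10[(RichCorrect * LeanIncorrect) / (RichIncorrect * LeanCorrect)]
    log d = 1/2 * log10[(RichCorrect * LeanCorrect) / (RichIncorrect * LeanIncorrect)]

If any of the four cells is zero, 0.5 is added to every cell (all-or-none)
so both ratios stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .types import BlockCounts, SubjectSession


@dataclass(frozen=True)
class SDTMeasures:
    subject_id: str
    block: int
    log_b: float
    log_d: float
    correction_applied: bool


def tabulate_blocks(session: SubjectSession) -> list[BlockCounts]:
    """Tally each block of a session into a 2x2 stimulus-by-correctness table."""
    session.validate()
    out = []
    for block in sorted({t.block for t in session.trials}):
        trials = session.block_trials(block)
        rc = sum(1 for t in trials if t.stimulus == "rich" and t.correct)
        ri = sum(1 for t in trials if t.stimulus == "rich" and not t.correct)
        lc = sum(1 for t in trials if t.stimulus == "lean" and t.correct)
        li = sum(1 for t in trials if t.stimulus == "lean" and not t.correct)
        out.append(BlockCounts(
            subject_id=session.subject_id, block=block,
            rich_correct=rc, rich_incorrect=ri,
            lean_correct=lc, lean_incorrect=li,
            rewards_delivered=sum(1 for t in trials if t.rewarded),
        ))
    return out


def corrected_cells(counts: BlockCounts) -> tuple[float, float, float, float, bool]:
    """Return (rich_correct, rich_incorrect, lean_correct, lean_incorrect)
    with the all-or-none 0.5 zero-cell correction, plus a correction flag."""
    cells = (counts.rich_correct, counts.rich_incorrect,
             counts.lean_correct, counts.lean_incorrect)
    if any(c == 0 for c in cells):
        return tuple(c + 0.5 for c in cells) + (True,)  # type: ignore[return-value]
    return tuple(float(c) for c in cells) + (False,)  # type: ignore[return-value]


def response_bias(counts: BlockCounts) -> float:
    rc, ri, lc, li = corrected_cells(counts)[:4]
    return 0.5 * math.log10((rc * li) / (ri * lc))


def discriminability(counts: BlockCounts) -> float:
    rc, ri, lc, li = corrected_cells(counts)[:4]
    return 0.5 * math.log10((rc * lc) / (ri * li))


def sdt_measures(counts: BlockCounts) -> SDTMeasures:
    correction = corrected_cells(counts)[4]
    return SDTMeasures(
        subject_id=counts.subject_id, block=counts.block,
        log_b=response_bias(counts), log_d=discriminability(counts),
        correction_applied=correction,
    )


def sdt_table(sessions) -> pd.DataFrame:
    """Per subject-block table of log b / log d for a collection of sessions."""
    rows = []
    for s in sessions:
        for counts in tabulate_blocks(s):
            m = sdt_measures(counts)
            rows.append({
                "subject_id": m.subject_id, "group": s.group, "block": m.block,
                "log_b": m.log_b, "log_d": m.log_d,
                "correction_applied": int(m.correction_applied),
            })
    return pd.DataFrame(rows, columns=[
        "subject_id", "group", "block", "log_b", "log_d", "correction_applied"])
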