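"""Component scoring: Likert sums with the DK and null rules, the EMA day
cut-off, the clinical-assessment conjunction rule, and cohort event counts.

Status semantics per component:

* ``zero`` — no scored answer above 0 / no painted slot / no finding.
* ``null`` — treated as non-positive despite a nonzero raw sum: a triplet
  whose only nonzero answer is a single "almost never" (score 1), or an EMA
  diary with paintings on fewer than 4 days.
* ``positive`` — the component passes its cut-off.

"Don't know" answers carry no score: they are excluded from sums and from the
null rule, so a triplet of (DK, almost_never, DK) has exactly one scored
behavior at score 1 and is null, and an all-DK triplet is zero.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .model import (
    BEHAVIORS,
    DK,
    BehaviorTriplet,
    ClinicalExam,
    EMADiary,
    LikertResponse,
    ParticipantRecord,
    Source,
    Stage,
)

__all__ = [
    "Status",
    "ComponentScore",
    "score_likert",
    "score_triplet",
    "score_ema",
    "score_clinical",
    "score_record",
    "summarize_tooth_wear",
    "aggregate_event_counts",
]

#: Minimum painted days for a positive EMA.
EMA_DAY_CUTOFF = 4


class Status(enum.Enum):
    ZERO = "zero"
    NULL = "null"
    POSITIVE = "positive"


@dataclass(frozen=True)
class ComponentScore:
    """Raw point sum and cut-off status for one component of one record."""

    component: str
    raw_sum: int
    status: Status
    dk_count: int = 0  # triplets only
    days_with_paintings: int = 0  # EMA only


def score_likert(response: LikertResponse) -> int | str:
    """Map a Likert answer to its 0-4 score, or the DK sentinel (no score)."""
    return response.score


def score_triplet(triplet: BehaviorTriplet) -> ComponentScore:
    """Sum the three question scores, applying the DK and null rules.

    The raw sum ranges 0-12.  Null applies when exactly one scored answer is
    nonzero and that answer is "almost never" (score 1).
    """
    scores = [r.score for r in triplet.responses]
    dk_count = sum(1 for s in scores if s == DK)
    numeric = [s for s in scores if s != DK]
    raw_sum = sum(numeric)
    nonzero = [s for s in numeric if s > 0]
    if raw_sum == 0:
        status = Status.ZERO
    elif len(nonzero) == 1 and nonzero[0] == 1:
        status = Status.NULL
    else:
        status = Status.POSITIVE
    return ComponentScore(triplet.source.value, raw_sum, status, dk_count=dk_count)


def score_ema(diary: EMADiary) -> ComponentScore:
    """Count painted slots and painted days; positive needs >= 4 painted days."""
    raw_sum = diary.painted_slots
    days = diary.days_with_paintings
    if raw_sum == 0:
        status = Status.ZERO
    elif days < EMA_DAY_CUTOFF:
        status = Status.NULL
    else:
        status = Status.POSITIVE
    return ComponentScore("EMA", raw_sum, status, days_with_paintings=days)


def score_clinical(exam: ClinicalExam) -> tuple[ComponentScore, ComponentScore, bool]:
    """Score the intraoral and extraoral assessments.

    Each present finding scores one point.  The clinical assessment as a whole
    is positive only when both ICA and ECA have at least one finding; the two
    raw sums enter the spectrum regardless of that conjunction.
    """
    ica_sum = sum(exam.ica_findings)
    eca_sum = sum(exam.eca_findings)
    ica = ComponentScore("ICA", ica_sum, Status.POSITIVE if ica_sum else Status.ZERO)
    eca = ComponentScore("ECA", eca_sum, Status.POSITIVE if eca_sum else Status.ZERO)
    return ica, eca, bool(ica_sum and eca_sum)


def score_record(record: ParticipantRecord) -> dict[str, ComponentScore]:
    """Score all six components of one record; key order is R1, SR, R2, ICA, ECA, EMA."""
    ica, eca, _ = score_clinical(record.exam)
    return {
        "R1": score_triplet(record.r1),
        "SR": score_triplet(record.sr),
        "R2": score_triplet(record.r2),
        "ICA": ica,
        "ECA": eca,
        "EMA": score_ema(record.ema),
    }


def summarize_tooth_wear(exam: ClinicalExam) -> dict[int, int]:
    """Histogram of recorded wear grades (grade -> tooth count).

    Complementary data only: the histogram never alters any score.
    """
    counts = Counter(exam.tooth_wear.values())
    return {grade: counts.get(grade, 0) for grade in range(5)}


#: Column order of the event-count table (parents' reports, then self-report).
EVENT_SOURCES = (Source.R1, Source.R2, Source.SR)


def aggregate_event_counts(
    cohort: list[ParticipantRecord], stage: Stage
) -> pd.DataFrame:
    """Count, per behavior and source, participants reporting the event at all.

    An event is counted whenever the answer scores above 0 — including answers
    inside a null triplet, which tallies perceived events rather than
    component positivity.  Rows are the three behaviors, columns R1/R2/SR plus
    a Total column summing the three sources.
    """
    wrong = [r.participant_id for r in cohort if r.stage is not stage]
    if wrong:
        raise ValueError(
            f"records not at stage {stage.value!r}: {', '.join(sorted(wrong))}"
        )
    table = pd.DataFrame(
        0, index=list(BEHAVIORS), columns=[s.value for s in EVENT_SOURCES]
    )
    for record in cohort:
        for source in EVENT_SOURCES:
            triplet = record.triplet(source)
            for behavior in BEHAVIORS:
                score = getattr(triplet, behavior).score
                if score != DK and score > 0:
                    table.loc[behavior, source.value] += 1
    table["Total"] = table.sum(axis=1)
    return table
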