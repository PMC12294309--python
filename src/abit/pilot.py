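"""Pilot-study event counts and a matching synthetic fixture cohort.

The ABIT pilot (10 families, test plus 15-day retest in a subgroup) reported
how many participants perceived each behavior at all, per source.  Those
printed per-source counts are data shipped with the instrument; the fixture
builder constructs a synthetic cohort whose positive-answer pattern
reproduces them exactly, which exercises the event-count aggregation against
known totals.
"""

from __future__ import annotations

from .model import (
    BEHAVIORS,
    BehaviorTriplet,
    ClinicalExam,
    EMADiary,
    LikertResponse,
    ParticipantRecord,
    Source,
    Stage,
)

__all__ = ["PILOT_EVENT_COUNTS", "pilot_event_cohort"]

#: Participants perceiving each behavior, per source, as printed in the pilot:
#: {stage: {behavior: (R1, R2, SR)}}.  Row totals follow by summation.
PILOT_EVENT_COUNTS: dict[Stage, dict[str, tuple[int, int, int]]] = {
    Stage.TEST: {
        "grinding": (1, 0, 4),
        "clenching": (1, 5, 5),
        "bracing_thrusting": (3, 4, 3),
    },
    Stage.RETEST: {
        "grinding": (0, 0, 3),
        "clenching": (2, 2, 3),
        "bracing_thrusting": (2, 2, 1),
    },
}

_SOURCE_ORDER = (Source.R1, Source.R2, Source.SR)


def pilot_event_cohort(stage: Stage = Stage.TEST, n: int = 10) -> list[ParticipantRecord]:
    """Synthetic cohort reproducing the pilot's per-source event counts.

    For each (behavior, source) cell with count c, the first c of the n
    participants answer "sometimes" on that question and the rest "never";
    diaries and exams are left empty.  Per-cell counts — and hence the row
    totals — of ``aggregate_event_counts`` then equal the printed table.
    """
    counts = PILOT_EVENT_COUNTS[stage]
    if any(c > n for row in counts.values() for c in row):
        raise ValueError(f"cohort of {n} cannot reproduce counts {counts}")
    cohort = []
    for i in range(n):
        triplets = {}
        for j, source in enumerate(_SOURCE_ORDER):
            answers = [
                LikertResponse.SOMETIMES
                if i < counts[behavior][j]
                else LikertResponse.NEVER
                for behavior in BEHAVIORS
            ]
            triplets[source] = BehaviorTriplet(source, *answers)
        cohort.append(
            ParticipantRecord(
                participant_id=f"F{i + 1:02d}",
                age_years=10,
                stage=stage,
                r1=triplets[Source.R1],
                sr=triplets[Source.SR],
                r2=triplets[Source.R2],
                ema=EMADiary.empty(),
                exam=ClinicalExam(),
            )
        )
    return cohort
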