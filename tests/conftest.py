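import numpy as np
import pytest

from abit.model import (
    BehaviorTriplet,
    ClinicalExam,
    EMADiary,
    LikertResponse,
    ParticipantRecord,
    Source,
    Stage,
)

SCORE_TO_LABEL = ["never", "almost_never", "sometimes", "most_of_time", "always"]


def triplet(source: Source, *answers) -> BehaviorTriplet:
    """Build a triplet from labels, LikertResponse values, or 0-4 scores."""
    parsed = []
    for a in answers:
        if isinstance(a, LikertResponse):
            parsed.append(a)
        elif isinstance(a, (int, np.integer)):
            parsed.append(LikertResponse(SCORE_TO_LABEL[a]))
        else:
            parsed.append(LikertResponse.from_label(a))
    return BehaviorTriplet(source, *parsed)


def diary_from_days(slots_per_day) -> EMADiary:
    """A diary painting the first k slots of each day, k given per day."""
    grid = np.zeros((7, 6), dtype=bool)
    for day, k in enumerate(slots_per_day):
        grid[day, :k] = True
    return EMADiary(grid)


def make_record(
    participant_id="P001",
    age_years=10,
    stage=Stage.TEST,
    r1=None,
    sr=None,
    r2=None,
    ema=None,
    exam=None,
    sb_reported=None,
) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=participant_id,
        age_years=age_years,
        stage=stage,
        r1=r1 or triplet(Source.R1, 0, 0, 0),
        sr=sr or triplet(Source.SR, 0, 0, 0),
        r2=r2 or triplet(Source.R2, 0, 0, 0),
        ema=ema or EMADiary.empty(),
        exam=exam or ClinicalExam(),
        sb_reported=sb_reported,
    )


@pytest.fixture
def blank_record():
    return make_record()
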