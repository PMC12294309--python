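"""Score a single child's administration and read off the AB Spectrum.

Builds one participant record by hand — parent report with occasional
clenching, a diary painted on four days, and a clinical exam with one
finding on each side — then scores every component and classifies it.
"""

import numpy as np

from abit import (
    BehaviorTriplet,
    ClinicalExam,
    EMADiary,
    LikertResponse as L,
    ParticipantRecord,
    Source,
    Stage,
    classify_record,
    score_record,
)

grid = np.zeros((7, 6), dtype=bool)
grid[0, 0] = grid[2, 1] = grid[3, 0] = grid[5, 2] = True  # 4 painted days

record = ParticipantRecord(
    participant_id="demo-01",
    age_years=9,
    stage=Stage.TEST,
    r1=BehaviorTriplet(Source.R1, L.NEVER, L.SOMETIMES, L.ALMOST_NEVER),
    sr=BehaviorTriplet(Source.SR, L.NEVER, L.ALMOST_NEVER, L.NEVER),
    r2=BehaviorTriplet(Source.R2, L.NEVER, L.MOST_OF_TIME, L.NEVER),
    ema=EMADiary(grid),
    exam=ClinicalExam(masseter_hypertrophy=True, tongue_indentation=True),
)

for name, score in score_record(record).items():
    print(f"{name:>4}: raw {score.raw_sum:>2}  status {score.status.value}")

result = classify_record(record)
print(f"\nspectrum total: {result.total}")
print(f"categories:     {result.label}")
print(
    "\nThe two parent reports (3 points each) plus the 4-day diary (4 points) put the"
    "\nchild in the combined report+EMA category; the self-report's lone"
    "\n'almost never' is null and contributes nothing; the clinical pair"
    "\n(1 intraoral + 1 extraoral finding) adds its points and the CA category."
)
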