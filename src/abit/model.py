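"""Domain types for ABIT administrations.

The Awake Bruxism Identification Tool (ABIT) screens children aged 8-12 for
awake bruxism by combining three 3-question Likert instruments (parents'
report R1, child self-report SR, parents' report after guided observation R2),
a 7-day analog ecological-momentary-assessment (EMA) painting diary, and a
clinical examination (extraoral muscle hypertrophy plus intraoral soft-tissue
markers, with per-tooth wear grades recorded as complementary data).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "DK",
    "LikertResponse",
    "Source",
    "Stage",
    "BehaviorTriplet",
    "EMADiary",
    "ClinicalExam",
    "ParticipantRecord",
    "BEHAVIORS",
    "ICA_FINDINGS",
    "ECA_FINDINGS",
    "WEAR_GRADES",
]

#: Sentinel score for a "don't know" answer; excluded from every sum.
DK = "DK"

#: The three awake-bruxism behaviors each triplet asks about, in question order.
BEHAVIORS = ("grinding", "clenching", "bracing_thrusting")

#: Intraoral findings scoring one ICA point each.
ICA_FINDINGS = (
    "buccal_hyperkeratosis_linea_alba",
    "labial_hyperkeratosis",
    "labial_indentation",
    "tongue_indentation",
    "buccal_indentation",
)

#: Extraoral findings scoring one ECA point each.
ECA_FINDINGS = ("masseter_hypertrophy", "temporal_hypertrophy")

#: Legal tooth-wear grades (five-point ordinal scale).
WEAR_GRADES = (0, 1, 2, 3, 4)


class LikertResponse(enum.Enum):
    """Five-point frequency scale plus a scoreless "don't know" option."""

    NEVER = "never"
    ALMOST_NEVER = "almost_never"
    SOMETIMES = "sometimes"
    MOST_OF_TIME = "most_of_time"
    ALWAYS = "always"
    DONT_KNOW = "dont_know"

    @property
    def score(self) -> int | str:
        """0-4 for frequency labels; the DK sentinel for don't-know."""
        if self is LikertResponse.DONT_KNOW:
            return DK
        return _LIKERT_POINTS[self]

    @classmethod
    def from_label(cls, label: str) -> "LikertResponse":
        """Parse a cell value (lowercase label, or the literal ``DK``)."""
        if label == DK:
            return cls.DONT_KNOW
        try:
            return cls(label)
        except ValueError:
            raise ValueError(f"unknown Likert label {label!r}") from None


_LIKERT_POINTS = {
    LikertResponse.NEVER: 0,
    LikertResponse.ALMOST_NEVER: 1,
    LikertResponse.SOMETIMES: 2,
    LikertResponse.MOST_OF_TIME: 3,
    LikertResponse.ALWAYS: 4,
}


class Source(enum.Enum):
    """Which administration a behavior triplet comes from."""

    R1 = "R1"
    SR = "SR"
    R2 = "R2"


class Stage(enum.Enum):
    """Test or 15-day retest administration of the whole tool."""

    TEST = "test"
    RETEST = "retest"


@dataclass(frozen=True)
class BehaviorTriplet:
    """One administration of the three behavior questions.

    Question order is fixed: (1) teeth grinding, (2) teeth clenching,
    (3) mandible bracing/thrusting.
    """

    source: Source
    grinding: LikertResponse
    clenching: LikertResponse
    bracing_thrusting: LikertResponse

    @property
    def responses(self) -> tuple[LikertResponse, LikertResponse, LikertResponse]:
        return (self.grinding, self.clenching, self.bracing_thrusting)


@dataclass(frozen=True, eq=False)
class EMADiary:
    """7-day x 6-slot painting grid; a painted emoji marks one perceived event.

    Days are study days 1-7 (day 1 = first day after the initial interview),
    not calendar weekdays.
    """

    grid: np.ndarray  # (7, 6) bool

    def __eq__(self, other) -> bool:
        if not isinstance(other, EMADiary):
            return NotImplemented
        return np.array_equal(self.grid, other.grid)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.shape != (7, 6):
            raise ValueError(f"EMA grid must be 7x6, got {g.shape}")
        object.__setattr__(self, "grid", g)

    @classmethod
    def empty(cls) -> "EMADiary":
        return cls(np.zeros((7, 6), dtype=bool))

    @property
    def painted_slots(self) -> int:
        return int(self.grid.sum())

    @property
    def days_with_paintings(self) -> int:
        return int(self.grid.any(axis=1).sum())


@dataclass(frozen=True)
class ClinicalExam:
    """Extraoral (ECA) and intraoral (ICA) findings plus tooth-wear grades.

    Each present finding scores one point.  Tooth wear is complementary data
    only and never enters any score; keys are FDI two-digit tooth identifiers.
    """

    masseter_hypertrophy: bool = False
    temporal_hypertrophy: bool = False
    buccal_hyperkeratosis_linea_alba: bool = False
    labial_hyperkeratosis: bool = False
    labial_indentation: bool = False
    tongue_indentation: bool = False
    buccal_indentation: bool = False
    tooth_wear: dict[str, int] = field(default_factory=dict)

    @property
    def ica_findings(self) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in ICA_FINDINGS)

    @property
    def eca_findings(self) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in ECA_FINDINGS)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant-stage administration of the full tool.

    ``sb_reported`` carries the anamnesis sleep-bruxism question; it is
    metadata only and never enters any score.
    """

    participant_id: str
    age_years: int
    stage: Stage
    r1: BehaviorTriplet
    sr: BehaviorTriplet
    r2: BehaviorTriplet
    ema: EMADiary
    exam: ClinicalExam
    sb_reported: bool | None = None

    def triplet(self, source: Source) -> BehaviorTriplet:
        return {Source.R1: self.r1, Source.SR: self.sr, Source.R2: self.r2}[source]


@dataclass(frozen=True)
class ValidationFinding:
    """One invariant violation (or warning) on a participant record."""

    field: str
    rule: str
    message: str
    severity: str = "error"  # "error" | "warning"


def validate_record(record: ParticipantRecord) -> list[ValidationFinding]:
    """Check a parsed record against the instrument's invariants.

    Returns one finding per violation; an empty list means the record is
    well-formed.  Never mutates the record.  All-DK triplets are legal but
    flagged with a warning finding, since they carry no information.
    """
    findings: list[ValidationFinding] = []
    if not 8 <= record.age_years <= 12:
        findings.append(
            ValidationFinding(
                "age_years",
                "age_range",
                f"age_years={record.age_years} outside the instrument's 8-12 range",
            )
        )
    for attr, expected in (("r1", Source.R1), ("sr", Source.SR), ("r2", Source.R2)):
        triplet = getattr(record, attr)
        if triplet.source is not expected:
            findings.append(
                ValidationFinding(
                    attr,
                    "source_slot",
                    f"{attr} slot holds a {triplet.source.value} triplet",
                )
            )
        if all(r is LikertResponse.DONT_KNOW for r in triplet.responses):
            findings.append(
                ValidationFinding(
                    attr,
                    "all_dont_know",
                    f"{attr}: all three answers are don't-know; triplet carries no score",
                    severity="warning",
                )
            )
    for tooth, grade in record.exam.tooth_wear.items():
        if grade not in WEAR_GRADES:
            findings.append(
                ValidationFinding(
                    "tooth_wear",
                    "wear_grade_scale",
                    f"tooth {tooth}: grade {grade} outside the 0-4 ordinal scale",
                )
            )
    return findings


def record_fields() -> list[str]:
    """Names of the scalar clinical-finding fields, in declaration order."""
    return [f.name for f in fields(ClinicalExam) if f.name != "tooth_wear"]
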