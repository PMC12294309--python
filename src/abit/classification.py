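"""AB Spectrum composition and identification categories.

The spectrum total sums the six component contributions.  A component
contributes its raw point sum when positive and nothing when zero or null:
null scores are grouped with zero under "Not AB", so letting their points
accumulate could give a "Not AB" child a nonzero spectrum.  The one exception
to contribution-follows-status is the clinical pair: ICA and ECA points enter
the total whenever present, but the clinical *category* requires findings on
both sides, because isolated clinical markers lack predictive power.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .instrument import InstrumentDefinition, default_instrument
from .scoring import ComponentScore, Status

__all__ = [
    "Category",
    "SpectrumResult",
    "component_contribution",
    "compute_spectrum",
    "max_spectrum",
    "classify_record",
]


class Category(enum.Enum):
    """Identification categories of the AB Spectrum."""

    NOT_AB = "Not AB"
    AB_R_SR = "AB based on R/SR"
    AB_R_SR_EMA = "AB based on R/SR and EMA"
    AB_EMA = "AB based on EMA"
    AB_CA = "AB based on CA"


#: Presentation order for combined labels (strongest evidence first).
_LABEL_ORDER = (
    Category.AB_R_SR_EMA,
    Category.AB_R_SR,
    Category.AB_EMA,
    Category.AB_CA,
    Category.NOT_AB,
)


@dataclass(frozen=True)
class SpectrumResult:
    """Per-component contributions, spectrum total, and assigned categories."""

    contributions: dict[str, int]
    total: int
    categories: frozenset[Category]

    @property
    def label(self) -> str:
        return " + ".join(c.value for c in _LABEL_ORDER if c in self.categories)


def component_contribution(
    score: ComponentScore, instrument: InstrumentDefinition | None = None
) -> int:
    """Points a component adds to the spectrum: raw sum if positive, else 0."""
    instrument = instrument or default_instrument()
    cap = instrument[score.component].score_max
    if score.raw_sum > cap:
        raise ValueError(
            f"{score.component} raw_sum {score.raw_sum} exceeds declared max {cap}"
        )
    return score.raw_sum if score.status is Status.POSITIVE else 0


def compute_spectrum(
    scores: dict[str, ComponentScore],
    ca_positive: bool,
    instrument: InstrumentDefinition | None = None,
) -> SpectrumResult:
    """Compose six component scores into an AB Spectrum result.

    Category rules: any positive triplet (R1/SR/R2) gives report/self-report
    evidence; that evidence plus a positive EMA upgrades to the combined
    report+EMA category (replacing the bare report category); a positive EMA
    without report evidence stands alone; the clinical category needs the
    ICA-and-ECA conjunction and combines with any other.  A record with no
    category is "Not AB".
    """
    instrument = instrument or default_instrument()
    contributions = {
        name: component_contribution(score, instrument) for name, score in scores.items()
    }
    report_positive = any(
        scores[c].status is Status.POSITIVE for c in ("R1", "SR", "R2") if c in scores
    )
    ema_positive = "EMA" in scores and scores["EMA"].status is Status.POSITIVE

    categories: set[Category] = set()
    if report_positive and ema_positive:
        categories.add(Category.AB_R_SR_EMA)
    elif report_positive:
        categories.add(Category.AB_R_SR)
    elif ema_positive:
        categories.add(Category.AB_EMA)
    if ca_positive:
        categories.add(Category.AB_CA)
    if not categories:
        categories.add(Category.NOT_AB)

    return SpectrumResult(
        contributions=contributions,
        total=sum(contributions.values()),
        categories=frozenset(categories),
    )


def max_spectrum(instrument: InstrumentDefinition | None = None) -> int:
    """Maximum attainable spectrum total: the sum of component maxima.

    For the default instrument this is 86 (3x12 + 6 + 2 + 42).  The published
    description rounds the range up to "0 to 96"; the attainable sum is what
    this function reports.
    """
    instrument = instrument or default_instrument()
    return sum(c.spectrum_max for c in instrument.components)


def classify_record(record, instrument: InstrumentDefinition | None = None) -> SpectrumResult:
    """Convenience: score a full participant record and compose its spectrum."""
    from .scoring import score_clinical, score_record

    scores = score_record(record)
    _, _, ca_positive = score_clinical(record.exam)
    return compute_spectrum(scores, ca_positive, instrument)
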