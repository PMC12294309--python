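"""Instrument definition: component score ranges, cut-offs and spectrum maxima.

The AB Spectrum sums six component contributions — the three behavior-question
triplets (R1, SR, R2, up to 12 points each: three questions scored 0-4), the
intraoral (ICA, up to 6) and extraoral (ECA, up to 2) clinical assessments,
and the 42-slot EMA diary.

Two published quirks of the instrument are carried as-is.  The declared ICA
maximum is 6 although only five intraoral findings are named; a sixth
configurable finding slot is permitted by the definition but ships disabled.
And the instrument's headline description gives the AB Spectrum a 0-96 range,
although the declared per-component maxima sum to 86 (36 + 6 + 2 + 42); this
package treats the component maxima as authoritative — the scoring rules
derive from them — so ``max_spectrum`` reports the attainable 86, and the
printed 96 is regarded as a publication erratum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

__all__ = ["ComponentDefinition", "InstrumentDefinition", "default_instrument"]

COMPONENTS = ("R1", "SR", "R2", "ICA", "ECA", "EMA")


@dataclass(frozen=True)
class ComponentDefinition:
    """Score range, positivity cut-off and spectrum maximum for one component."""

    component: str
    score_min: int
    score_max: int
    cutoff_rule: str
    spectrum_max: int

    def to_dict(self) -> dict:
        return {
            "name": self.component,
            "score_min": self.score_min,
            "score_max": self.score_max,
            "cutoff": self.cutoff_rule,
            "spectrum_max": self.spectrum_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComponentDefinition":
        return cls(d["name"], d["score_min"], d["score_max"], d["cutoff"], d["spectrum_max"])


@dataclass(frozen=True)
class InstrumentDefinition:
    """Ordered per-component definitions making up one instrument version."""

    components: tuple[ComponentDefinition, ...]

    def __getitem__(self, name: str) -> ComponentDefinition:
        for c in self.components:
            if c.component == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.component == name for c in self.components)

    def to_json(self) -> str:
        """Canonical JSON serialization (round-trips bit-exactly)."""
        return json.dumps(
            [c.to_dict() for c in self.components], indent=2, sort_keys=True
        ) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "InstrumentDefinition":
        return cls(tuple(ComponentDefinition.from_dict(d) for d in json.loads(text)))

    def sha256(self) -> str:
        """Short content hash, stamped into every output file header."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def default_instrument() -> InstrumentDefinition:
    """The published ABIT definition.

    Triplet cut-offs are "score >= 1, unless the only nonzero answer is a
    single 'almost never' (null)"; clinical cut-offs are ">= 1 finding, valid
    only when both ICA and ECA are above 0"; the EMA cut-off is ">= 4 days
    with paintings".
    """
    return InstrumentDefinition(
        (
            ComponentDefinition("R1", 0, 12, ">=1, null if single almost-never", 12),
            ComponentDefinition("SR", 0, 12, ">=1, null if single almost-never", 12),
            ComponentDefinition("R2", 0, 12, ">=1, null if single almost-never", 12),
            ComponentDefinition("ICA", 0, 6, ">=1, valid only with ECA>=1", 6),
            ComponentDefinition("ECA", 0, 2, ">=1, valid only with ICA>=1", 2),
            ComponentDefinition("EMA", 0, 42, ">=4 days with paintings", 42),
        )
    )
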