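"""Cohort file formats: the participant-record CSV/JSON-lines dialects and
the derived scores / classification / event-count tables.

The CSV dialect is UTF-8, comma-separated, one row per participant-stage,
with a required header row.  Likert cells hold the lowercase labels or the
literal ``DK``; the EMA grid is 42 columns ``d1s1`` … ``d7s6`` holding 0/1;
clinical findings are 0/1 columns; tooth wear is a semicolon-delimited
``tooth:grade`` list.  A JSON-lines dialect with nested objects is accepted
interchangeably (detected by a ``.json``/``.jsonl`` extension).

Every output file starts with a ``#`` header comment carrying the tool
version, the instrument-definition hash, and the seed when one applies;
readers skip comment lines.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .classification import classify_record
from .instrument import InstrumentDefinition, default_instrument
from .model import (
    BEHAVIORS,
    BehaviorTriplet,
    ClinicalExam,
    EMADiary,
    LikertResponse,
    ParticipantRecord,
    Source,
    Stage,
    ECA_FINDINGS,
    ICA_FINDINGS,
)
from .scoring import aggregate_event_counts, score_clinical, score_record

import numpy as np

__all__ = [
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "cohort_to_csv",
    "scores_frame",
    "classification_frame",
    "write_table",
    "EXPECTED_COLUMNS",
]


class CohortFormatError(ValueError):
    """A malformed cohort file; the message names row, column and token."""


_EMA_COLUMNS = [f"d{d}s{s}" for d in range(1, 8) for s in range(1, 7)]
_TRIPLET_COLUMNS = [
    f"{src}_{behavior}" for src in ("r1", "sr", "r2") for behavior in BEHAVIORS
]
_FINDING_COLUMNS = list(ICA_FINDINGS) + list(ECA_FINDINGS)

EXPECTED_COLUMNS = (
    ["participant_id", "age_years", "stage", "sb_reported"]
    + _TRIPLET_COLUMNS
    + _EMA_COLUMNS
    + _FINDING_COLUMNS
    + ["tooth_wear"]
)


def _header_comment(seed: int | None, instrument: InstrumentDefinition | None) -> str:
    instrument = instrument or default_instrument()
    line = f"# abit v{__version__} instrument={instrument.sha256()}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _parse_likert(token: str, row: int, column: str) -> LikertResponse:
    try:
        return LikertResponse.from_label(token)
    except ValueError:
        raise CohortFormatError(
            f"row {row}, column {column!r}: unknown Likert label {token!r}"
        ) from None


def _parse_binary(token: str, row: int, column: str) -> bool:
    if token in ("0", "1"):
        return token == "1"
    raise CohortFormatError(
        f"row {row}, column {column!r}: expected 0/1, got {token!r}"
    )


def _parse_wear(token: str, row: int) -> dict[str, int]:
    wear: dict[str, int] = {}
    if not token:
        return wear
    for pair in token.split(";"):
        try:
            tooth, grade = pair.split(":")
            wear[tooth.strip()] = int(grade)
        except ValueError:
            raise CohortFormatError(
                f"row {row}, column 'tooth_wear': malformed pair {pair!r}"
            ) from None
    return wear


def _record_from_row(row: dict[str, str], rownum: int) -> ParticipantRecord:
    try:
        age = int(row["age_years"])
    except ValueError:
        raise CohortFormatError(
            f"row {rownum}, column 'age_years': not an integer: {row['age_years']!r}"
        ) from None
    try:
        stage = Stage(row["stage"])
    except ValueError:
        raise CohortFormatError(
            f"row {rownum}, column 'stage': expected test/retest, got {row['stage']!r}"
        ) from None

    triplets = {}
    for src_key, source in (("r1", Source.R1), ("sr", Source.SR), ("r2", Source.R2)):
        answers = [
            _parse_likert(row[f"{src_key}_{b}"], rownum, f"{src_key}_{b}")
            for b in BEHAVIORS
        ]
        triplets[src_key] = BehaviorTriplet(source, *answers)

    grid = np.zeros((7, 6), dtype=bool)
    for d in range(7):
        for s in range(6):
            col = f"d{d + 1}s{s + 1}"
            grid[d, s] = _parse_binary(row[col], rownum, col)

    findings = {
        name: _parse_binary(row[name], rownum, name) for name in _FINDING_COLUMNS
    }
    sb_token = row.get("sb_reported", "")
    sb = None if sb_token == "" else _parse_binary(sb_token, rownum, "sb_reported")

    return ParticipantRecord(
        participant_id=row["participant_id"],
        age_years=age,
        stage=stage,
        r1=triplets["r1"],
        sr=triplets["sr"],
        r2=triplets["r2"],
        ema=EMADiary(grid),
        exam=ClinicalExam(tooth_wear=_parse_wear(row["tooth_wear"], rownum), **findings),
        sb_reported=sb,
    )


def _read_csv(path: Path) -> list[ParticipantRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    header = reader.fieldnames or []
    missing = [c for c in EXPECTED_COLUMNS if c not in header]
    extra = [c for c in header if c not in EXPECTED_COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected columns: {', '.join(extra)}")
        raise CohortFormatError("; ".join(parts))
    return [_record_from_row(row, i + 2) for i, row in enumerate(reader)]


def _record_from_json(obj: dict, rownum: int) -> ParticipantRecord:
    """Flatten one nested JSON-lines object onto the CSV cell layout."""
    flat: dict[str, str] = {
        "participant_id": str(obj.get("participant_id", "")),
        "age_years": str(obj.get("age_years", "")),
        "stage": str(obj.get("stage", "")),
        "sb_reported": (
            "" if obj.get("sb_reported") is None else str(int(obj["sb_reported"]))
        ),
    }
    for src in ("r1", "sr", "r2"):
        block = obj.get(src, {})
        for b in BEHAVIORS:
            flat[f"{src}_{b}"] = str(block.get(b, ""))
    grid = obj.get("ema", [])
    if len(grid) != 7 or any(len(day) != 6 for day in grid):
        raise CohortFormatError(f"row {rownum}: 'ema' must be a 7x6 grid")
    for d in range(7):
        for s in range(6):
            flat[f"d{d + 1}s{s + 1}"] = str(int(grid[d][s]))
    exam = obj.get("exam", {})
    for name in _FINDING_COLUMNS:
        flat[name] = str(int(bool(exam.get(name, False))))
    wear = exam.get("tooth_wear", {})
    flat["tooth_wear"] = ";".join(f"{t}:{g}" for t, g in sorted(wear.items()))
    return _record_from_row(flat, rownum)


def _read_jsonl(path: Path) -> list[ParticipantRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortFormatError(f"row {i}: invalid JSON: {exc}") from None
            records.append(_record_from_json(obj, i))
    return records


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort file (CSV or JSON-lines, by extension)."""
    path = Path(path)
    if path.suffix in (".json", ".jsonl"):
        return _read_jsonl(path)
    return _read_csv(path)


def _row_from_record(record: ParticipantRecord) -> list[str]:
    row = [
        record.participant_id,
        str(record.age_years),
        record.stage.value,
        "" if record.sb_reported is None else str(int(record.sb_reported)),
    ]
    for triplet in (record.r1, record.sr, record.r2):
        for response in triplet.responses:
            row.append(
                "DK" if response is LikertResponse.DONT_KNOW else response.value
            )
    row.extend(str(int(v)) for v in record.ema.grid.ravel())
    for name in _FINDING_COLUMNS:
        row.append(str(int(getattr(record.exam, name))))
    row.append(";".join(f"{t}:{g}" for t, g in sorted(record.exam.tooth_wear.items())))
    return row


def cohort_to_csv(
    cohort: list[ParticipantRecord],
    seed: int | None = None,
    instrument: InstrumentDefinition | None = None,
) -> str:
    """Render a cohort to the canonical CSV text (deterministic byte-for-byte)."""
    buf = io.StringIO()
    buf.write(_header_comment(seed, instrument))
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(EXPECTED_COLUMNS)
    for record in cohort:
        writer.writerow(_row_from_record(record))
    return buf.getvalue()


def write_cohort(
    path: str | Path,
    cohort: list[ParticipantRecord],
    seed: int | None = None,
    instrument: InstrumentDefinition | None = None,
) -> None:
    Path(path).write_text(cohort_to_csv(cohort, seed, instrument), encoding="utf-8")


def scores_frame(cohort: list[ParticipantRecord]) -> pd.DataFrame:
    """Per-participant-stage component scores (one row per record)."""
    rows = []
    for record in cohort:
        scores = score_record(record)
        _, _, ca_positive = score_clinical(record.exam)
        row: dict = {"participant_id": record.participant_id, "stage": record.stage.value}
        for name in ("R1", "SR", "R2"):
            row[f"{name.lower()}_sum"] = scores[name].raw_sum
            row[f"{name.lower()}_status"] = scores[name].status.value
            row[f"{name.lower()}_dk"] = scores[name].dk_count
        row["ica_sum"] = scores["ICA"].raw_sum
        row["eca_sum"] = scores["ECA"].raw_sum
        row["ca_positive"] = int(ca_positive)
        row["ema_sum"] = scores["EMA"].raw_sum
        row["ema_days"] = scores["EMA"].days_with_paintings
        row["ema_status"] = scores["EMA"].status.value
        rows.append(row)
    return pd.DataFrame(rows)


def classification_frame(
    cohort: list[ParticipantRecord], instrument: InstrumentDefinition | None = None
) -> pd.DataFrame:
    """Per-record spectrum contributions, total and category label."""
    rows = []
    for record in cohort:
        result = classify_record(record, instrument)
        row = {"participant_id": record.participant_id, "stage": record.stage.value}
        for name, points in result.contributions.items():
            row[f"{name.lower()}_points"] = points
        row["total"] = result.total
        row["label"] = result.label
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(
    path: str | Path,
    frame: pd.DataFrame,
    seed: int | None = None,
    instrument: InstrumentDefinition | None = None,
    index: bool = False,
) -> None:
    """Write a derived table as CSV under the standard header comment."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(seed, instrument))
        frame.to_csv(fh, index=index, lineterminator="\n")


def event_counts_frame(cohort: list[ParticipantRecord], stage: Stage) -> pd.DataFrame:
    table = aggregate_event_counts(cohort, stage)
    table.index.name = "behavior"
    return table
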