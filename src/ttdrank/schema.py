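"""Typed representation, validation and querying of TTD evidence tables.

A TTD (targeted-therapy database) table holds one curated study finding per
row: a molecule (in a molecular state) linked to a drug through an efficacy,
synergism or toxicity relationship, together with the hypothesis direction
the study supports (+1 favourable, -1 unfavourable, 0 no effect), the
experimental model that produced the finding, and an optional case count.

The canonical interchange format is UTF-8 delimited text with the fifteen
column headers listed in :data:`CANONICAL_COLUMNS`.  The spreadsheet
colour-coding of the relationship direction is encoded textually as
``class:direction`` (e.g. ``efficacy:sensitivity``); the ``H (hypothesis)``
column remains the authoritative integer direction and the two encodings
must agree.
"""

from __future__ import annotations

import csv
import enum
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

__all__ = [
    "CANONICAL_COLUMNS",
    "Direction",
    "ModelTier",
    "RecordIssue",
    "RelationshipClass",
    "TTDRecord",
    "filter_by_subtype",
    "normalize_text",
    "parse_ttd_table",
    "read_ttd_csv",
    "read_ttd_xlsx",
    "sort_records",
    "validate_table",
    "write_ttd_csv",
    "write_ttd_table",
]

#: Exact header of the canonical delimited-text dialect, in column order.
CANONICAL_COLUMNS = (
    "ID",
    "Source",
    "Molecule",
    "Alias (molecule)",
    "State (molecule)",
    "Modifier",
    "Alias (modifier)",
    "Relationship",
    "Drug (therapy)",
    "Alias (drug)",
    "Model",
    "H (hypothesis)",
    "Cases",
    "Reference",
    "Notes",
)

_WS = re.compile(r"\s+")


def normalize_text(value: str) -> str:
    """Trim, collapse internal whitespace and casefold, for grouping/sorting.

    Original casing is always preserved on output; normalization is applied
    only when comparing or grouping values.
    """
    return _WS.sub(" ", value.strip()).casefold()


class ModelTier(enum.IntEnum):
    """The seven experimental-model tiers, ordered by distance from the
    human in-vivo condition (lowest evidence first)."""

    ANIMAL_IN_VITRO = 0
    ANIMAL_IN_VIVO = 1
    HUMAN_IN_VITRO = 2
    HUMAN_XENOGRAFT = 3
    CLINICAL_STUDY = 4
    RANDOMIZED_CONTROLLED_TRIAL = 5
    META_ANALYSIS = 6

    @property
    def label(self) -> str:
        return _TIER_LABELS[self]

    @property
    def is_clinical(self) -> bool:
        """Clinical tiers are the ones for which case counts (patients) are
        recorded in curated tables."""
        return self >= ModelTier.CLINICAL_STUDY

    @classmethod
    def from_label(cls, label: str) -> "ModelTier":
        try:
            return _TIER_BY_NORMALIZED[normalize_text(label)]
        except KeyError:
            raise ValueError(f"unknown model label: {label!r}") from None


_TIER_LABELS = {
    ModelTier.ANIMAL_IN_VITRO: "animal in vitro",
    ModelTier.ANIMAL_IN_VIVO: "animal in vivo",
    ModelTier.HUMAN_IN_VITRO: "human in vitro",
    ModelTier.HUMAN_XENOGRAFT: "human xenograft",
    ModelTier.CLINICAL_STUDY: "clinical study/non-randomized trial",
    ModelTier.RANDOMIZED_CONTROLLED_TRIAL: "randomized controlled trial",
    ModelTier.META_ANALYSIS: "meta-analysis",
}
_TIER_BY_NORMALIZED = {normalize_text(v): k for k, v in _TIER_LABELS.items()}
# accepted synonyms seen in hand-edited tables
_TIER_BY_NORMALIZED.update(
    {
        normalize_text("animal, in vitro"): ModelTier.ANIMAL_IN_VITRO,
        normalize_text("animal, in vivo"): ModelTier.ANIMAL_IN_VIVO,
        normalize_text("human, in vitro"): ModelTier.HUMAN_IN_VITRO,
        normalize_text("clinical study"): ModelTier.CLINICAL_STUDY,
        normalize_text("non-randomized trial"): ModelTier.CLINICAL_STUDY,
        normalize_text("meta-analysis of clinical trials/studies"): ModelTier.META_ANALYSIS,
    }
)


class RelationshipClass(str, enum.Enum):
    EFFICACY = "efficacy"
    SYNERGISM = "synergism"
    TOXICITY = "toxicity"


class Direction(enum.IntEnum):
    """Hypothesis direction: +1 favourable for the patient, -1 unfavourable,
    0 no influence."""

    POSITIVE = 1
    NEGATIVE = -1
    NULL = 0


# textual direction words used in the Relationship cell, per class
_DIRECTION_WORDS = {
    RelationshipClass.EFFICACY: {
        Direction.POSITIVE: "sensitivity",
        Direction.NEGATIVE: "resistance",
        Direction.NULL: "null",
    },
    RelationshipClass.SYNERGISM: {
        Direction.POSITIVE: "synergism",
        Direction.NEGATIVE: "antagonism",
        Direction.NULL: "null",
    },
    RelationshipClass.TOXICITY: {
        Direction.POSITIVE: "decreased",
        Direction.NEGATIVE: "increased",
        Direction.NULL: "null",
    },
}
_DIRECTION_BY_WORD = {
    (cls, word): direction
    for cls, words in _DIRECTION_WORDS.items()
    for direction, word in words.items()
}


def format_relationship(relationship_class: RelationshipClass, direction: Direction) -> str:
    """Render the textual ``class:direction`` cell for the Relationship column."""
    return f"{relationship_class.value}:{_DIRECTION_WORDS[relationship_class][direction]}"


def parse_relationship(cell: str) -> tuple[RelationshipClass, Direction]:
    parts = normalize_text(cell).split(":")
    if len(parts) != 2:
        raise ValueError(f"relationship cell must be 'class:direction', got {cell!r}")
    try:
        cls = RelationshipClass(parts[0])
    except ValueError:
        raise ValueError(f"unknown relationship class: {parts[0]!r}") from None
    try:
        direction = _DIRECTION_BY_WORD[(cls, parts[1])]
    except KeyError:
        raise ValueError(
            f"unknown direction {parts[1]!r} for relationship class {cls.value!r}"
        ) from None
    return cls, direction


@dataclass
class TTDRecord:
    """One curated study finding (one row of a TTD table)."""

    id: int
    source: str
    molecule: str
    state: str
    relationship_class: RelationshipClass
    direction: Direction
    drug: str
    model: ModelTier
    hypothesis: int
    reference: str = ""
    notes: str = ""
    molecule_aliases: list[str] = field(default_factory=list)
    modifier: str | None = None
    modifier_aliases: list[str] = field(default_factory=list)
    drug_alias: str | None = None
    cases: int | None = None

    def copy(self) -> "TTDRecord":
        return replace(
            self,
            molecule_aliases=list(self.molecule_aliases),
            modifier_aliases=list(self.modifier_aliases),
        )


@dataclass(frozen=True)
class RecordIssue:
    """A validation finding; ``record_id`` 0 marks a table-level issue."""

    record_id: int
    severity: str  # "error" | "warning"
    message: str


_ALIAS_SEP = "; "


def _split_aliases(cell: str) -> list[str]:
    return [a.strip() for a in cell.split(";") if a.strip()]


def _record_errors(rec: TTDRecord) -> list[str]:
    """Row-level invariant violations (empty list means the row is well formed)."""
    errors: list[str] = []
    if rec.id <= 0:
        errors.append("ID must be a positive integer")
    if not rec.molecule.strip():
        errors.append("Molecule must be non-empty")
    if not rec.drug.strip():
        errors.append("Drug (therapy) must be non-empty")
    if rec.hypothesis != int(rec.direction):
        errors.append(
            "H (hypothesis) disagrees with the Relationship direction "
            f"({rec.hypothesis:+d} vs {int(rec.direction):+d})"
        )
    if rec.relationship_class is RelationshipClass.SYNERGISM and not (rec.modifier or "").strip():
        errors.append("Modifier is required for synergism records")
    if rec.cases is not None and rec.cases < 0:
        errors.append("Cases must be >= 0 when present")
    return errors


def _parse_row(row: dict[str, str], position: int) -> tuple[TTDRecord | None, list[RecordIssue]]:
    issues: list[RecordIssue] = []

    def err(record_id: int, message: str) -> None:
        issues.append(RecordIssue(record_id, "error", f"row {position}: {message}"))

    raw_id = (row.get("ID") or "").strip()
    try:
        rec_id = int(raw_id)
    except ValueError:
        err(0, f"ID {raw_id!r} is not an integer")
        return None, issues

    try:
        rel_class, direction = parse_relationship(row.get("Relationship") or "")
    except ValueError as exc:
        err(rec_id, str(exc))
        return None, issues

    try:
        model = ModelTier.from_label(row.get("Model") or "")
    except ValueError as exc:
        err(rec_id, str(exc))
        return None, issues

    raw_h = (row.get("H (hypothesis)") or "").replace("−", "-").strip()
    try:
        hypothesis = int(raw_h.lstrip("+") or "x")
    except ValueError:
        err(rec_id, f"H (hypothesis) must be +1, -1 or 0, got {raw_h!r}")
        return None, issues
    if hypothesis not in (-1, 0, 1):
        err(rec_id, f"H (hypothesis) must be +1, -1 or 0, got {raw_h!r}")
        return None, issues

    raw_cases = (row.get("Cases") or "").strip()
    cases: int | None = None
    if raw_cases:
        try:
            cases = int(raw_cases)
        except ValueError:
            err(rec_id, f"Cases must be an integer, got {raw_cases!r}")
            return None, issues

    rec = TTDRecord(
        id=rec_id,
        source=(row.get("Source") or "").strip(),
        molecule=(row.get("Molecule") or "").strip(),
        molecule_aliases=_split_aliases(row.get("Alias (molecule)") or ""),
        state=(row.get("State (molecule)") or "").strip(),
        modifier=(row.get("Modifier") or "").strip() or None,
        modifier_aliases=_split_aliases(row.get("Alias (modifier)") or ""),
        relationship_class=rel_class,
        direction=direction,
        drug=(row.get("Drug (therapy)") or "").strip(),
        drug_alias=(row.get("Alias (drug)") or "").strip() or None,
        model=model,
        hypothesis=hypothesis,
        cases=cases,
        reference=(row.get("Reference") or "").strip(),
        notes=(row.get("Notes") or "").strip(),
    )
    for message in _record_errors(rec):
        err(rec_id, message)
    if any(i.severity == "error" for i in issues):
        return None, issues
    return rec, issues


def parse_ttd_table(
    stream: TextIO | str, *, delimiter: str = ","
) -> tuple[list[TTDRecord], list[RecordIssue]]:
    """Parse a canonical delimited-text TTD table.

    Returns the well-formed records (input order preserved) and the list of
    issues.  Malformed rows are excluded and reported as error-severity
    issues; a missing mandatory column is a table-level error and no records
    are returned.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream, delimiter=delimiter)
    header = reader.fieldnames or []
    missing = [c for c in CANONICAL_COLUMNS if c not in header]
    if missing:
        return [], [
            RecordIssue(0, "error", f"missing mandatory column(s): {', '.join(missing)}")
        ]
    issues: list[RecordIssue] = []
    extra = [c for c in header if c not in CANONICAL_COLUMNS and c is not None]
    if extra:
        issues.append(RecordIssue(0, "warning", f"ignoring extra column(s): {', '.join(extra)}"))

    records: list[TTDRecord] = []
    seen_ids: dict[int, int] = {}
    for position, row in enumerate(reader, start=2):
        rec, row_issues = _parse_row(row, position)
        issues.extend(row_issues)
        if rec is None:
            continue
        if rec.id in seen_ids:
            issues.append(
                RecordIssue(
                    rec.id,
                    "error",
                    f"duplicate ID {rec.id}: rows {seen_ids[rec.id]} and {position}",
                )
            )
            continue
        seen_ids[rec.id] = position
        records.append(rec)
    return records, issues


def write_ttd_table(records: Iterable[TTDRecord], stream: TextIO, *, delimiter: str = ",") -> None:
    """Write records in the canonical dialect; ``parse_ttd_table`` round-trips
    the output field-for-field."""
    writer = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    writer.writerow(CANONICAL_COLUMNS)
    for rec in records:
        writer.writerow(
            [
                rec.id,
                rec.source,
                rec.molecule,
                _ALIAS_SEP.join(rec.molecule_aliases),
                rec.state,
                rec.modifier or "",
                _ALIAS_SEP.join(rec.modifier_aliases),
                format_relationship(rec.relationship_class, rec.direction),
                rec.drug,
                rec.drug_alias or "",
                rec.model.label,
                f"{rec.hypothesis:+d}" if rec.hypothesis else "0",
                "" if rec.cases is None else rec.cases,
                rec.reference,
                rec.notes,
            ]
        )


def read_ttd_csv(path, *, delimiter: str = ",") -> tuple[list[TTDRecord], list[RecordIssue]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return parse_ttd_table(fh, delimiter=delimiter)


def write_ttd_csv(records: Iterable[TTDRecord], path, *, delimiter: str = ",") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        write_ttd_table(records, fh, delimiter=delimiter)


def read_ttd_xlsx(path, *, sheet: str | int = 0) -> tuple[list[TTDRecord], list[RecordIssue]]:
    """Spreadsheet import adapter: degrades an XLSX sheet to the canonical
    record model (formatting, including any colour coding, is ignored; the
    textual Relationship and H columns are authoritative)."""
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb[wb.sheetnames[sheet]] if isinstance(sheet, int) else wb[sheet]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    for row in ws.iter_rows(values_only=True):
        writer.writerow(["" if v is None else v for v in row])
    wb.close()
    buf.seek(0)
    return parse_ttd_table(buf)


# --- synopsis-style querying ---------------------------------------------

_COLUMN_ACCESSORS = {
    "ID": lambda r: r.id,
    "Source": lambda r: normalize_text(r.source),
    "Molecule": lambda r: normalize_text(r.molecule),
    "Alias (molecule)": lambda r: normalize_text(_ALIAS_SEP.join(r.molecule_aliases)),
    "State (molecule)": lambda r: normalize_text(r.state),
    "Modifier": lambda r: normalize_text(r.modifier or ""),
    "Alias (modifier)": lambda r: normalize_text(_ALIAS_SEP.join(r.modifier_aliases)),
    "Relationship": lambda r: format_relationship(r.relationship_class, r.direction),
    "Drug (therapy)": lambda r: normalize_text(r.drug),
    "Alias (drug)": lambda r: normalize_text(r.drug_alias or ""),
    "Model": lambda r: int(r.model),
    "H (hypothesis)": lambda r: r.hypothesis,
    "Cases": lambda r: (r.cases is None, r.cases or 0),  # absent sorts last
    "Reference": lambda r: normalize_text(r.reference),
    "Notes": lambda r: normalize_text(r.notes),
}


def sort_records(records: Sequence[TTDRecord], keys: Sequence[str]) -> list[TTDRecord]:
    """Stable lexicographic sort on 1-3 canonical column names.

    Text keys compare case-insensitively after whitespace normalization;
    Model sorts by tier ordinal; absent Cases sort last.
    """
    if not 1 <= len(keys) <= 3:
        raise ValueError("sort requires between 1 and 3 keys")
    unknown = [k for k in keys if k not in _COLUMN_ACCESSORS]
    if unknown:
        raise ValueError(f"unknown sort key(s): {', '.join(unknown)}")
    accessors = [_COLUMN_ACCESSORS[k] for k in keys]
    return sorted(records, key=lambda r: tuple(a(r) for a in accessors))


def filter_by_subtype(
    records: Iterable[TTDRecord], tag: str, *, negate: bool = False
) -> list[TTDRecord]:
    """Records whose Notes begin with ``tag`` (case-insensitive); disease
    subtypes such as uveal melanoma are tagged this way at curation time.
    ``negate=True`` returns the complement."""
    if not tag.strip():
        raise ValueError("subtype tag must be non-empty")
    prefix = normalize_text(tag)
    return [r for r in records if normalize_text(r.notes).startswith(prefix) is not negate]


def validate_table(records: Sequence[TTDRecord]) -> list[RecordIssue]:
    """Aggregate all invariant violations across a record list.

    Case counts on non-clinical tiers are warnings, not errors: curated
    tables record cases only for clinical studies/trials, but a count on a
    preclinical record is suspicious rather than contradictory.
    """
    issues: list[RecordIssue] = []
    seen: dict[int, int] = {}
    for pos, rec in enumerate(records):
        for message in _record_errors(rec):
            issues.append(RecordIssue(rec.id, "error", message))
        if rec.id in seen:
            issues.append(
                RecordIssue(
                    rec.id,
                    "error",
                    f"duplicate ID {rec.id}: positions {seen[rec.id]} and {pos}",
                )
            )
        else:
            seen[rec.id] = pos
        if rec.cases is not None and not rec.model.is_clinical:
            issues.append(
                RecordIssue(
                    rec.id,
                    "warning",
                    f"cases={rec.cases} recorded for non-clinical model {rec.model.label!r}",
                )
            )
    return issues
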