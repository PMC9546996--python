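"""Assembly of per-event annotations from BIDS-style event files.

An events table (TSV with ``onset``/``duration`` columns) describes *when*
things happened; a JSON sidecar maps column values to HED strings describing
*what* happened. Assembly concatenates, for each row, the annotations
contributed by every annotated column, yielding one complete HED string per
event. Sidecar entries come in two kinds: *categorical* (a map from cell
value to annotation) and *value columns* (a single annotation containing one
``#`` placeholder replaced by the cell text).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import definitions as defs_mod
from . import strings as st
from .definitions import DefinitionSet
from .issues import (
    EMPTY_ANNOTATION,
    MISSING_ONSET_COLUMN,
    MULTIPLE_PLACEHOLDERS,
    NON_NUMERIC_ONSET,
    NON_TEXT_ANNOTATION,
    UNMAPPED_CATEGORY,
    WARNING,
    AssemblyError,
    HedSyntaxError,
    ValidationIssue,
)
from .schema import SchemaSet

NA = "n/a"


@dataclass
class EventRow:
    onset: float
    duration: Optional[float]
    columns: Dict[str, str]


@dataclass
class EventTable:
    rows: List[EventRow]
    column_order: List[str]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class AssembledEvent:
    """One event with its fully concatenated (but unexpanded) annotation."""

    onset: float
    duration: Optional[float]
    annotation: st.HedString
    row_index: int


class CategoricalEntry(dict):
    """cell value -> HED string text."""


@dataclass
class ValueEntry:
    """HED template with exactly one '#' placeholder."""

    template: str


@dataclass
class Sidecar:
    entries: Dict[str, Union[CategoricalEntry, ValueEntry]]
    metadata: dict = field(default_factory=dict)


def read_events(tsv: str) -> EventTable:
    """Parse events TSV text; ``n/a`` cells are preserved as missing.

    Rows are sorted by onset (stable). Raises :class:`AssemblyError` with
    MISSING_ONSET_COLUMN or NON_NUMERIC_ONSET (with the offending row number).
    """
    frame = pd.read_csv(io.StringIO(tsv), sep="\t", dtype=str,
                        keep_default_na=False)
    if "onset" not in frame.columns:
        raise AssemblyError(MISSING_ONSET_COLUMN,
                            f"columns present: {list(frame.columns)}")
    rows: List[EventRow] = []
    for i, rec in enumerate(frame.to_dict("records")):
        raw_onset = rec.get("onset", "").strip()
        try:
            onset = float(raw_onset)
        except ValueError:
            raise AssemblyError(
                NON_NUMERIC_ONSET,
                f"row {i}: onset {raw_onset!r} is not a number") from None
        if not math.isfinite(onset) or onset < 0:
            raise AssemblyError(
                NON_NUMERIC_ONSET,
                f"row {i}: onset {raw_onset!r} must be finite and >= 0")
        raw_dur = rec.get("duration", NA).strip()
        duration = None if raw_dur in (NA, "") else float(raw_dur)
        columns = {k: v for k, v in rec.items()
                   if k not in ("onset", "duration")}
        rows.append(EventRow(onset, duration, columns))
    rows.sort(key=lambda r: r.onset)
    return EventTable(rows, list(frame.columns))


def read_sidecar(text: str) -> Sidecar:
    """Parse sidecar JSON; entries are classified by '#' presence.

    Non-HED keys inside column entries (``Levels``, ``Description``...) are
    ignored; top-level keys without a ``HED`` member land in ``metadata``.
    """
    data = json.loads(text)
    entries: Dict[str, Union[CategoricalEntry, ValueEntry]] = {}
    metadata: dict = {}
    for col, spec in data.items():
        if not isinstance(spec, dict) or "HED" not in spec:
            metadata[col] = spec
            continue
        hed = spec["HED"]
        if isinstance(hed, dict):
            entry = CategoricalEntry()
            for value, annotation in hed.items():
                if not isinstance(annotation, str):
                    raise AssemblyError(
                        NON_TEXT_ANNOTATION,
                        f"{col}.{value}: annotation must be text")
                entry[value] = annotation
            entries[col] = entry
        elif isinstance(hed, str):
            if hed.count("#") != 1:
                raise AssemblyError(
                    MULTIPLE_PLACEHOLDERS,
                    f"{col}: value-column annotation must contain exactly "
                    f"one '#', found {hed.count('#')}")
            entries[col] = ValueEntry(hed)
        else:
            raise AssemblyError(NON_TEXT_ANNOTATION,
                                f"{col}: HED must be text or a value map")
    return Sidecar(entries, metadata)


def assemble(
    events: EventTable,
    sidecar: Sidecar,
    schemas: SchemaSet,
    defs: Optional[DefinitionSet] = None,
) -> Tuple[List[AssembledEvent], DefinitionSet, List[ValidationIssue]]:
    """Build one annotation per event row.

    Column contributions are concatenated in sorted column-name order, with a
    literal ``HED`` column (verbatim annotation text) last; ``n/a`` cells
    contribute nothing. Definition groups found anywhere are collected into
    the returned :class:`DefinitionSet` and removed from row annotations;
    rows carrying only definitions produce no event. Each remaining
    annotation is validated; issues carry the source row index.
    """
    defs = defs if defs is not None else DefinitionSet()
    issues: List[ValidationIssue] = []
    assembled: List[AssembledEvent] = []

    for idx, row in enumerate(events.rows):
        pieces: List[str] = []
        data_cols = sorted(c for c in row.columns if c != "HED")
        for col in data_cols:
            cell = row.columns.get(col, "").strip()
            if cell in ("", NA):
                continue
            entry = sidecar.entries.get(col)
            if entry is None:
                continue
            if isinstance(entry, CategoricalEntry):
                if cell not in entry:
                    issues.append(ValidationIssue(
                        UNMAPPED_CATEGORY,
                        f"column {col!r}: value {cell!r} has no annotation",
                        WARNING, row=idx))
                    continue
                pieces.append(entry[cell])
            else:
                pieces.append(entry.template.replace("#", cell))
        literal = row.columns.get("HED", "").strip()
        if literal and literal != NA:
            pieces.append(literal)

        text = ", ".join(pieces)
        if not text:
            issues.append(ValidationIssue(
                EMPTY_ANNOTATION, "row contributes no annotation",
                WARNING, row=idx))
            assembled.append(AssembledEvent(row.onset, row.duration,
                                            st.HedString(), idx))
            continue
        try:
            parsed = st.parse(text)
        except HedSyntaxError as exc:
            issue = exc.to_issue()
            issue.row = idx
            issues.append(issue)
            continue

        had_defs = bool(defs_mod.definition_groups(parsed))
        if had_defs:
            _, def_issues = defs_mod.collect_definitions([parsed], into=defs)
            for di in def_issues:
                di.row = idx
            issues.extend(def_issues)
            parsed = defs_mod.strip_definitions(parsed)
            if parsed.is_empty():
                continue  # pure definition carrier, not an event
        assembled.append(AssembledEvent(row.onset, row.duration, parsed, idx))

    # validate after full collection so forward Def references are legal
    names = defs.names()
    for ev in assembled:
        if ev.annotation.is_empty():
            continue
        for issue in st.validate_string(ev.annotation, schemas, names):
            issue.row = ev.row_index
            issues.append(issue)
    return assembled, defs, issues


def assembled_frame(assembled: Sequence[AssembledEvent],
                    schemas: SchemaSet) -> pd.DataFrame:
    """Tabular view with long- and short-form annotation columns."""
    records = []
    for ev in assembled:
        if ev.annotation.is_empty():
            long_text = short_text = ""
        else:
            long_text = st.to_long(ev.annotation, schemas).text()
            short_text = st.to_short(ev.annotation, schemas).text()
        records.append({
            "row": ev.row_index,
            "onset": ev.onset,
            "duration": NA if ev.duration is None else ev.duration,
            "HED_long": long_text,
            "HED_short": short_text,
        })
    return pd.DataFrame.from_records(
        records, columns=["row", "onset", "duration", "HED_long", "HED_short"])
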