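"""Issue records shared by schema linting and annotation validation.

All diagnostics in hedkit are value objects rather than exceptions: linting
and validation return lists of issues so callers can collect every problem in
one pass. Exceptions are reserved for malformed inputs that prevent building
a data structure at all (see :class:`HedError` subclasses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

# Severities
ERROR = "error"
WARNING = "warning"
INFO = "info"

# Schema lint codes
DUPLICATE_TERM = "DUPLICATE_TERM"
TOO_MANY_CHILDREN = "TOO_MANY_CHILDREN"
CHILD_COUNT_OUTSIDE_IDEAL = "CHILD_COUNT_OUTSIDE_IDEAL"
EMPTY_DESCRIPTION = "EMPTY_DESCRIPTION"
BAD_TERM_CHARS = "BAD_TERM_CHARS"

# String validation codes
UNBALANCED_PARENS = "UNBALANCED_PARENS"
EMPTY_TAG = "EMPTY_TAG"
TAG_NOT_FOUND = "TAG_NOT_FOUND"
INVALID_PARENT = "INVALID_PARENT"
AMBIGUOUS = "AMBIGUOUS"
INVALID_UNITS = "INVALID_UNITS"
VALUE_WITHOUT_PLACEHOLDER = "VALUE_WITHOUT_PLACEHOLDER"
DUPLICATE_TAG_IN_GROUP = "DUPLICATE_TAG_IN_GROUP"
DEF_UNDEFINED = "DEF_UNDEFINED"
DEF_SYNTAX = "DEF_SYNTAX"
DEF_DUPLICATE = "DEF_DUPLICATE"
EXTENSION_WARNING = "EXTENSION_WARNING"

# Event-table / sidecar codes
MISSING_ONSET_COLUMN = "MISSING_ONSET_COLUMN"
NON_NUMERIC_ONSET = "NON_NUMERIC_ONSET"
MULTIPLE_PLACEHOLDERS = "MULTIPLE_PLACEHOLDERS"
NON_TEXT_ANNOTATION = "NON_TEXT_ANNOTATION"
UNMAPPED_CATEGORY = "UNMAPPED_CATEGORY"
EMPTY_ANNOTATION = "EMPTY_ANNOTATION"

# Temporal scope codes
OFFSET_WITHOUT_ONSET = "OFFSET_WITHOUT_ONSET"
UNCLOSED_ONSET = "UNCLOSED_ONSET"


@dataclass
class LintIssue:
    """A problem found in a vocabulary schema, located by full node path."""

    code: str
    path: str
    detail: str
    severity: str = ERROR

    def to_json(self) -> str:
        return json.dumps(
            {"code": self.code, "severity": self.severity,
             "path": self.path, "detail": self.detail}
        )


@dataclass
class ValidationIssue:
    """A problem found in a HED string or event row.

    ``span`` holds character offsets into the original input text when known;
    ``row`` holds the event-table row index when the issue is row-scoped.
    """

    code: str
    detail: str
    severity: str = ERROR
    span: Optional[Tuple[int, int]] = None
    row: Optional[int] = None

    def to_json(self) -> str:
        rec = {"code": self.code, "severity": self.severity,
               "span": list(self.span) if self.span else None,
               "detail": self.detail}
        if self.row is not None:
            rec["row"] = self.row
        return json.dumps(rec)


def has_errors(issues) -> bool:
    return any(i.severity == ERROR for i in issues)


class HedError(Exception):
    """Base for unrecoverable input errors; carries a machine-readable code."""

    def __init__(self, code: str, detail: str):
        super().__init__(f"{code}: {detail}")
        self.code = code
        self.detail = detail


class SchemaParseError(HedError):
    """Malformed schema source (wiki or XML dialect)."""

    def __init__(self, detail: str, line: Optional[int] = None):
        if line is not None:
            detail = f"line {line}: {detail}"
        super().__init__("PARSE_ERROR", detail)
        self.line = line


class DuplicateTermError(HedError):
    def __init__(self, term: str, paths):
        super().__init__(
            DUPLICATE_TERM,
            f"term {term!r} appears at multiple paths: {', '.join(paths)}",
        )
        self.term = term
        self.paths = list(paths)


class ResolutionError(HedError):
    """A single tag could not be resolved against the schema set."""


class HedSyntaxError(HedError):
    """HED string text is ungrammatical (parens/commas)."""

    def __init__(self, code: str, detail: str, span: Tuple[int, int]):
        super().__init__(code, detail)
        self.span = span

    def to_issue(self) -> ValidationIssue:
        return ValidationIssue(self.code, self.detail, ERROR, self.span)


class DefinitionError(HedError):
    """Definition collection or expansion failed."""


class AssemblyError(HedError):
    """Event table or sidecar cannot be read."""
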