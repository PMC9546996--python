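"""Tag-based event search and time-locked epoch extraction.

Queries are boolean combinations of tag terms. A term matches an event when
any tag in the event's (long-form, context-included) annotation resolves to
the term's node or anywhere in its subtree — so the query ``2D-shape``
matches an event annotated ``.../2D-shape/Triangle``. Hits anchor epoch
windows ``[onset - pre, onset + post]`` for downstream time-locked analysis;
windows running past the recording span are flagged and dropped rather than
truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

from . import strings as st
from .assembly import AssembledEvent
from .definitions import split_marker
from .schema import SchemaSet, resolve_tag


# --- query expression tree ---

@dataclass
class Term:
    tag_text: str


@dataclass
class Not:
    operand: "Query"


@dataclass
class And:
    left: "Query"
    right: "Query"


@dataclass
class Or:
    left: "Query"
    right: "Query"


Query = Union[Term, Not, And, Or]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_query(text: str) -> Query:
    """Parse the query mini-language: terms, parentheses, AND / OR / NOT.

    Precedence is NOT > AND > OR; keywords are case-insensitive, anything
    else is a tag term.
    """
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Query:
        node = parse_and()
        while peek() is not None and peek().upper() == "OR":
            take()
            node = Or(node, parse_and())
        return node

    def parse_and() -> Query:
        node = parse_not()
        while peek() is not None and peek().upper() == "AND":
            take()
            node = And(node, parse_not())
        return node

    def parse_not() -> Query:
        if peek() is not None and peek().upper() == "NOT":
            take()
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> Query:
        tok = peek()
        if tok is None:
            raise ValueError("query ended unexpectedly")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError("unbalanced parenthesis in query")
            take()
            return node
        if tok == ")":
            raise ValueError("unmatched ')' in query")
        if tok.upper() in ("AND", "OR", "NOT"):
            raise ValueError(f"misplaced keyword {tok!r} in query")
        return Term(take())

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in query: {tokens[pos:]!r}")
    return node


def _event_tags(event: AssembledEvent, include_context: bool
                ) -> List[st.HedTag]:
    """All tags of the event, optionally skipping Event-context groups."""
    tags: List[st.HedTag] = []

    def visit(members) -> None:
        for m in members:
            if isinstance(m, st.HedTag):
                tags.append(m)
            else:
                if not include_context and any(
                        split_marker(t, "event-context") is not None
                        for t in m.tags()):
                    continue
                visit(m.members)

    visit(event.annotation.top)
    return tags


def matches(event: AssembledEvent, q: Query, schemas: SchemaSet,
            include_context: bool = True) -> bool:
    """Evaluate a query against one event's annotation.

    The annotation should be fully assembled for analysis (Defs expanded,
    Event-context inserted); tags are resolved on the fly as needed. A term
    carrying a value (``Experimental-trial/3``) additionally requires an
    exact value match; a bare term matches any value.
    """
    if isinstance(q, Not):
        return not matches(event, q.operand, schemas, include_context)
    if isinstance(q, And):
        return (matches(event, q.left, schemas, include_context)
                and matches(event, q.right, schemas, include_context))
    if isinstance(q, Or):
        return (matches(event, q.left, schemas, include_context)
                or matches(event, q.right, schemas, include_context))

    res = resolve_tag(schemas, q.tag_text)  # raises for unresolvable terms
    want_path = res.path.lower()
    want_ns = res.namespace
    want_value = res.value
    for tag in _event_tags(event, include_context):
        if not tag.is_resolved():
            try:
                tres = resolve_tag(schemas, tag.given_text)
            except Exception:
                continue
            path, ns, value = tres.path, tres.namespace, tres.value
        else:
            path, ns, value = tag.resolved_path, tag.namespace, tag.value
        if ns != want_ns:
            continue
        low = path.lower()
        if low == want_path or low.startswith(want_path + "/"):
            if want_value and value != want_value:
                continue
            return True
    return False


def search(events: Sequence[AssembledEvent], q: Query, schemas: SchemaSet,
           include_context: bool = True) -> List[int]:
    """Indices (into ``events``, onset order) of all matching events."""
    return [i for i, ev in enumerate(events)
            if matches(ev, q, schemas, include_context)]


@dataclass
class EpochSpec:
    """Window extent around an anchor event, in seconds (both >= 0)."""

    pre: float
    post: float

    def __post_init__(self) -> None:
        if self.pre < 0 or self.post < 0 or self.pre + self.post <= 0:
            raise ValueError("epoch window must have pre, post >= 0 and "
                             "pre + post > 0")


@dataclass
class Epoch:
    start: float
    end: float
    anchor_row: int


def extract_epochs(
    events: Sequence[AssembledEvent],
    hits: Sequence[int],
    spec: EpochSpec,
    record_span: Tuple[float, float],
) -> Tuple[List[Epoch], List[int]]:
    """Time windows ``[onset - pre, onset + post]`` around each hit.

    Returns (kept epochs, dropped hit indices). A window that would extend
    beyond ``record_span`` is dropped, not truncated: a partial epoch is not
    comparable to complete ones in time-locked averaging.
    """
    lo, hi = record_span
    kept: List[Epoch] = []
    dropped: List[int] = []
    for i in hits:
        ev = events[i]
        start = ev.onset - spec.pre
        end = ev.onset + spec.post
        if start < lo or end > hi:
            dropped.append(i)
        else:
            kept.append(Epoch(start, end, ev.row_index))
    return kept, dropped
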