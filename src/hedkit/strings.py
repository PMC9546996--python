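"""HED string parsing, canonicalization, validation, and form conversion.

A HED string is a comma-separated list of tags and parenthesized tag groups;
groups nest to arbitrary depth and bind modifiers to the items they modify.
Parsing is purely syntactic (no schema consulted); resolution against a
:class:`~hedkit.schema.SchemaSet` turns written short forms into full paths
and is required for validation, canonicalization, and conversion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple, Union

from . import schema as sc
from .issues import (
    DEF_SYNTAX,
    DEF_UNDEFINED,
    DUPLICATE_TAG_IN_GROUP,
    EMPTY_TAG,
    ERROR,
    EXTENSION_WARNING,
    INVALID_UNITS,
    UNBALANCED_PARENS,
    WARNING,
    HedSyntaxError,
    ResolutionError,
    ValidationIssue,
)


@dataclass
class HedTag:
    """One tag as written, plus its resolved identity once resolved.

    ``given_text`` is the text between separators as typed (namespace prefix
    included); ``resolved_path`` / ``value`` / ``units`` are filled in by
    :func:`resolve` and stay empty for unresolved tags.
    """

    given_text: str
    namespace: str = ""
    resolved_path: str = ""
    value: str = ""
    units: str = ""
    span: Tuple[int, int] = (0, 0)
    is_extension: bool = False

    def __post_init__(self) -> None:
        ns, _ = sc.split_namespace(self.given_text)
        self.namespace = ns

    @property
    def body(self) -> str:
        """Given text without the namespace prefix."""
        _, body = sc.split_namespace(self.given_text)
        return body

    @property
    def term(self) -> str:
        """Terminal schema term (last path component before any value)."""
        if self.resolved_path:
            return self.resolved_path.split("/")[-1]
        return self.body.split("/")[0]

    def is_resolved(self) -> bool:
        return bool(self.resolved_path)

    def text(self, form: str = "given") -> str:
        """Serialize in ``given``, ``long``, or ``short`` form."""
        if form == "given" or not self.resolved_path:
            return self.given_text
        prefix = f"{self.namespace}:" if self.namespace else ""
        base = (self.resolved_path if form == "long"
                else self.resolved_path.split("/")[-1])
        if self.value:
            base += f"/{self.value}"
            if self.units:
                base += f" {self.units}"
        return prefix + base

    def copy(self) -> "HedTag":
        return copy.deepcopy(self)


@dataclass
class HedGroup:
    """A parenthesized, ordered list of tags and sub-groups."""

    members: List[Union[HedTag, "HedGroup"]] = field(default_factory=list)
    span: Tuple[int, int] = (0, 0)

    def tags(self) -> List[HedTag]:
        """Direct tag members only."""
        return [m for m in self.members if isinstance(m, HedTag)]

    def groups(self) -> List["HedGroup"]:
        return [m for m in self.members if isinstance(m, HedGroup)]

    def iter_tags(self) -> Iterator[HedTag]:
        for m in self.members:
            if isinstance(m, HedTag):
                yield m
            else:
                yield from m.iter_tags()

    def iter_groups(self) -> Iterator["HedGroup"]:
        yield self
        for m in self.members:
            if isinstance(m, HedGroup):
                yield from m.iter_groups()

    def text(self, form: str = "given") -> str:
        return "(" + ", ".join(m.text(form) for m in self.members) + ")"

    def copy(self) -> "HedGroup":
        return copy.deepcopy(self)


@dataclass
class HedString:
    """Top level of an annotation: ordered tags and groups."""

    top: List[Union[HedTag, HedGroup]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.top

    def iter_tags(self) -> Iterator[HedTag]:
        for m in self.top:
            if isinstance(m, HedTag):
                yield m
            else:
                yield from m.iter_tags()

    def iter_groups(self) -> Iterator[HedGroup]:
        for m in self.top:
            if isinstance(m, HedGroup):
                yield from m.iter_groups()

    def text(self, form: str = "given") -> str:
        return ", ".join(m.text(form) for m in self.top)

    def copy(self) -> "HedString":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse(text: str) -> HedString:
    """Parse HED string text into its tag/group structure.

    Whitespace (including newlines and tabs) around separators is ignored.
    Raises :class:`HedSyntaxError` with UNBALANCED_PARENS or EMPTY_TAG on
    ungrammatical input; empty groups ``()`` and dangling commas are errors,
    not silently dropped.
    """
    if not text or not text.strip():
        raise HedSyntaxError(EMPTY_TAG, "empty HED string", (0, len(text or "")))

    root = HedGroup(span=(0, len(text)))
    stack: List[HedGroup] = [root]
    token_start: Optional[int] = None
    # pending tracks whether the current list position awaits a member
    # (True right after '(' or ','), to catch ",,", "(,", "()", trailing ','.
    pending = False
    had_member = False

    def close_token(end: int) -> None:
        nonlocal token_start, pending, had_member
        if token_start is None:
            return
        raw = text[token_start:end]
        stripped = raw.strip()
        if stripped:
            lead = len(raw) - len(raw.lstrip())
            trail = len(raw) - len(raw.rstrip())
            stack[-1].members.append(
                HedTag(stripped, span=(token_start + lead, end - trail)))
            pending = False
            had_member = True
        token_start = None

    for i, ch in enumerate(text):
        if ch == "(":
            close_token(i)
            if stack[-1].members and not pending:
                raise HedSyntaxError(
                    EMPTY_TAG, "missing comma before '('", (i, i + 1))
            group = HedGroup(span=(i, i))
            stack[-1].members.append(group)
            stack.append(group)
            pending = True
            had_member = True
        elif ch == ")":
            close_token(i)
            if len(stack) == 1:
                raise HedSyntaxError(
                    UNBALANCED_PARENS, "unmatched ')'", (i, i + 1))
            closing = stack.pop()
            closing.span = (closing.span[0], i + 1)
            if not closing.members:
                raise HedSyntaxError(
                    EMPTY_TAG, "empty parentheses", (closing.span[0], i + 1))
            if pending:
                raise HedSyntaxError(
                    EMPTY_TAG, "empty tag before ')'", (i, i + 1))
            pending = False
        elif ch == ",":
            close_token(i)
            if pending or not stack[-1].members:
                raise HedSyntaxError(
                    EMPTY_TAG, "empty tag at comma", (i, i + 1))
            pending = True
        else:
            if token_start is None and not ch.isspace():
                if stack[-1].members and not pending and _last_is_group(stack[-1]):
                    raise HedSyntaxError(
                        EMPTY_TAG, "missing comma after ')'", (i, i + 1))
                token_start = i

    close_token(len(text))
    if len(stack) != 1:
        raise HedSyntaxError(
            UNBALANCED_PARENS,
            f"{len(stack) - 1} unclosed '('", (stack[-1].span[0],
                                               stack[-1].span[0] + 1))
    if pending:
        raise HedSyntaxError(EMPTY_TAG, "trailing comma", (len(text) - 1,
                                                           len(text)))
    return HedString(top=root.members)


def _last_is_group(group: HedGroup) -> bool:
    return bool(group.members) and isinstance(group.members[-1], HedGroup)


# ---------------------------------------------------------------------------
# Resolution and conversion
# ---------------------------------------------------------------------------

def resolve(s: HedString, schemas: sc.SchemaSet) -> List[ValidationIssue]:
    """Resolve every tag in place; returns one issue per unresolvable tag."""
    issues: List[ValidationIssue] = []
    for tag in s.iter_tags():
        if tag.is_resolved():
            continue
        try:
            res = sc.resolve_tag(schemas, tag.given_text)
        except ResolutionError as exc:
            issues.append(ValidationIssue(exc.code, exc.detail, ERROR,
                                          span=tag.span))
            continue
        tag.resolved_path = res.path
        tag.namespace = res.namespace
        tag.value = res.value
        tag.units = res.units
        tag.is_extension = res.is_extension
    return issues


def _converted(s: HedString, schemas: sc.SchemaSet, form: str) -> HedString:
    out = s.copy()
    issues = resolve(out, schemas)
    if issues:
        first = issues[0]
        raise ResolutionError(first.code, first.detail)
    for tag in out.iter_tags():
        tag.given_text = tag.text(form)
    return out


def to_long(s: HedString, schemas: sc.SchemaSet) -> HedString:
    """Rewrite every tag as its full root-to-node path (structure unchanged)."""
    return _converted(s, schemas, "long")


def to_short(s: HedString, schemas: sc.SchemaSet) -> HedString:
    """Rewrite every tag as its terminal term (plus value/units)."""
    return _converted(s, schemas, "short")


def _canonical_key(member: Union[HedTag, HedGroup]) -> Tuple[int, str]:
    # tags sort before groups; both lexicographic on their canonical text
    if isinstance(member, HedTag):
        return (0, member.text("long").lower())
    return (1, member.text("long").lower())


def _sort_members(members: List[Union[HedTag, HedGroup]]) -> None:
    for m in members:
        if isinstance(m, HedGroup):
            _sort_members(m.members)
    members.sort(key=_canonical_key)


def canonical(s: HedString, schemas: sc.SchemaSet) -> str:
    """Order-insensitive canonical text: long form, recursively sorted.

    Two annotations that differ only in the order of members (at the top
    level or inside any group) canonicalize to identical text, making tag
    equivalence a string comparison.
    """
    out = to_long(s, schemas)
    _sort_members(out.top)
    return out.text("long")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_DEFINITION_TERM = "definition"
_DEF_TERM = "def"
_DEF_EXPAND_TERM = "def-expand"


def _def_name(tag: HedTag) -> str:
    """Definition name carried by a Def/Definition/Def-expand tag's value."""
    return tag.value.split("/")[0] if tag.value else ""


def validate_string(
    s: HedString,
    schemas: sc.SchemaSet,
    defs: Optional[Sequence[str]] = None,
) -> List[ValidationIssue]:
    """Validate a parsed string against the vocabulary and known definitions.

    Checks, in order: tag resolution (and value/placeholder consistency,
    which resolution enforces), unit membership, duplicate identical tags
    within a single group, ``Def/Name`` references against ``defs`` (an
    iterable of known definition names), Definition-group syntax, and
    extension warnings. All issues are returned, not just the first.
    """
    work = s.copy()
    issues = resolve(work, schemas)
    known = {d.lower() for d in defs} if defs is not None else None

    for tag in work.iter_tags():
        if not tag.is_resolved():
            continue
        # units must belong to the node's unit class
        if tag.units:
            uc_name = tag_unit_class(tag, schemas)
            uc = schemas.schema_for(tag.namespace).unit_classes.get(uc_name)
            if uc is None or tag.units not in uc.units:
                allowed = uc.units if uc else []
                issues.append(ValidationIssue(
                    INVALID_UNITS,
                    f"unit {tag.units!r} not in unit class "
                    f"{uc_name or '<none>'!r} {allowed} for {tag.term}",
                    ERROR, span=tag.span))
        if tag.is_extension:
            issues.append(ValidationIssue(
                EXTENSION_WARNING,
                f"{tag.given_text!r} extends the schema below "
                f"{tag.resolved_path.rsplit('/', 1)[0]!r}",
                WARNING, span=tag.span))
        if known is not None and tag.term.lower() == _DEF_TERM:
            name = _def_name(tag)
            if not name:
                issues.append(ValidationIssue(
                    DEF_SYNTAX, "Def tag without a definition name",
                    ERROR, span=tag.span))
            elif name.lower() not in known:
                issues.append(ValidationIssue(
                    DEF_UNDEFINED, f"definition {name!r} is not defined",
                    ERROR, span=tag.span))

    # duplicate identical tags within one group (warning); across groups legal
    containers: List[List[Union[HedTag, HedGroup]]] = [work.top]
    containers += [g.members for g in work.iter_groups()]
    for members in containers:
        seen = {}
        for m in members:
            if not isinstance(m, HedTag) or not m.is_resolved():
                continue
            key = m.text("long").lower()
            if key in seen:
                issues.append(ValidationIssue(
                    DUPLICATE_TAG_IN_GROUP,
                    f"tag {m.text('short')!r} repeated in the same group",
                    WARNING, span=m.span))
            seen[key] = m

    # Definition-group syntax: exactly one Definition tag + one inner group,
    # nothing else; no Definition nested deeper inside
    for group in work.iter_groups():
        def_tags = [t for t in group.tags()
                    if t.term.lower() == _DEFINITION_TERM]
        if not def_tags:
            continue
        ok = (len(def_tags) == 1 and len(group.members) == 2
              and len(group.groups()) == 1)
        if ok:
            inner = group.groups()[0]
            nested = [t for t in inner.iter_tags()
                      if t.term.lower() in (_DEFINITION_TERM, _DEF_TERM,
                                            _DEF_EXPAND_TERM)]
            ok = not nested
        if not ok:
            issues.append(ValidationIssue(
                DEF_SYNTAX,
                "a Definition group must be exactly (Definition/Name, "
                "(contents)) with no nested Definition/Def/Def-expand",
                ERROR, span=group.span))
    return issues


def tag_unit_class(tag: HedTag, schemas: sc.SchemaSet) -> str:
    """Unit-class name of the schema node a resolved tag points at."""
    schema = schemas.schema_for(tag.namespace)
    node = schema.node_by_path(tag.resolved_path)
    if node is None:  # extension: unit class comes from the anchored node
        node = schema.node_by_term(tag.resolved_path.split("/")[-1])
    return node.unit_class if node is not None else ""


def validate_text(text: str, schemas: sc.SchemaSet,
                  defs: Optional[Sequence[str]] = None
                  ) -> List[ValidationIssue]:
    """Parse then validate raw text, folding syntax errors into the issues."""
    try:
        parsed = parse(text)
    except HedSyntaxError as exc:
        return [exc.to_issue()]
    return validate_string(parsed, schemas, defs)
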