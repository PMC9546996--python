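"""User definitions: named, reusable tag groups and their expansion.

A definition is declared once as ``(Definition/Name, (contents))`` and then
referenced as ``Def/Name`` in event annotations. At analysis time each
``Def/Name`` is replaced by ``(Def-expand/Name, (contents))`` so the inserted
tags keep their association with the definition without being confused with
the declaration itself. Definitions whose contents carry a ``#`` placeholder
take a value: ``Def/Name/value`` substitutes the value for ``#`` in the copy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from .issues import (
    DEF_DUPLICATE,
    DEF_SYNTAX,
    DEF_UNDEFINED,
    ERROR,
    DefinitionError,
    ValidationIssue,
)
from .strings import HedGroup, HedString, HedTag

_NAME_RE = re.compile(r"^[^\s/,()]+$")


@dataclass
class Definition:
    """A named tag group; ``takes_value`` when contents contain ``#``."""

    name: str
    contents: HedGroup
    takes_value: bool = False

    def signature(self) -> str:
        """Schema-free structural fingerprint used for duplicate detection."""
        return _signature(self.contents)


def _signature(member: Union[HedTag, HedGroup]) -> str:
    if isinstance(member, HedTag):
        return member.given_text.lower()
    parts = sorted(_signature(m) for m in member.members)
    return "(" + ",".join(parts) + ")"


class DefinitionSet:
    """Case-insensitive registry of definitions by name."""

    def __init__(self, definitions: Iterable[Definition] = ()):
        self._by_name: Dict[str, Definition] = {}
        for d in definitions:
            self._by_name[d.name.lower()] = d

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def get(self, name: str) -> Definition:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise DefinitionError(
                DEF_UNDEFINED, f"definition {name!r} is not defined"
            ) from None

    def names(self) -> List[str]:
        return [d.name for d in self._by_name.values()]

    def add(self, definition: Definition) -> List[ValidationIssue]:
        """Register; identical re-registration is a no-op, conflicting is an issue."""
        key = definition.name.lower()
        existing = self._by_name.get(key)
        if existing is not None:
            if existing.signature() == definition.signature():
                return []
            return [ValidationIssue(
                DEF_DUPLICATE,
                f"definition {definition.name!r} re-declared with different "
                f"contents", ERROR)]
        self._by_name[key] = definition
        return []


def split_marker(tag: HedTag, marker: str):
    """Reference text after a Def/Definition/Def-expand path component.

    Returns the text following the marker component (may be empty), or None
    when the tag is not a ``marker`` tag. Works on short, partial, and long
    forms: the marker is located as an exact, case-insensitive path component
    anywhere in the written body.
    """
    parts = tag.body.split("/")
    for i, p in enumerate(parts):
        if p.lower() == marker:
            return "/".join(parts[i + 1:])
    return None


def _is_term(tag: HedTag, term: str) -> bool:
    return split_marker(tag, term) is not None


def definition_groups(s: HedString) -> List[HedGroup]:
    """Top-level groups of shape (Definition/..., ...) in declaration position."""
    return [g for g in s.top if isinstance(g, HedGroup)
            and any(_is_term(t, "definition") for t in g.tags())]


def _parse_definition_group(group: HedGroup
                            ) -> Tuple[Definition, List[ValidationIssue]]:
    def_tags = [t for t in group.tags() if _is_term(t, "definition")]
    issues: List[ValidationIssue] = []
    if (len(def_tags) != 1 or len(group.members) != 2
            or len(group.groups()) != 1):
        return None, [ValidationIssue(
            DEF_SYNTAX,
            "a Definition group must be exactly (Definition/Name, (contents))",
            ERROR, span=group.span)]
    name_part = split_marker(def_tags[0], "definition") or ""
    pieces = name_part.split("/")
    name = pieces[0]
    declared_valued = len(pieces) > 1 and pieces[1] == "#"
    if not name or not _NAME_RE.match(name):
        return None, [ValidationIssue(
            DEF_SYNTAX, f"bad definition name {name!r}", ERROR,
            span=def_tags[0].span)]
    contents = group.groups()[0]
    for t in contents.iter_tags():
        if t.term.lower() in ("definition", "def", "def-expand"):
            issues.append(ValidationIssue(
                DEF_SYNTAX,
                f"definition {name!r} contents may not contain "
                f"Definition/Def/Def-expand tags", ERROR, span=t.span))
    takes_value = any("#" in t.given_text for t in contents.iter_tags())
    if declared_valued and not takes_value:
        issues.append(ValidationIssue(
            DEF_SYNTAX,
            f"definition {name!r} declared with '#' but contents have no "
            f"placeholder", ERROR, span=group.span))
    if issues:
        return None, issues
    return Definition(name, contents.copy(), takes_value), []


def collect_definitions(
    strings: Sequence[HedString],
    into: DefinitionSet = None,
) -> Tuple[DefinitionSet, List[ValidationIssue]]:
    """Scan strings for Definition groups and register them.

    Registration is idempotent for byte-identical contents; a name re-declared
    with different contents yields DEF_DUPLICATE.
    """
    defs = into if into is not None else DefinitionSet()
    issues: List[ValidationIssue] = []
    for s in strings:
        for group in definition_groups(s):
            definition, errs = _parse_definition_group(group)
            issues.extend(errs)
            if definition is not None:
                issues.extend(defs.add(definition))
    return defs, issues


def strip_definitions(s: HedString) -> HedString:
    """Copy of ``s`` without its top-level Definition groups (declarations
    live apart from event content)."""
    keep = []
    decls = set(id(g) for g in definition_groups(s))
    for m in s.top:
        if id(m) not in decls:
            keep.append(m)
    return HedString(top=[m.copy() for m in keep])


def _substitute(member: Union[HedTag, HedGroup], value: str) -> None:
    if isinstance(member, HedTag):
        if "#" in member.given_text:
            member.given_text = member.given_text.replace("#", value)
            if member.resolved_path:
                member.value = member.value.replace("#", value)
    else:
        for m in member.members:
            _substitute(m, value)


def expand_defs(s: HedString, defs: DefinitionSet) -> HedString:
    """Replace every ``Def/Name`` tag by ``(Def-expand/Name, (contents))``.

    The original string is unmodified. Expansion is not recursive (definition
    contents may not themselves contain Def tags) and is idempotent: groups
    already marked with Def-expand are left alone. Raises
    :class:`DefinitionError` (DEF_UNDEFINED) for unknown names, and DEF_SYNTAX
    when a valued definition is referenced without a value.
    """
    out = s.copy()

    def expand_members(members: List[Union[HedTag, HedGroup]]) -> None:
        for i, m in enumerate(members):
            if isinstance(m, HedGroup):
                expand_members(m.members)
                continue
            ref = split_marker(m, "def")
            if ref is None or split_marker(m, "def-expand") is not None:
                continue
            pieces = ref.split("/", 1)
            name = pieces[0]
            value = pieces[1] if len(pieces) > 1 else ""
            definition = defs.get(name)  # raises DEF_UNDEFINED
            if definition.takes_value and not value:
                raise DefinitionError(
                    DEF_SYNTAX,
                    f"definition {definition.name!r} takes a value; "
                    f"use Def/{definition.name}/<value>")
            contents = definition.contents.copy()
            if value:
                _substitute(contents, value)
            marker_text = f"Def-expand/{definition.name}"
            if value:
                marker_text += f"/{value}"
            members[i] = HedGroup(
                members=[HedTag(marker_text), contents], span=m.span)

    expand_members(out.top)
    return out


def shrink_defs(s: HedString, defs: DefinitionSet) -> HedString:
    """Inverse of :func:`expand_defs`: collapse Def-expand groups back to Def
    references when their contents match the registered definition."""
    out = s.copy()

    def shrink_members(members: List[Union[HedTag, HedGroup]]) -> None:
        for i, m in enumerate(members):
            if not isinstance(m, HedGroup):
                continue
            markers = [t for t in m.tags() if _is_term(t, "def-expand")]
            if (len(markers) == 1 and len(m.members) == 2
                    and len(m.groups()) == 1):
                ref = split_marker(markers[0], "def-expand") or ""
                name = ref.split("/")[0]
                value = ref.split("/", 1)[1] if "/" in ref else ""
                if name in defs:
                    expected = defs.get(name).contents.copy()
                    if value:
                        _substitute(expected, value)
                    if _signature(expected) == _signature(m.groups()[0]):
                        members[i] = HedTag(f"Def/{ref}", span=m.span)
                        continue
            shrink_members(m.members)

    shrink_members(out.top)
    return out


def parse_definitions_file(text: str) -> Tuple[DefinitionSet, List[ValidationIssue]]:
    """Read a definitions file: one HED string per line; ``//`` comments."""
    from .strings import parse as parse_string

    strings = []
    issues: List[ValidationIssue] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("//"):
            continue
        strings.append(parse_string(line))
    defs, errs = collect_definitions(strings)
    return defs, issues + errs
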