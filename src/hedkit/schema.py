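"""Vocabulary schema loading, indexing, linting, and short-form resolution.

A HED vocabulary is a forest of uniquely named terms.  The *unique mapping*
rule — every term name occurs at exactly one position in a schema — is what
makes short-form annotation possible: any suffix of a node's full path,
down to the bare node name, identifies the node unambiguously and can be
expanded mechanically to the full root-to-node path.

Two on-disk dialects are supported:

* a human-editable wiki dialect (``.mediawiki``): one node per line, nesting
  depth given by the number of leading asterisks, attributes in ``{...}``
  braces after the term, free-text description after the braces, and a
  ``!# unit classes`` section at the end;
* an XML dialect (``.xml``) mirroring the tree with one ``<node>`` element
  per term, used for machine processing.

Both serialize losslessly: loading either serialization of a schema yields
a node-for-node identical tree.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .issues import (
    BAD_TERM_CHARS,
    CHILD_COUNT_OUTSIDE_IDEAL,
    DUPLICATE_TERM,
    EMPTY_DESCRIPTION,
    ERROR,
    INFO,
    INVALID_PARENT,
    TAG_NOT_FOUND,
    TOO_MANY_CHILDREN,
    VALUE_WITHOUT_PLACEHOLDER,
    WARNING,
    DuplicateTermError,
    HedError,
    LintIssue,
    ResolutionError,
    SchemaParseError,
)

_FORBIDDEN_TERM_CHARS = set(",()/ \t")
_LIST_ATTRS = ("suggestedTag", "relatedTag")


@dataclass
class UnitClass:
    """A named family of units for numeric tag values (e.g. time: s, ms)."""

    name: str
    units: List[str]
    default_unit: str

    def __post_init__(self) -> None:
        if self.default_unit not in self.units:
            raise ValueError(
                f"unit class {self.name!r}: default {self.default_unit!r} "
                f"not among units {self.units}"
            )


@dataclass
class SchemaNode:
    """One term in the vocabulary tree."""

    term: str
    description: str = ""
    children: List["SchemaNode"] = field(default_factory=list)
    takes_value: bool = False
    extension_allowed: bool = False
    unit_class: str = ""
    suggested_tags: List[str] = field(default_factory=list)
    related_tags: List[str] = field(default_factory=list)
    parent: Optional["SchemaNode"] = field(default=None, repr=False, compare=False)

    @property
    def path(self) -> str:
        """Slash-joined full path from root to this node."""
        parts = []
        node: Optional[SchemaNode] = self
        while node is not None:
            parts.append(node.term)
            node = node.parent
        return "/".join(reversed(parts))

    def walk(self) -> Iterator["SchemaNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def child_by_term(self, term: str) -> Optional["SchemaNode"]:
        low = term.lower()
        for child in self.children:
            if child.term.lower() == low:
                return child
        return None


class HedSchema:
    """A parsed vocabulary: roots, term index, and unit classes.

    The term index maps lower-cased term names to nodes and exists only for
    schemas satisfying unique mapping; permissively loaded schemas (used for
    linting duplicate-bearing sources) have an empty index.
    """

    def __init__(
        self,
        roots: List[SchemaNode],
        name: str = "",
        version: str = "",
        unit_classes: Optional[Dict[str, UnitClass]] = None,
        permissive: bool = False,
    ):
        self.name = name
        self.version = version
        self.roots = roots
        self.unit_classes: Dict[str, UnitClass] = dict(unit_classes or {})
        self.term_index: Dict[str, SchemaNode] = {}
        for root in roots:
            _link_parents(root, None)
        if not permissive:
            self._build_index()

    def _build_index(self) -> None:
        index: Dict[str, SchemaNode] = {}
        for node in self.iter_nodes():
            key = node.term.lower()
            if key in index:
                raise DuplicateTermError(node.term, [index[key].path, node.path])
            index[key] = node
        self.term_index = index

    def iter_nodes(self) -> Iterator[SchemaNode]:
        for root in self.roots:
            yield from root.walk()

    def node_by_term(self, term: str) -> Optional[SchemaNode]:
        return self.term_index.get(term.lower())

    def node_by_path(self, path: str) -> Optional[SchemaNode]:
        parts = path.split("/")
        node: Optional[SchemaNode] = None
        roots = {r.term.lower(): r for r in self.roots}
        node = roots.get(parts[0].lower())
        for part in parts[1:]:
            if node is None:
                return None
            node = node.child_by_term(part)
        return node


def _link_parents(node: SchemaNode, parent: Optional[SchemaNode]) -> None:
    node.parent = parent
    for child in node.children:
        _link_parents(child, node)


class SchemaSet:
    """A base schema plus zero or more namespaced library schemas.

    Lookup is namespace-scoped: an unprefixed tag resolves only against the
    base schema, ``ns:tag`` only against the library registered under ``ns``.
    Term collisions between libraries, or between a library and the base, are
    therefore legal and never ambiguous.
    """

    def __init__(self, base: HedSchema,
                 libraries: Optional[Dict[str, HedSchema]] = None):
        self.base = base
        self.libraries: Dict[str, HedSchema] = {}
        for ns, lib in (libraries or {}).items():
            self.add_library(ns, lib)

    def add_library(self, namespace: str, library: HedSchema) -> None:
        if not namespace or ":" in namespace:
            raise HedError("BAD_NAMESPACE",
                           f"invalid namespace identifier {namespace!r}")
        if namespace in self.libraries:
            raise HedError("DUPLICATE_NAMESPACE",
                           f"namespace {namespace!r} registered twice")
        self.libraries[namespace] = library

    def schema_for(self, namespace: str) -> HedSchema:
        if not namespace:
            return self.base
        try:
            return self.libraries[namespace]
        except KeyError:
            raise ResolutionError(
                TAG_NOT_FOUND, f"unknown library namespace {namespace!r}"
            ) from None


def merge_libraries(
    base: HedSchema, libs: Sequence[Tuple[str, HedSchema]] = ()
) -> SchemaSet:
    """Register libraries under independent namespaces alongside a base schema."""
    schemas = SchemaSet(base)
    for namespace, lib in libs:
        schemas.add_library(namespace, lib)
    return schemas


# ---------------------------------------------------------------------------
# Wiki dialect
# ---------------------------------------------------------------------------

_WIKI_NODE_RE = re.compile(r"^(\*+)?\s*(\S+)\s*(\{[^}]*\})?\s*(.*)$")


def _parse_attr_block(block: str, lineno: int) -> dict:
    out: dict = {}
    inner = block.strip()[1:-1].strip()
    if not inner:
        return out
    for item in inner.split(","):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, value = (p.strip() for p in item.split("=", 1))
        else:
            key, value = item, True
        if key in _LIST_ATTRS:
            out.setdefault(key, []).append(value)
        elif key in out:
            raise SchemaParseError(f"duplicate attribute {key!r}", lineno)
        else:
            out[key] = value
    return out


def _apply_attrs(node: SchemaNode, attrs: dict, lineno: int) -> None:
    for key, value in attrs.items():
        if key == "takesValue":
            node.takes_value = True
        elif key == "extensionAllowed":
            node.extension_allowed = True
        elif key == "unitClass":
            node.unit_class = str(value)
        elif key == "suggestedTag":
            node.suggested_tags = [str(v) for v in value]
        elif key == "relatedTag":
            node.related_tags = [str(v) for v in value]
        else:
            raise SchemaParseError(f"unknown attribute {key!r}", lineno)


def _check_term(term: str, lineno: int) -> None:
    if not term:
        raise SchemaParseError("empty term", lineno)
    bad = _FORBIDDEN_TERM_CHARS.intersection(term)
    if bad:
        raise SchemaParseError(
            f"term {term!r} contains forbidden characters {sorted(bad)}", lineno
        )


def _load_wiki(text: str, permissive: bool) -> HedSchema:
    name = ""
    version = ""
    roots: List[SchemaNode] = []
    stack: List[SchemaNode] = []  # stack[d] = last node at depth d
    unit_classes: Dict[str, UnitClass] = {}
    in_units = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.lstrip().startswith("<!--"):
            continue
        if line.startswith("HED "):
            header = line[4:]
            m = re.search(r'version="([^"]*)"', header)
            version = m.group(1) if m else ""
            m = re.search(r'library="([^"]*)"', header)
            name = m.group(1) if m else ""
            continue
        if line.strip().lower() == "!# unit classes":
            in_units = True
            continue
        m = _WIKI_NODE_RE.match(line)
        if m is None:
            raise SchemaParseError(f"unparseable line: {line!r}", lineno)
        stars, term, attr_block, description = m.groups()
        depth = len(stars) if stars else 0

        if in_units:
            # unit-class lines: "* name {default=u} u1, u2"
            attrs = _parse_attr_block(attr_block or "{}", lineno)
            default = str(attrs.get("default", ""))
            units = [u.strip() for u in description.split(",") if u.strip()]
            if not units or not default:
                raise SchemaParseError(
                    f"unit class {term!r} needs units and a default", lineno
                )
            try:
                unit_classes[term] = UnitClass(term, units, default)
            except ValueError as exc:
                raise SchemaParseError(str(exc), lineno) from None
            continue

        _check_term(term, lineno)
        node = SchemaNode(term=term, description=description.strip())
        _apply_attrs(node, _parse_attr_block(attr_block, lineno)
                     if attr_block else {}, lineno)
        if depth == 0:
            roots.append(node)
            stack = [node]
        else:
            if depth > len(stack):
                raise SchemaParseError(
                    f"nesting jumps from depth {len(stack) - 1} to {depth}", lineno
                )
            parent = stack[depth - 1]
            if parent.takes_value:
                raise SchemaParseError(
                    f"takesValue node {parent.term!r} cannot have children", lineno
                )
            parent.children.append(node)
            del stack[depth:]
            stack.append(node)

    if not roots:
        raise SchemaParseError("schema defines no nodes", 0)
    return HedSchema(roots, name=name, version=version,
                     unit_classes=unit_classes, permissive=permissive)


def _serialize_wiki(schema: HedSchema) -> str:
    out = io.StringIO()
    out.write(f'HED version="{schema.version}" library="{schema.name}"\n\n')

    def attr_block(node: SchemaNode) -> str:
        items = []
        if node.takes_value:
            items.append("takesValue")
        if node.extension_allowed:
            items.append("extensionAllowed")
        if node.unit_class:
            items.append(f"unitClass={node.unit_class}")
        items += [f"suggestedTag={t}" for t in node.suggested_tags]
        items += [f"relatedTag={t}" for t in node.related_tags]
        return " {" + ", ".join(items) + "}" if items else ""

    def emit(node: SchemaNode, depth: int) -> None:
        stars = "*" * depth + " " if depth else ""
        desc = f" {node.description}" if node.description else ""
        out.write(f"{stars}{node.term}{attr_block(node)}{desc}\n")
        for child in node.children:
            emit(child, depth + 1)

    for root in schema.roots:
        emit(root, 0)
        out.write("\n")
    if schema.unit_classes:
        out.write("!# unit classes\n")
        for uc in schema.unit_classes.values():
            out.write(
                f"* {uc.name} {{default={uc.default_unit}}} {', '.join(uc.units)}\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

def _node_from_xml(elem: ET.Element) -> SchemaNode:
    term = elem.get("name", "")
    _check_term(term, 0)
    node = SchemaNode(term=term)
    for child in elem:
        if child.tag == "description":
            node.description = (child.text or "").strip()
        elif child.tag == "attribute":
            key = child.get("name", "")
            value = child.get("value", True)
            if key in _LIST_ATTRS:
                getattr(node, "suggested_tags" if key == "suggestedTag"
                        else "related_tags").append(str(value))
            else:
                _apply_attrs(node, {key: value}, 0)
        elif child.tag == "node":
            if node.takes_value:
                raise SchemaParseError(
                    f"takesValue node {term!r} cannot have children"
                )
            node.children.append(_node_from_xml(child))
    return node


def _load_xml(text: str, permissive: bool) -> HedSchema:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        line = getattr(exc, "position", (None,))[0]
        raise SchemaParseError(str(exc), line) from None
    if root.tag != "HED":
        raise SchemaParseError(f"root element is <{root.tag}>, expected <HED>")
    roots = [_node_from_xml(e) for e in root if e.tag == "node"]
    unit_classes: Dict[str, UnitClass] = {}
    for ucs in root.iter("unitClasses"):
        for uc in ucs.iter("unitClass"):
            units = [u.text or "" for u in uc.iter("unit")]
            name = uc.get("name", "")
            try:
                unit_classes[name] = UnitClass(name, units, uc.get("default", ""))
            except ValueError as exc:
                raise SchemaParseError(str(exc)) from None
    if not roots:
        raise SchemaParseError("schema defines no nodes")
    return HedSchema(roots, name=root.get("library", ""),
                     version=root.get("version", ""),
                     unit_classes=unit_classes, permissive=permissive)


def _serialize_xml(schema: HedSchema) -> str:
    top = ET.Element("HED", version=schema.version, library=schema.name)

    def emit(node: SchemaNode, parent: ET.Element) -> None:
        elem = ET.SubElement(parent, "node", name=node.term)
        if node.description:
            ET.SubElement(elem, "description").text = node.description
        if node.takes_value:
            ET.SubElement(elem, "attribute", name="takesValue")
        if node.extension_allowed:
            ET.SubElement(elem, "attribute", name="extensionAllowed")
        if node.unit_class:
            ET.SubElement(elem, "attribute", name="unitClass",
                          value=node.unit_class)
        for t in node.suggested_tags:
            ET.SubElement(elem, "attribute", name="suggestedTag", value=t)
        for t in node.related_tags:
            ET.SubElement(elem, "attribute", name="relatedTag", value=t)
        for child in node.children:
            emit(child, elem)

    for root in schema.roots:
        emit(root, top)
    if schema.unit_classes:
        ucs = ET.SubElement(top, "unitClasses")
        for uc in schema.unit_classes.values():
            elem = ET.SubElement(ucs, "unitClass", name=uc.name,
                                 default=uc.default_unit)
            for unit in uc.units:
                ET.SubElement(elem, "unit").text = unit
    ET.indent(top)
    return ET.tostring(top, encoding="unicode") + "\n"


# ---------------------------------------------------------------------------
# Public load/serialize and lint API
# ---------------------------------------------------------------------------

def load_schema(source: str, dialect: str = "wiki",
                permissive: bool = False) -> HedSchema:
    """Parse schema text in the named dialect (``wiki`` or ``xml``).

    Loading fails with :class:`DuplicateTermError` when the source violates
    unique mapping, unless ``permissive`` is set — permissive mode builds the
    tree without a term index so :func:`check_uniqueness` can report all
    duplicates.
    """
    if dialect == "wiki":
        return _load_wiki(source, permissive)
    if dialect == "xml":
        return _load_xml(source, permissive)
    raise ValueError(f"unknown schema dialect {dialect!r}")


def serialize_schema(schema: HedSchema, dialect: str = "wiki") -> str:
    if dialect == "wiki":
        return _serialize_wiki(schema)
    if dialect == "xml":
        return _serialize_xml(schema)
    raise ValueError(f"unknown schema dialect {dialect!r}")


def check_uniqueness(schema: HedSchema) -> List[LintIssue]:
    """One DUPLICATE_TERM error per term name occurring at two or more paths.

    Matching is case-insensitive, mirroring tag resolution.
    """
    paths_by_term: Dict[str, List[str]] = {}
    for node in schema.iter_nodes():
        paths_by_term.setdefault(node.term.lower(), []).append(node.path)
    issues = []
    for term, paths in paths_by_term.items():
        if len(paths) > 1:
            issues.append(LintIssue(
                DUPLICATE_TERM, paths[0],
                f"term {term!r} appears at {len(paths)} paths: "
                + "; ".join(paths),
                ERROR,
            ))
    return issues


def lint_structure(schema: HedSchema, max_children: int = 10,
                   ideal_range: Tuple[int, int] = (3, 7)) -> List[LintIssue]:
    """Structural-sparsity lint.

    Nodes with ``max_children`` or more children get a warning (menu-design
    guidance: fewer than 10 items per level); non-leaf nodes whose child count
    falls outside ``ideal_range`` get an informational note.
    """
    lo, hi = ideal_range
    issues = []
    for node in schema.iter_nodes():
        n = len(node.children)
        if n >= max_children:
            issues.append(LintIssue(
                TOO_MANY_CHILDREN, node.path,
                f"{n} children (limit {max_children})", WARNING))
        elif n and not lo <= n <= hi:
            issues.append(LintIssue(
                CHILD_COUNT_OUTSIDE_IDEAL, node.path,
                f"{n} children (ideal {lo}-{hi})", INFO))
    return issues


def lint_schema(schema: HedSchema, max_children: int = 10) -> List[LintIssue]:
    """Full lint: uniqueness, sparsity, empty descriptions, bad characters."""
    issues = check_uniqueness(schema) + lint_structure(schema, max_children)
    for node in schema.iter_nodes():
        if not node.description:
            issues.append(LintIssue(EMPTY_DESCRIPTION, node.path,
                                    "node has no description", WARNING))
        bad = _FORBIDDEN_TERM_CHARS.intersection(node.term)
        if bad:
            issues.append(LintIssue(
                BAD_TERM_CHARS, node.path,
                f"term contains forbidden characters {sorted(bad)}", ERROR))
    return issues


@dataclass
class SchemaStats:
    top_level: int
    children_per_top: Dict[str, int]
    total_nodes: int


def schema_stats(schema: HedSchema) -> SchemaStats:
    """Counts from an exhaustive traversal: roots, second-level fan-out, total."""
    total = sum(1 for _ in schema.iter_nodes())
    return SchemaStats(
        top_level=len(schema.roots),
        children_per_top={r.term: len(r.children) for r in schema.roots},
        total_nodes=total,
    )


# ---------------------------------------------------------------------------
# Tag resolution (short form -> long form)
# ---------------------------------------------------------------------------

@dataclass
class Resolution:
    """Outcome of resolving one tag against a schema set."""

    path: str                 # full schema path, plus extension segments if any
    node: SchemaNode          # deepest schema node on the path
    namespace: str = ""
    value: str = ""
    units: str = ""
    is_extension: bool = False

    @property
    def prefixed_path(self) -> str:
        return f"{self.namespace}:{self.path}" if self.namespace else self.path


def split_namespace(tag_text: str) -> Tuple[str, str]:
    """Split an optional leading ``ns:`` prefix off a tag body."""
    colon = tag_text.find(":")
    slash = tag_text.find("/")
    if colon > 0 and (slash == -1 or colon < slash):
        return tag_text[:colon], tag_text[colon + 1:]
    return "", tag_text


def resolve_tag(schemas: SchemaSet, tag_text: str) -> Resolution:
    """Resolve a single tag (any partial path, optionally valued) to its node.

    The leading components must form a contiguous downward chain ending at a
    schema node; matching is case-insensitive and the returned path uses the
    schema's stored casing. Trailing components are the value (after a
    takesValue node; an optional unit follows the value after one space) or
    novel extension terms (after an extensionAllowed node).
    """
    namespace, body = split_namespace(tag_text.strip())
    schema = schemas.schema_for(namespace)
    parts = [p.strip() for p in body.split("/")]
    if not parts or not parts[0]:
        raise ResolutionError(TAG_NOT_FOUND, f"empty tag in {tag_text!r}")

    node = schema.node_by_term(parts[0])
    if node is None:
        raise ResolutionError(
            TAG_NOT_FOUND,
            f"{parts[0]!r} is not a term of "
            + (f"library {namespace!r}" if namespace else "the base schema"),
        )
    i = 1
    while i < len(parts):
        child = node.child_by_term(parts[i])
        if child is None:
            break
        node = child
        i += 1
    remainder = parts[i:]

    if not remainder:
        return Resolution(node.path, node, namespace)

    if node.takes_value:
        value = "/".join(remainder)
        units = ""
        if " " in value:
            value, units = (p.strip() for p in value.rsplit(" ", 1))
        return Resolution(node.path, node, namespace, value=value, units=units)

    if node.extension_allowed:
        for part in remainder:
            _check_term(part, 0)
        ext_path = node.path + "/" + "/".join(remainder)
        return Resolution(ext_path, node, namespace, is_extension=True)

    nxt = remainder[0].split(" ")[0]
    if schema.node_by_term(nxt) is not None:
        raise ResolutionError(
            INVALID_PARENT,
            f"{nxt!r} exists in the schema but not under "
            f"{node.path!r} (tag {tag_text!r})",
        )
    raise ResolutionError(
        VALUE_WITHOUT_PLACEHOLDER,
        f"{node.path!r} does not take a value; cannot attach "
        f"{'/'.join(remainder)!r}",
    )
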