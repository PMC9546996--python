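"""Schema loading, linting, round-tripping, and short-form resolution."""

import random

import pytest

import hedkit as hk
from hedkit.issues import (
    DUPLICATE_TERM,
    INVALID_PARENT,
    TAG_NOT_FOUND,
    TOO_MANY_CHILDREN,
    ResolutionError,
)
from hedkit.schema import serialize_schema

MINI_WIKI = """\
HED version="0.0.1" library=""

Top The only root
* Alpha First child
** Leafy {takesValue} A leaf with value
* Beta Second child
"""


def paths(schema):
    return {n.path for n in schema.iter_nodes()}


def attrs(schema):
    return {
        n.path: (n.takes_value, n.extension_allowed, n.unit_class,
                 tuple(n.suggested_tags), tuple(n.related_tags))
        for n in schema.iter_nodes()
    }


class TestLoad:
    def test_fixture_has_six_roots(self, base_schema):
        assert len(base_schema.roots) == 6

    def test_mini_wiki_structure(self):
        schema = hk.load_schema(MINI_WIKI, "wiki")
        assert paths(schema) == {"Top", "Top/Alpha", "Top/Alpha/Leafy",
                                 "Top/Beta"}
        assert schema.node_by_term("leafy").takes_value

    def test_empty_source_is_parse_error(self):
        with pytest.raises(hk.SchemaParseError):
            hk.load_schema("", "wiki")
        with pytest.raises(hk.SchemaParseError):
            hk.load_schema("<HED version='1'></HED>", "xml")

    def test_depth_jump_is_parse_error(self):
        bad = "Top Root here\n*** Deep Orphan node\n"
        with pytest.raises(hk.SchemaParseError) as err:
            hk.load_schema(bad, "wiki")
        assert err.value.line == 2

    def test_duplicate_terms_refuse_strict_load(self):
        dup = "Top Root\n* Red A color\n* Other X\n** Red Another color\n"
        with pytest.raises(hk.HedError) as err:
            hk.load_schema(dup, "wiki")
        assert err.value.code == DUPLICATE_TERM
        # permissive load still builds the tree for linting
        schema = hk.load_schema(dup, "wiki", permissive=True)
        assert len(paths(schema)) == 4

    @pytest.mark.parametrize("dialect", ["wiki", "xml"])
    def test_round_trip_preserves_tree(self, base_schema, dialect):
        text = serialize_schema(base_schema, dialect)
        reloaded = hk.load_schema(text, dialect)
        assert paths(reloaded) == paths(base_schema)
        assert attrs(reloaded) == attrs(base_schema)
        assert {u.name: (tuple(u.units), u.default_unit)
                for u in reloaded.unit_classes.values()} == \
               {u.name: (tuple(u.units), u.default_unit)
                for u in base_schema.unit_classes.values()}

    def test_cross_dialect_round_trip(self, base_schema):
        via_xml = hk.load_schema(serialize_schema(base_schema, "xml"), "xml")
        back = hk.load_schema(serialize_schema(via_xml, "wiki"), "wiki")
        assert paths(back) == paths(base_schema)
        assert attrs(back) == attrs(base_schema)


class TestUniqueness:
    def test_fixture_is_unique(self, base_schema):
        assert hk.check_uniqueness(base_schema) == []

    def test_duplicate_reported_with_both_paths(self):
        dup = "Top Root\n* Red A color\n* Other X\n** Red Another\n"
        schema = hk.load_schema(dup, "wiki", permissive=True)
        issues = hk.check_uniqueness(schema)
        assert len(issues) == 1
        assert "Top/Red" in issues[0].detail
        assert "Top/Other/Red" in issues[0].detail

    def test_case_insensitive_duplicates(self):
        dup = "Top Root\n* red Lower\n* Other X\n** Red Upper\n"
        schema = hk.load_schema(dup, "wiki", permissive=True)
        assert len(hk.check_uniqueness(schema)) == 1

    def test_agrees_with_brute_force_on_perturbed_schemas(self, base_schema):
        """Randomly duplicate fixture terms; issue count must equal the
        brute-force count of lower-cased terms occurring at >= 2 paths."""
        rng = random.Random(20240901)
        source_terms = [n.term for n in base_schema.iter_nodes()
                        if not n.children]
        for _ in range(20):
            k = rng.randint(1, 4)
            extra = rng.sample(source_terms, k)
            lines = ["Top Synthetic root"]
            lines += [f"* {t} Duplicated on purpose" for t in extra]
            lines += [f"* Unique-{i} Filler" for i in range(3)]
            base_text = serialize_schema(base_schema, "wiki")
            head, sep, tail = base_text.partition("!# unit classes")
            text = head + "\n".join(lines) + "\n" + sep + tail
            schema = hk.load_schema(text, "wiki", permissive=True)
            from collections import Counter
            counts = Counter(n.term.lower() for n in schema.iter_nodes())
            expected = sum(1 for c in counts.values() if c > 1)
            assert len(hk.check_uniqueness(schema)) == expected


class TestLintStructure:
    @pytest.mark.parametrize("n_children,n_warnings", [(9, 0), (10, 1), (12, 1)])
    def test_child_count_threshold(self, n_children, n_warnings):
        lines = ["Top Root"] + [f"* Child-{i} A child" for i in range(n_children)]
        schema = hk.load_schema("\n".join(lines) + "\n", "wiki")
        warnings = [i for i in hk.lint_structure(schema)
                    if i.code == TOO_MANY_CHILDREN]
        assert len(warnings) == n_warnings

    def test_fixture_matches_exhaustive_count(self, base_schema):
        expected = sum(1 for n in base_schema.iter_nodes()
                       if len(n.children) >= 10)
        warnings = [i for i in hk.lint_structure(base_schema)
                    if i.code == TOO_MANY_CHILDREN]
        assert len(warnings) == expected == 0

    def test_ideal_range_notes_are_informational(self, base_schema):
        notes = [i for i in hk.lint_structure(base_schema)
                 if i.severity == "info"]
        brute = [n for n in base_schema.iter_nodes()
                 if n.children and not 3 <= len(n.children) <= 7]
        assert len(notes) == len(brute)


class TestResolveTag:
    def test_known_short_forms(self, schemas):
        got = hk.resolve_tag(schemas, "Visual-presentation").path
        assert got == ("Property/Sensory-property/Sensory-presentation/"
                       "Visual-presentation")
        assert hk.resolve_tag(schemas, "Event").path == "Event"
        assert hk.resolve_tag(
            schemas, "Sensory-presentation/Visual-presentation").path == got

    def test_every_suffix_resolves_to_same_path(self, schemas):
        for node in schemas.base.iter_nodes():
            full = node.path
            parts = full.split("/")
            for start in range(len(parts)):
                suffix = "/".join(parts[start:])
                assert hk.resolve_tag(schemas, suffix).path == full, suffix

    def test_case_insensitive_with_schema_casing_output(self, schemas):
        assert hk.resolve_tag(schemas, "visual-PRESENTATION").path.endswith(
            "/Visual-presentation")

    def test_value_and_units_preserved(self, schemas):
        res = hk.resolve_tag(schemas, "Duration/0.5 s")
        assert res.path.endswith("/Duration")
        assert (res.value, res.units) == ("0.5", "s")

    def test_unknown_term(self, schemas):
        with pytest.raises(ResolutionError) as err:
            hk.resolve_tag(schemas, "Parallelogram")
        assert err.value.code == TAG_NOT_FOUND

    def test_contradicting_parent_chain(self, schemas):
        with pytest.raises(ResolutionError) as err:
            hk.resolve_tag(schemas, "Event/Visual-presentation")
        assert err.value.code == INVALID_PARENT

    def test_extension_allowed_appends_novel_terms(self, schemas):
        res = hk.resolve_tag(schemas, "Man-made-object/Teacup")
        assert res.is_extension
        assert res.path.endswith("Man-made-object/Teacup")


class TestLibraries:
    def test_namespace_scoped_lookup(self, schemas_with_library):
        assert hk.resolve_tag(schemas_with_library, "sc:Spike").path == \
            "Clinical-finding/Epileptiform-activity/Spike"
        with pytest.raises(ResolutionError):
            hk.resolve_tag(schemas_with_library, "Spike")

    def test_partial_path_with_namespace(self, schemas_with_library):
        res = hk.resolve_tag(schemas_with_library,
                             "sc:Epileptiform-activity/Spike")
        assert res.prefixed_path == \
            "sc:Clinical-finding/Epileptiform-activity/Spike"

    def test_empty_library_list_is_identity(self, base_schema, schemas):
        merged = hk.merge_libraries(base_schema, [])
        assert hk.resolve_tag(merged, "Red").path == \
            hk.resolve_tag(schemas, "Red").path

    def test_duplicate_namespace_rejected(self, base_schema):
        lib = hk.build_clinical_library()
        with pytest.raises(hk.HedError) as err:
            hk.merge_libraries(base_schema, [("sc", lib), ("sc", lib)])
        assert err.value.code == "DUPLICATE_NAMESPACE"


class TestStats:
    def test_fixture_counts(self, base_schema):
        stats = hk.schema_stats(base_schema)
        assert stats.top_level == 6
        assert stats.children_per_top == {
            "Event": 7, "Agent": 6, "Action": 5,
            "Item": 4, "Property": 7, "Relation": 5}

    def test_totals_match_exhaustive_traversal(self, base_schema):
        def count(node):
            return 1 + sum(count(c) for c in node.children)

        assert hk.schema_stats(base_schema).total_nodes == \
            sum(count(r) for r in base_schema.roots)

    def test_single_node_schema(self):
        schema = hk.load_schema("Solo The only node\n", "wiki")
        stats = hk.schema_stats(schema)
        assert (stats.top_level, stats.total_nodes) == (1, 1)
        assert stats.children_per_top == {"Solo": 0}
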