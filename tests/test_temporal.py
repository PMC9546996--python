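"""Enduring-event scope resolution, Event-context insertion, timelines."""

import random

import pytest

import hedkit as hk
from hedkit.assembly import AssembledEvent
from hedkit.definitions import collect_definitions
from hedkit.issues import OFFSET_WITHOUT_ONSET, UNCLOSED_ONSET, HedError

PLAYMOVIE_DEF = "(Definition/PlayMovie, (Visual-presentation, Label/MovieClip))"
DISTRACTOR_DEF = "(Definition/Noise, (Auditory-presentation))"


def make_events(rows):
    """rows: list of (onset, hed text or None)."""
    out = []
    for i, (onset, text) in enumerate(rows):
        annotation = hk.parse(text) if text else hk.HedString()
        out.append(AssembledEvent(onset, None, annotation, i))
    return out


def movie_defs():
    defs, issues = collect_definitions(
        [hk.parse(PLAYMOVIE_DEF), hk.parse(DISTRACTOR_DEF)])
    assert not issues
    return defs


class TestResolveScopes:
    def test_onset_offset_pair(self):
        events = make_events([
            (20.0, "(Def/PlayMovie, Onset)"),
            (50.0, "Sensory-event"),
            (100.0, "(Def/PlayMovie, Offset)"),
        ])
        scopes, issues = hk.resolve_scopes(events, movie_defs())
        assert issues == []
        assert len(scopes) == 1
        assert (scopes[0].start, scopes[0].end) == (20.0, 100.0)
        assert scopes[0].def_name == "PlayMovie"
        assert scopes[0].source_rows == (0, 2)

    def test_offset_without_onset(self):
        events = make_events([(10.0, "(Def/PlayMovie, Offset)")])
        scopes, issues = hk.resolve_scopes(events, movie_defs())
        assert scopes == []
        assert [i.code for i in issues] == [OFFSET_WITHOUT_ONSET]

    def test_reonset_closes_prior_interval(self):
        events = make_events([
            (10.0, "(Def/PlayMovie, Onset)"),
            (30.0, "(Def/PlayMovie, Onset)"),
            (50.0, "(Def/PlayMovie, Offset)"),
        ])
        scopes, issues = hk.resolve_scopes(events, movie_defs())
        assert issues == []
        assert [(s.start, s.end) for s in scopes] == [(10.0, 30.0),
                                                      (30.0, 50.0)]

    def test_unclosed_interval_ends_at_last_event(self):
        events = make_events([
            (10.0, "(Def/PlayMovie, Onset)"),
            (90.0, "Sensory-event"),
        ])
        scopes, issues = hk.resolve_scopes(events, movie_defs())
        assert [i.code for i in issues] == [UNCLOSED_ONSET]
        assert scopes[0].end == 90.0
        assert scopes[0].flagged_unclosed

    def test_duration_group_creates_closed_interval(self):
        events = make_events([(5.0, "(Sensory-event, Duration/2.5 s)")])
        scopes, issues = hk.resolve_scopes(events, movie_defs())
        assert issues == []
        assert [(s.start, s.end) for s in scopes] == [(5.0, 7.5)]

    def test_multiple_duration_groups_in_one_event(self):
        events = make_events([
            (5.0, "(Red, Duration/1 s), (Green, Duration/3 s)")])
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        assert sorted((s.start, s.end) for s in scopes) == [(5.0, 6.0),
                                                            (5.0, 8.0)]

    def test_duration_in_ms(self):
        events = make_events([(1.0, "(Red, Duration/500 ms)")])
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        assert (scopes[0].start, scopes[0].end) == (1.0, 1.5)

    def test_annotation_carries_companions_and_expansion(self):
        events = make_events([
            (20.0, "(Def/PlayMovie, Onset, Red)"),
            (100.0, "(Def/PlayMovie, Offset)"),
        ])
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        text = scopes[0].annotation.text()
        assert "Def-expand/PlayMovie" in text
        assert "Label/MovieClip" in text
        assert "Red" in text
        assert "Onset" not in text


class TestEventContext:
    def movie_interval_events(self):
        return make_events([
            (10.0, "Sensory-event"),
            (20.0, "(Def/PlayMovie, Onset)"),
            (30.0, "Agent-action"),
            (50.0, "Sensory-event"),
            (90.0, "Agent-action"),
            (100.0, "(Def/PlayMovie, Offset)"),
            (110.0, "Sensory-event"),
        ])

    def test_intervening_events_inherit_context(self, schemas):
        events = self.movie_interval_events()
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        with_ctx = hk.insert_event_context(events, scopes, schemas)
        texts = [e.annotation.text() for e in with_ctx]
        assert "Event-context" in texts[3]
        assert "PlayMovie" in texts[3]
        # exactly the three events in [20, 100) that are not markers
        assert sum("Event-context" in t for t in texts) == 3
        assert "Event-context" not in texts[0]   # before
        assert "Event-context" not in texts[6]   # after
        assert "Event-context" not in texts[1]   # opening marker
        assert "Event-context" not in texts[5]   # closing marker

    def test_event_at_offset_instant_excluded(self):
        events = make_events([
            (20.0, "(Def/PlayMovie, Onset)"),
            (100.0, "Sensory-event"),
            (100.0, "(Def/PlayMovie, Offset)"),
        ])
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        with_ctx = hk.insert_event_context(events, scopes)
        assert "Event-context" not in with_ctx[1].annotation.text()

    def test_event_at_onset_instant_included(self):
        events = make_events([
            (20.0, "(Def/PlayMovie, Onset)"),
            (20.0, "Sensory-event"),
            (100.0, "(Def/PlayMovie, Offset)"),
        ])
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        with_ctx = hk.insert_event_context(events, scopes)
        assert "Event-context" in with_ctx[1].annotation.text()

    def test_single_context_group_and_insertion_guard(self, schemas):
        events = self.movie_interval_events()
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        with_ctx = hk.insert_event_context(events, scopes, schemas)
        for ev in with_ctx:
            n = sum(1 for g in ev.annotation.iter_groups()
                    if any("Event-context" in t.given_text
                           for t in g.tags()))
            assert n <= 1
        with pytest.raises(HedError):
            hk.insert_event_context(with_ctx, scopes, schemas)

    def test_agrees_with_brute_force_oracle(self):
        """1000 random events x 50 random intervals: context contents match
        an independent all-pairs overlap check."""
        rng = random.Random(404)
        n_events, n_intervals = 1000, 50
        defs_texts, rows = [], []
        starts_ends = []
        for k in range(n_intervals):
            name = f"Scope{k}"
            defs_texts.append(f"(Definition/{name}, (Time-block, "
                              f"Label/{name}))")
            start = round(rng.uniform(0, 900), 3)
            end = round(start + rng.uniform(1, 100), 3)
            starts_ends.append((name, start, end))
            rows.append((start, f"(Def/{name}, Onset)"))
            rows.append((end, f"(Def/{name}, Offset)"))
        for _ in range(n_events):
            rows.append((round(rng.uniform(0, 1000), 3), "Sensory-event"))
        rows.sort(key=lambda r: r[0])
        events = make_events(rows)
        defs, issues = collect_definitions([hk.parse(t) for t in defs_texts])
        assert not issues
        scopes, scope_issues = hk.resolve_scopes(events, defs)
        assert not [i for i in scope_issues if i.severity == "error"]
        with_ctx = hk.insert_event_context(events, scopes)

        marker_rows = {}
        for i, (onset, text) in enumerate(rows):
            if "Def/" in text:
                name = text.split("Def/")[1].split(",")[0]
                marker_rows.setdefault(name, set()).add(i)
        for i, (onset, text) in enumerate(rows):
            expected = sorted(
                name for name, start, end in starts_ends
                if start <= onset < end and i not in marker_rows.get(name, ()))
            got = []
            for g in with_ctx[i].annotation.iter_groups():
                if any(t.given_text == "Event-context" for t in g.tags()):
                    for t in g.iter_tags():
                        if t.given_text.startswith("Def-expand/"):
                            got.append(t.given_text.split("/")[1])
            assert sorted(got) == expected, f"row {i} at {onset}"


class TestTimeline:
    def test_design1_tracks(self, design1_assembled, schemas):
        _, assembled, defs = design1_assembled
        scopes, issues = hk.resolve_scopes(assembled, defs)
        assert not [i for i in issues if i.severity == "error"]
        timeline = hk.extract_timeline(scopes, defs, schemas)
        assert len(timeline.tracks["Time-block"]) == 2
        assert len(timeline.tracks["Task"]) == 1
        assert len(timeline.tracks["Condition-variable"]) == 1
        assert len(timeline.tracks["Experimental-trial"]) == 20
        # blocks are separated by a visible gap
        (l1, s1, e1), (l2, s2, e2) = timeline.tracks["Time-block"]
        assert e1 < s2
        assert {l1, l2} == {"Block-1", "Block-2"}

    def test_design2_blocks_disjoint_tasks_differ(self, schemas):
        gen = hk.generate_design(hk.DesignSpec(design=2, seed=1))
        events = hk.read_events(gen.events_tsv)
        sidecar = hk.read_sidecar(gen.sidecar_json)
        defs, _ = hk.parse_definitions_file(gen.definitions_txt)
        assembled, defs, issues = hk.assemble(events, sidecar, schemas, defs)
        assert not [i for i in issues if i.severity == "error"]
        scopes, _ = hk.resolve_scopes(assembled, defs)
        timeline = hk.extract_timeline(scopes, defs, schemas)
        blocks = timeline.tracks["Time-block"]
        assert len(blocks) == 2
        assert blocks[0][2] <= blocks[1][1]  # disjoint
        tasks = timeline.tracks["Task"]
        assert len(tasks) == 2
        assert tasks[0][0] != tasks[1][0]

    def test_design3_condition_per_trial(self, schemas):
        gen = hk.generate_design(hk.DesignSpec(design=3, n_blocks=1,
                                               trials_per_block=12, seed=5))
        events = hk.read_events(gen.events_tsv)
        sidecar = hk.read_sidecar(gen.sidecar_json)
        defs, _ = hk.parse_definitions_file(gen.definitions_txt)
        assembled, defs, issues = hk.assemble(events, sidecar, schemas, defs)
        scopes, _ = hk.resolve_scopes(assembled, defs)
        timeline = hk.extract_timeline(scopes, defs, schemas)
        assert len(timeline.tracks["Condition-variable"]) == 12

    def test_no_organizational_tags_all_tracks_empty(self, schemas):
        events = make_events([
            (20.0, "(Def/PlayMovie, Onset)"),
            (100.0, "(Def/PlayMovie, Offset)"),
        ])
        scopes, _ = hk.resolve_scopes(events, movie_defs())
        timeline = hk.extract_timeline(scopes, movie_defs(), schemas)
        assert all(not track for track in timeline.tracks.values())

    def test_interval_invariants(self, design1_assembled, schemas):
        gen, assembled, defs = design1_assembled
        scopes, _ = hk.resolve_scopes(assembled, defs)
        span = gen.record_span[1] - gen.record_span[0]
        timeline = hk.extract_timeline(scopes, defs, schemas)
        for track, intervals in timeline.tracks.items():
            assert all(end >= start for _, start, end in intervals)
            assert sum(end - start for _, start, end in intervals) <= span
            assert intervals == sorted(intervals, key=lambda r: r[1])
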