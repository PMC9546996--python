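"""Enduring events: temporal scope resolution, context insertion, timelines.

Instantaneous event rows can delimit *enduring* events — intervals during
which some annotated state holds.  A ``(Def/Name, Onset)`` group opens an
interval at its row's onset; a later ``(Def/Name, Offset)`` group closes it,
and a repeated Onset for the same name closes the running interval and opens
a new one.  A group carrying ``Duration/v`` opens a self-closing interval
``[onset, onset + v]`` with no separate closing row.  All tags grouped with
the Onset or Duration apply throughout the interval.

At analysis time, every event falling inside an interval inherits a copy of
the interval's annotation inside a single ``(Event-context, ...)`` group —
distinguishing "happened while the movie played" from the movie onset/offset
events themselves. Interval membership is half-open, ``start <= t < end``,
and an interval's own marker rows never receive its context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import strings as st
from .assembly import AssembledEvent
from .definitions import DefinitionSet, expand_defs, split_marker
from .issues import (
    ERROR,
    OFFSET_WITHOUT_ONSET,
    UNCLOSED_ONSET,
    WARNING,
    HedError,
    ValidationIssue,
)
from .schema import SchemaSet

ORGANIZATIONAL_TRACKS = ("Task", "Time-block", "Condition-variable",
                         "Experimental-trial", "Recording")


@dataclass
class EnduringEvent:
    """A named interval carrying an annotation that holds throughout it.

    ``def_name`` is the defined name (with value for valued definitions) for
    Onset/Offset scopes, and may be empty for anonymous Duration scopes.
    ``annotation`` holds the expanded definition contents plus any companion
    tags from the opening group.
    """

    def_name: str
    start: float
    end: Optional[float]  # None while still open
    annotation: st.HedGroup
    source_rows: Tuple[int, Optional[int]]
    flagged_unclosed: bool = False

    @property
    def closed(self) -> bool:
        return self.end is not None

    def contains(self, t: float) -> bool:
        return self.closed and self.start <= t < self.end


@dataclass
class Timeline:
    """Organizational intervals grouped onto named tracks."""

    tracks: Dict[str, List[Tuple[str, float, float]]] = field(
        default_factory=lambda: {k: [] for k in ORGANIZATIONAL_TRACKS})

    def to_records(self) -> List[dict]:
        out = []
        for track in ORGANIZATIONAL_TRACKS:
            for label, start, end in self.tracks[track]:
                out.append({"track": track, "label": label,
                            "start": start, "end": end})
        return out

    def to_bed(self, track: str) -> str:
        lines = [f"{label}\t{start}\t{end}"
                 for label, start, end in self.tracks[track]]
        return "\n".join(lines) + ("\n" if lines else "")


def _duration_seconds(tag: st.HedTag, schemas: Optional[SchemaSet]) -> float:
    value = split_marker(tag, "duration")
    if value is None:
        raise ValueError("not a Duration tag")
    value = value.strip()
    parts = value.split(" ")
    number = float(parts[0])
    unit = parts[1] if len(parts) > 1 else ""
    if unit in ("", "s"):
        return number
    if unit == "ms":
        return number / 1000.0
    raise ValueError(f"unsupported time unit {unit!r}")


def _classify_group(group: st.HedGroup):
    """Find Def/Onset/Offset/Duration roles among a group's direct tags."""
    def_ref = onset = offset = duration = None
    for tag in group.tags():
        if split_marker(tag, "def") is not None and \
                split_marker(tag, "def-expand") is None:
            def_ref = tag
        elif split_marker(tag, "onset") is not None:
            onset = tag
        elif split_marker(tag, "offset") is not None:
            offset = tag
        elif split_marker(tag, "duration") is not None:
            duration = tag
    return def_ref, onset, offset, duration


def _scope_annotation(group: st.HedGroup, exclude: Sequence[st.HedTag],
                      defs: DefinitionSet) -> st.HedGroup:
    """Expanded definition contents plus companion tags of the opening group."""
    drop = {id(t) for t in exclude if t is not None}
    members = [m.copy() for m in group.members if id(m) not in drop]
    expanded = expand_defs(st.HedString(top=members), defs)
    return st.HedGroup(members=expanded.top, span=group.span)


def resolve_scopes(
    events: Sequence[AssembledEvent],
    defs: DefinitionSet,
) -> Tuple[List[EnduringEvent], List[ValidationIssue]]:
    """Scan onset-ordered events and build all enduring-event intervals.

    Offsets without a matching open Onset are errors; intervals still open
    after the last event close at the last event's onset with a warning
    (the event file does not know the recording end).
    """
    issues: List[ValidationIssue] = []
    open_by_name: Dict[str, EnduringEvent] = {}
    out: List[EnduringEvent] = []
    last_onset = 0.0

    for ev in events:
        last_onset = ev.onset
        if ev.annotation.is_empty():
            continue
        for group in ev.annotation.iter_groups():
            def_ref, onset, offset, duration = _classify_group(group)
            if duration is not None:
                seconds = _duration_seconds(duration, None)
                name = ""
                if def_ref is not None:
                    name = split_marker(def_ref, "def") or ""
                scope = EnduringEvent(
                    def_name=name, start=ev.onset, end=ev.onset + seconds,
                    annotation=_scope_annotation(group, [duration], defs),
                    source_rows=(ev.row_index, None))
                out.append(scope)
                continue
            if def_ref is None or (onset is None and offset is None):
                continue
            name = split_marker(def_ref, "def") or ""
            key = name.lower()
            if onset is not None:
                prior = open_by_name.pop(key, None)
                if prior is not None:
                    prior.end = ev.onset
                scope = EnduringEvent(
                    def_name=name, start=ev.onset, end=None,
                    annotation=_scope_annotation(group, [onset], defs),
                    source_rows=(ev.row_index, None))
                open_by_name[key] = scope
                out.append(scope)
            else:
                prior = open_by_name.pop(key, None)
                if prior is None:
                    issues.append(ValidationIssue(
                        OFFSET_WITHOUT_ONSET,
                        f"Offset for {name!r} at {ev.onset} s has no open "
                        f"Onset", ERROR, row=ev.row_index))
                    continue
                prior.end = ev.onset
                prior.source_rows = (prior.source_rows[0], ev.row_index)

    for scope in open_by_name.values():
        scope.end = last_onset
        scope.flagged_unclosed = True
        issues.append(ValidationIssue(
            UNCLOSED_ONSET,
            f"{scope.def_name!r} opened at {scope.start} s never closed; "
            f"closing at last event ({last_onset} s)", WARNING,
            row=scope.source_rows[0]))
    out.sort(key=lambda e: (e.start, e.def_name))
    return out, issues


_EVENT_CONTEXT = "event-context"


def _has_context_group(annotation: st.HedString) -> bool:
    for group in annotation.iter_groups():
        if any(split_marker(t, _EVENT_CONTEXT) is not None
               for t in group.tags()):
            return True
    return False


def insert_event_context(
    events: Sequence[AssembledEvent],
    enduring: Sequence[EnduringEvent],
    schemas: Optional[SchemaSet] = None,
) -> List[AssembledEvent]:
    """Append one ``(Event-context, ...)`` group per event with ongoing scopes.

    Each event at time ``t`` receives a copy of the annotation of every
    enduring event with ``start <= t < end``, except scopes whose opening or
    closing marker row is the event itself. Events with nothing ongoing are
    returned unchanged (no empty context group). Passing an event that
    already carries an Event-context group raises — insertion is a one-shot
    analysis step, not idempotent by silent skipping.

    When ``schemas`` is given, inserted copies are rewritten to long form.
    """
    out: List[AssembledEvent] = []
    for ev in events:
        if _has_context_group(ev.annotation):
            raise HedError("CONTEXT_ALREADY_INSERTED",
                           f"row {ev.row_index} already has an Event-context "
                           f"group")
        ongoing = [sc for sc in enduring
                   if sc.contains(ev.onset)
                   and ev.row_index not in sc.source_rows]
        if not ongoing:
            out.append(ev)
            continue
        ongoing.sort(key=lambda s: (s.start, s.def_name))
        copies: List[st.HedGroup] = []
        for sc in ongoing:
            copy = sc.annotation.copy()
            if schemas is not None:
                as_string = st.to_long(
                    st.HedString(top=copy.members), schemas)
                copy = st.HedGroup(members=as_string.top)
            copies.append(copy)
        context = st.HedGroup(members=[st.HedTag("Event-context"), *copies])
        annotation = ev.annotation.copy()
        annotation.top.append(context)
        out.append(AssembledEvent(ev.onset, ev.duration, annotation,
                                  ev.row_index))
    return out


def extract_timeline(
    enduring: Sequence[EnduringEvent],
    defs: DefinitionSet,
    schemas: SchemaSet,
) -> Timeline:
    """Place organizational enduring events onto per-kind timeline tracks.

    A scope lands on the ``Task`` track when its (expanded) annotation
    contains a tag resolving into the Task subtree, and so on for the other
    organizational kinds; the interval label is the defined name. Scopes
    without organizational tags do not appear.
    """
    timeline = Timeline()
    track_paths = {}
    for kind in ORGANIZATIONAL_TRACKS:
        node = schemas.base.node_by_term(kind)
        track_paths[kind] = node.path if node is not None else kind

    for scope in enduring:
        if not scope.closed:
            continue
        paths = set()
        as_string = st.HedString(top=[m.copy() for m in
                                      scope.annotation.members])
        st.resolve(as_string, schemas)
        for tag in as_string.iter_tags():
            if tag.resolved_path:
                paths.add(tag.resolved_path)
        for kind, prefix in track_paths.items():
            if any(p == prefix or p.startswith(prefix + "/") for p in paths):
                label = scope.def_name or kind
                timeline.tracks[kind].append((label, scope.start, scope.end))
    for track in timeline.tracks.values():
        track.sort(key=lambda rec: rec[1])
    return timeline
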