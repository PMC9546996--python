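"""Bundled mini vocabulary and synthetic experiment-design generators.

The fixture schema is a small but complete vocabulary mirroring the base
schema's shape: six top-level categories with second-level fan-outs
Event(7), Agent(6), Action(5), Item(4), Property(7), Relation(5), unique
mapping throughout, and the organizational machinery (Definition / Def /
Def-expand, Event-context, Onset / Offset / Duration, Recording / Task /
Time-block / Condition-variable / Experimental-trial) needed to express
experiment structure.

``generate_design`` emits a synthetic recording — events TSV, sidecar JSON,
and a definitions file — for one of three classic single-session designs of
a two-task, two-condition study:

1. one Task and one Condition-variable span the whole recording, which is
   split into Time-blocks separated by relief breaks;
2. one Task/Condition-variable pair per Time-block, counterbalanced across
   blocks;
3. a single Task and Time-block, with the Condition-variable drawn at random
   for every Experimental-trial.

Every trial contains three instantaneous events — stimulus (Sensory-event),
response (Agent-action), feedback (Sensory-event) — and is wrapped in a
valued Experimental-trial scope via a Duration group. Output is
deterministic given the seed, which is recorded in the sidecar.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from .issues import HedError
from .schema import HedSchema, SchemaSet, load_schema, serialize_schema

FIXTURE_SCHEMA_WIKI = '''\
HED version="1.0.0" library=""

Event Something that happens at a moment or over an interval during the recording
* Sensory-event A perceivable stimulus reaches the participant
* Agent-action An action performed by an agent, typically the participant
* Data-feature A feature computed from or observed in the recorded data
* Experiment-control An event issued by the experiment control software
* Experiment-procedure A procedural step of running the experiment
* Experiment-structure An event marking the structure of the experiment
* Measurement-event A value acquired from a measurement device

Agent An entity that can act on or perceive the environment
* Animal-agent A non-human animal agent
* Avatar-agent A graphical stand-in for an agent
* Controller-agent An automatic controller acting on the experiment
* Human-agent A human, usually the participant or experimenter
* Robotic-agent A robotic device acting as an agent
* Software-agent A software process acting as an agent

Action A motion or activity performed by an agent
* Communicate Convey information to another agent
* Move Move the body or an object
** Press Push down on something, such as a response button
** Reach Extend a limb toward a target
* Perceive Receive sensory input
* Perform Carry out a task or procedure
* Think Engage in covert cognitive activity

Item A physical, virtual, or symbolic thing
* Biological-item An item that is part of or produced by an organism
* Language-item A linguistic unit such as a word or sentence
* Object An inanimate thing, real or virtual
** Geometric-object An idealized geometric form
*** 2D-shape A two-dimensional shape
**** Cross A cross shape
**** Ellipse An ellipse
**** Rectangle A four-sided shape with right angles
**** Square A rectangle with equal sides
**** Triangle A three-sided shape
*** 3D-shape A three-dimensional shape
** Man-made-object {extensionAllowed} A manufactured object
** Natural-object A naturally occurring object
* Sound-item An auditory item

Property An attribute, quality, or descriptor attached to other tags
* Agent-property A property of an agent
* Data-property A property of the recorded data or its markers
** Data-marker A marker placed on the data timeline
*** Temporal-marker A marker of temporal structure
**** Onset The start of an enduring event
**** Offset The end of an enduring event
**** Pause A temporary interruption
** Data-value A value attached to the data
*** Temporal-value A value with units of time
**** Delay {takesValue, unitClass=time} Time elapsed relative to a reference event
**** Duration {takesValue, unitClass=time} The temporal extent of an enduring event
*** Spatial-value A value with units of length
**** Size {takesValue, unitClass=physicalLength} The spatial extent of something
* Environmental-property A property of the surrounding environment
* Informational-property Information attached for identification or bookkeeping
** Description {takesValue} A free-text elaboration
** Label {takesValue} A brief identifying label
** Metadata Structured metadata references
*** CogAtlas {takesValue} A Cognitive Atlas term identifier
*** CogPo {takesValue} A CogPO term identifier
* Organizational-property Tags encoding experiment organization and analysis structure
** Condition-variable An experimental condition or control variable
** Def {takesValue} A reference to a named definition
** Def-expand {takesValue} Marker wrapping an expanded definition
** Definition {takesValue} Declares a named reusable tag group
** Event-context Group holding annotations of ongoing enduring events
** Experimental-trial {takesValue} A data segment containing one trial sequence
** Recording The data recording as a whole
** Task The task the participant is performing
** Time-block A contiguous block of time within the recording
* Sensory-property A property of sensory stimulation or perception
** Sensory-attribute An attribute of a sensory percept
*** Color The perceived color of something
**** Black Black color
**** Blue Blue color
**** Green Green color
**** Red Red color
**** White White color
*** Luminance The perceived brightness
** Sensory-presentation How a stimulus is presented
*** Auditory-presentation Presentation through hearing
*** Tactile-presentation Presentation through touch
*** Visual-presentation Presentation through vision
* Task-property A property describing the role of something in the task
** Task-event-role The role an event plays in the task

Relation A relationship between two entities
* Comparative-relation A comparison between entities
* Connective-relation A connection between entities
* Directional-relation A directed spatial relation
* Logical-relation A logical relation between statements
* Spatiotemporal-relation A relation in space and time

!# unit classes
* time {default=s} s, ms
* physicalLength {default=m} m, cm, mm
'''

CLINICAL_LIBRARY_WIKI = '''\
HED version="0.2.0" library="clinical"

Clinical-finding A clinically notable feature of the recording
* Epileptiform-activity Activity suggestive of epileptic processes
** Spike A transient sharp waveform
** Sharp-wave A sharp transient slower than a spike
* Artifact A non-cerebral contamination of the signal
** Eye-blink-artifact Signal deflection caused by an eye blink
** Muscle-artifact Contamination from muscle activity
'''


def build_fixture_schema() -> HedSchema:
    """Load the bundled mini base schema."""
    return load_schema(FIXTURE_SCHEMA_WIKI, "wiki")


def build_clinical_library() -> HedSchema:
    """Load the bundled mini clinical library schema."""
    return load_schema(CLINICAL_LIBRARY_WIKI, "wiki")


def fixture_schema_set() -> SchemaSet:
    return SchemaSet(build_fixture_schema())


def write_fixture_schema(directory) -> Dict[str, Path]:
    """Write the fixture schema in both dialects; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = build_fixture_schema()
    out = {}
    for dialect, ext in (("wiki", "mediawiki"), ("xml", "xml")):
        path = directory / f"fixture_schema.{ext}"
        path.write_text(serialize_schema(schema, dialect), encoding="utf-8")
        out[dialect] = path
    return out


# ---------------------------------------------------------------------------
# Synthetic experiment designs
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    design: int
    n_blocks: int = 2
    trials_per_block: int = 10
    trial_period: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.design not in (1, 2, 3):
            raise HedError("INVALID_SPEC", f"design must be 1, 2, or 3, "
                                           f"got {self.design}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise HedError("INVALID_SPEC", "counts must be >= 1")
        if not self.trial_period > 0:
            raise HedError("INVALID_SPEC", "trial_period must be > 0")


@dataclass
class GeneratedDesign:
    spec: DesignSpec
    events_tsv: str
    sidecar_json: str
    definitions_txt: str
    record_span: Tuple[float, float]

    def write(self, directory, prefix: str = "design") -> Dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": directory / f"{prefix}_events.tsv",
            "sidecar": directory / f"{prefix}_events.json",
            "defs": directory / f"{prefix}_defs.txt",
        }
        paths["events"].write_text(self.events_tsv, encoding="utf-8")
        paths["sidecar"].write_text(self.sidecar_json, encoding="utf-8")
        paths["defs"].write_text(self.definitions_txt, encoding="utf-8")
        return paths


_TASK_DEFS = {
    "ViewShapes": "(Definition/ViewShapes, (Task, CogAtlas/trm_view_shapes))",
    "CountShapes": "(Definition/CountShapes, (Task, CogAtlas/trm_count_shapes))",
}
_COND_DEFS = {
    "SlowPresentation":
        "(Definition/SlowPresentation, (Condition-variable, Label/Slow))",
    "FastPresentation":
        "(Definition/FastPresentation, (Condition-variable, Label/Fast))",
}
_TRIAL_DEF = "(Definition/Trial/#, (Experimental-trial/#))"

_SIDECAR_EVENT_TYPES = {
    "stimulus": "Sensory-event, Visual-presentation, "
                "((Triangle, Red), (Square, Green))",
    "response": "Agent-action, (Human-agent, Press)",
    "feedback": "Sensory-event, Visual-presentation, (Square, Green)",
}


def _fmt(t: float) -> str:
    return f"{t:.3f}"


def generate_design(spec: DesignSpec) -> GeneratedDesign:
    """Generate one synthetic recording for the requested design.

    Trials are laid out at fixed ``trial_period`` spacing; consecutive
    blocks are separated by a relief gap of five trial periods, producing
    visible gaps in extracted timelines. The response latency of each trial
    is drawn uniformly from [0.35, 0.65] of a trial period by a generator
    seeded from ``spec.seed``, so identical specs give byte-identical files.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    period = spec.trial_period
    t0 = 1.0
    gap = 5.0 * period
    block_len = spec.trials_per_block * period

    if spec.design == 3:
        n_blocks = 1
        trials_per_block = spec.n_blocks * spec.trials_per_block
        block_len = trials_per_block * period
    else:
        n_blocks = spec.n_blocks
        trials_per_block = spec.trials_per_block

    def block_start(b: int) -> float:
        return t0 + b * (block_len + gap)

    recording_end = block_start(n_blocks - 1) + block_len

    defs_lines: List[str] = [_TRIAL_DEF]
    rows: List[Tuple[float, str, str, str]] = []  # (onset, etype, rt, literal)

    def add(onset: float, etype: str = "n/a", rt: str = "n/a",
            literal: str = "n/a", duration: str = "n/a") -> None:
        rows.append((onset, etype, rt, literal, duration))

    block_names = [f"Block-{b + 1}" for b in range(n_blocks)]
    for name in block_names:
        defs_lines.append(f"(Definition/{name}, (Time-block, Label/{name}))")

    if spec.design == 1:
        defs_lines += [_TASK_DEFS["ViewShapes"],
                       _COND_DEFS["SlowPresentation"]]
        add(t0 - 0.5,
            literal="(Def/ViewShapes, Onset), (Def/SlowPresentation, Onset)")
        add(recording_end,
            literal="(Def/ViewShapes, Offset), (Def/SlowPresentation, Offset)")
    elif spec.design == 2:
        defs_lines += list(_TASK_DEFS.values()) + list(_COND_DEFS.values())
        task_names = list(_TASK_DEFS)
        cond_names = list(_COND_DEFS)
        for b in range(n_blocks):
            task = task_names[b % 2]
            cond = cond_names[b % 2]
            add(block_start(b),
                literal=f"(Def/{task}, Onset), (Def/{cond}, Onset)")
            add(block_start(b) + block_len,
                literal=f"(Def/{task}, Offset), (Def/{cond}, Offset)")
    else:
        defs_lines += [_TASK_DEFS["ViewShapes"]] + list(_COND_DEFS.values())
        add(t0 - 0.5, literal="(Def/ViewShapes, Onset)")
        add(recording_end, literal="(Def/ViewShapes, Offset)")

    trial_no = 0
    for b in range(n_blocks):
        bs = block_start(b)
        add(bs, literal=f"(Def/{block_names[b]}, Onset)")
        for i in range(trials_per_block):
            trial_no += 1
            ts = bs + i * period
            marker = f"(Def/Trial/{trial_no}, Duration/{_fmt(period)} s)"
            if spec.design == 3:
                cond = rng.choice(["SlowPresentation", "FastPresentation"])
                marker += f", (Def/{cond}, Onset)"
                add(ts + 0.9 * period, literal=f"(Def/{cond}, Offset)")
            add(ts, literal=marker)
            rt = round(rng.uniform(0.35, 0.65) * period, 3)
            add(ts, etype="stimulus", duration="0.100")
            add(ts + rt, etype="response", rt=_fmt(rt * 1000.0))
            add(ts + 0.75 * period, etype="feedback")
        add(bs + block_len, literal=f"(Def/{block_names[b]}, Offset)")

    rows.sort(key=lambda r: r[0])
    lines = ["onset\tduration\tevent_type\tresponse_time\tHED"]
    for onset, etype, rt, literal, duration in rows:
        lines.append(
            f"{_fmt(onset)}\t{duration}\t{etype}\t{rt}\t{literal}")
    events_tsv = "\n".join(lines) + "\n"

    sidecar = {
        "event_type": {"HED": dict(_SIDECAR_EVENT_TYPES)},
        "response_time": {"HED": "Delay/# ms"},
        "generated": {
            "design": spec.design, "seed": spec.seed,
            "n_blocks": spec.n_blocks,
            "trials_per_block": spec.trials_per_block,
            "trial_period": spec.trial_period,
        },
    }
    return GeneratedDesign(
        spec=spec,
        events_tsv=events_tsv,
        sidecar_json=json.dumps(sidecar, indent=2) + "\n",
        definitions_txt="\n".join(defs_lines) + "\n",
        record_span=(0.0, recording_end + 1.0),
    )
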