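# hedkit

An annotation engine for **Hierarchical Event Descriptors (HED)** — the
controlled-vocabulary system used to describe what happened, moment by
moment, during electrophysiological (EEG/MEG/iEEG) recordings so that event
records become machine-actionable across studies. `hedkit` is aimed at
researchers and tool builders who need to validate, transform, and search
HED annotations in BIDS-style datasets without a GUI or a web service.

## What it implements

A HED **schema** is a forest of uniquely named terms. Under the *unique
mapping* rule — each term occurs at exactly one position — any suffix of a
node's full path identifies it, so annotators can write the compact **short
form** (`Visual-presentation`) and tools can expand it mechanically to the
**long form**
(`Property/Sensory-property/Sensory-presentation/Visual-presentation`).
On top of the schema layer, `hedkit` provides:

- **Schema engine** — load/serialize schemas in a wiki-style indented text
  dialect and an XML dialect, lint them (uniqueness, structural sparsity:
  warning at ≥ 10 children per node, ideal 3–7), and merge namespaced
  library schemas (`sc:Spike`) next to a base vocabulary.
- **HED strings** — parse comma-separated tags and arbitrarily nested
  parenthesized tag groups; validate against the vocabulary (values,
  unit classes, duplicates, definition references); convert short ↔ long;
  compute an order-insensitive canonical form so annotation equivalence is
  a string comparison.
- **Definitions** — `(Definition/Name, (contents))` declarations, referenced
  as `Def/Name` and expanded at analysis time into
  `(Def-expand/Name, (contents))`; valued definitions substitute
  `Def/Name/value` for a `#` placeholder.
- **Event assembly** — combine a BIDS `_events.tsv` with a JSON sidecar
  (categorical and `#`-placeholder value columns) into one validated HED
  string per event.
- **Temporal context** — resolve *enduring events* from `(Def/Name, Onset)`
  / `(Def/Name, Offset)` pairs and `Duration/v` groups into time intervals;
  insert an `(Event-context, …)` group into every event occurring inside an
  interval; extract experiment timelines from the organizational tags
  (`Task`, `Time-block`, `Condition-variable`, `Experimental-trial`,
  `Recording`).
- **Search & epochs** — boolean tag queries with subtree matching
  (`2D-shape` matches `…/2D-shape/Triangle`), and extraction of time-locked
  epoch windows around matched events.
- **Fixtures** — a bundled mini vocabulary (six top-level categories with
  second-level fan-outs Event 7, Agent 6, Action 5, Item 4, Property 7,
  Relation 5) and a deterministic generator for three synthetic experiment
  designs, so the whole pipeline runs offline.

## Worked example

```python
import hedkit as hk

schemas = hk.fixture_schema_set()

# short-form annotation of a visual stimulus: a red triangle and green square
s = hk.parse("Sensory-event, Visual-presentation, "
             "((Triangle, Red), (Square, Green))")
print(hk.to_long(s, schemas).text())

# enduring movie presentation: onset at 20 s, offset at 100 s
defs, _ = hk.collect_definitions(
    [hk.parse("(Definition/PlayMovie, (Visual-presentation, Label/MovieClip))")])
rows = [(20.0, "(Def/PlayMovie, Onset)"), (50.0, "Sensory-event"),
        (100.0, "(Def/PlayMovie, Offset)")]
events = [hk.AssembledEvent(t, None, hk.parse(x), i)
          for i, (t, x) in enumerate(rows)]
scopes, _ = hk.resolve_scopes(events, defs)
print(f"scope: {scopes[0].def_name} [{scopes[0].start}, {scopes[0].end}] s")
with_ctx = hk.insert_event_context(events, scopes, schemas)
print(with_ctx[1].annotation.text())
```

prints

```
Event/Sensory-event, Property/Sensory-property/Sensory-presentation/Visual-presentation, ((Item/Object/Geometric-object/2D-shape/Triangle, Property/Sensory-property/Sensory-attribute/Color/Red), (Item/Object/Geometric-object/2D-shape/Square, Property/Sensory-property/Sensory-attribute/Color/Green))
scope: PlayMovie [20.0, 100.0] s
Sensory-event, (Event-context, ((Property/Organizational-property/Def-expand/PlayMovie, (Property/Sensory-property/Sensory-presentation/Visual-presentation, Property/Informational-property/Label/MovieClip))))
```

The first line is the automatic short→long expansion of the stimulus
annotation. The next lines show the movie presentation resolved to the
interval [20, 100] s, and the intervening event at 50 s inheriting a copy of
the movie's annotation inside its single `Event-context` group — it
happened *while* the movie played, without being confused with the movie's
own onset or offset.

The same operations are available from the shell:

```bash
hedkit generate --design 1 --seed 0 --out demo/
hedkit validate --schema demo/fixture_schema.mediawiki \
    --defs demo/design1_defs.txt \
    --events demo/design1_events.tsv --sidecar demo/design1_events.json
hedkit timeline --schema demo/fixture_schema.mediawiki \
    --defs demo/design1_defs.txt \
    --events demo/design1_events.tsv --sidecar demo/design1_events.json
```

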