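# Methods

This note records how `hedkit` models HED annotation, the choices made where
the design was genuinely open, and what the bundled synthetic data does and
does not exercise.

## Vocabulary model

A schema is a forest of named nodes; a node's identity is its full
root-to-node path. The engine enforces *unique mapping* — a term name may
occur at only one position per schema — at load time: strict loading fails
on the first duplicate, while a permissive mode builds the tree without a
term index so the linter can enumerate every duplicate. Term matching is
case-insensitive throughout, and canonical output always uses the schema's
stored casing; this treats hand-typed annotations (`visual-PRESENTATION`)
as equivalent to schema spelling, which we judged more robust than
case-sensitive matching at the cost of forbidding case-distinguished terms.

Two serializations are supported and round-trip losslessly. The wiki
dialect is line-oriented: depth is the count of leading asterisks,
attributes sit in `{...}` braces (`takesValue`, `extensionAllowed`,
`unitClass=time`, repeatable `suggestedTag=`/`relatedTag=`), the
description is the rest of the line, and unit classes follow a
`!# unit classes` marker. The XML dialect mirrors the tree with one
`<node>` element per term. Only these two dialects are parsed; no attempt
is made to read other schema exchange formats.

Library schemas are registered under namespace identifiers and resolved
only via the `ns:` prefix; an unprefixed tag never falls through to a
library, so term collisions between libraries, or between a library and the
base schema, are legal and unambiguous. The alternative reading — letting
libraries shadow or extend base lookup — was rejected because it would make
the meaning of an annotation depend on which libraries happen to be loaded.

Tag resolution walks the written components downward from the first
component's unique node. Leftover components after the walk are a value
(when the reached node has `takesValue`; an optional unit follows the value
after a single space, e.g. `Duration/0.5 s`), novel extension terms (when
the node has `extensionAllowed`; reported as a warning, not an error), an
`INVALID_PARENT` error when the next component exists elsewhere in the
schema, or a `VALUE_WITHOUT_PLACEHOLDER` error otherwise.

## Strings, canonical form, validation

The grammar is commas and balanced parentheses only; all other whitespace
is insignificant. Empty groups, empty tags, and trailing commas are errors
rather than silently dropped — an annotation that parses differently from
how it reads is worse than one that fails loudly. The canonical form is
long form with members recursively sorted (tags before groups, each
lexicographically on lower-cased long text), so two annotations differing
only in member order compare equal as strings.

Validation returns every issue rather than stopping at the first, in a
fixed order: resolution (including value/placeholder consistency), unit
membership, duplicate identical tags within a single group (warning;
duplicates across groups are legal since groups carry distinct semantics),
`Def/Name` references against the known definition set, Definition-group
syntax, extension warnings.

## Definitions

A declaration is exactly `(Definition/Name, (contents))`; contents may not
contain `Definition`, `Def`, or `Def-expand`, which makes expansion
non-recursive by construction. Re-declaring a name with structurally
identical contents is a no-op; different contents are an error. Valued
definitions carry a `#` placeholder in their contents (declared
`Definition/Name/#`); referencing one without a value is an error, and
substitution is textual. Expansion rewrites `Def/Name[/v]` to
`(Def-expand/Name[/v], (contents))` and is idempotent; `shrink_defs`
inverts it when the expanded contents still match the registry, giving a
lossless round trip. Definition groups found during event assembly are
collected and then removed from row annotations: declarations are not
events.

## Event assembly

Events tables are TSV with an `onset` column (seconds, finite, ≥ 0);
`duration` and other cells use `n/a` for missing. Rows are processed in
onset order (stable sort). Column contributions are concatenated in sorted
column-name order with the literal `HED` column last; the ordering is
arbitrary but fixed, chosen so identical inputs yield byte-identical
output. When both a categorical map and a literal `HED` cell annotate a
row, both are kept — there is no precedence rule to get wrong. A `#` in a
value-column template is replaced by the cell text and then validated like
any other value, including unit-class checks.

## Temporal scopes and Event-context

Scope bookkeeping is a single forward scan keyed by lower-cased defined
name: Onset opens (closing any interval already open under that name at the
new onset), Offset closes, `Duration/v` creates a closed interval
`[onset, onset + v]` immediately (multiple Duration groups per event are
allowed; `ms` values are converted to seconds via the time unit class).
Offsets without a matching Onset are errors. Intervals still open after the
last event are closed at the last event's onset and flagged — the event
file does not know when the recording ended, and extrapolating to infinity
would poison every later query.

Membership is half-open, `start ≤ t < end`: an event simultaneous with the
Offset marker is outside, one simultaneous with the Onset is inside, which
avoids double counting at re-onsets. The opening and closing marker rows of
an interval never receive that interval's context, keeping "the movie
started" distinct from "this happened during the movie". Each event gains
at most one `Event-context` group, with member copies ordered by
(start, name) for determinism and rewritten to long form when a schema set
is supplied; attempting to insert context twice raises instead of silently
duplicating. Duration-created intervals participate in context exactly like
Onset/Offset ones. Timeline extraction places closed intervals whose
annotation resolves into one of the organizational subtrees (`Task`,
`Time-block`, `Condition-variable`, `Experimental-trial`, `Recording`) on
the matching track, labeled by defined name; anonymous Duration scopes may
therefore appear with an empty-name label only if organizational tags are
present.

## Queries and epochs

A query term resolves through the same machinery as an annotation tag and
matches any tag whose long path equals the term's path or lies in its
subtree; a term written with a value requires an exact value match, a bare
term matches any value. Event-context contents are searched by default
(excludable per call or via the CLI flag), since "select everything that
happened during condition X" is the primary use of context. Epoch windows
`[onset − pre, onset + post]` that would cross the recording span are
dropped, not clipped: a truncated epoch is not comparable to complete ones
in time-locked averaging.

## Synthetic designs

The generator emulates a single-session visual discrimination study in
three layouts: (1) one task and one condition variable spanning a recording
with two time blocks separated by a relief break; (2) one task/condition
pair per block, counterbalanced; (3) a single task and block with the
condition drawn uniformly at random per trial. Defaults are 2 blocks × 10
trials at a 2 s trial period; the inter-block gap is five trial periods so
extracted timelines show visible gaps. Every trial contains a stimulus
(`Sensory-event`), a response (`Agent-action`, with latency drawn uniformly
from 0.35–0.65 of a trial period and recorded in a `response_time` value
column), and a feedback event, wrapped in a valued `Def/Trial/k` scope via
a Duration group; blocks, tasks, and conditions are marked with
Onset/Offset definition groups, the recommended practice for structural
annotation. A single seeded generator drives all randomness and the seed is
recorded in the sidecar, so outputs are byte-reproducible.

What the generator does not emulate: jittered or missing events, annotation
typos, overlapping tasks, multi-recording counterbalancing (a multi-session
study is n independent calls), and any signal payload. Passing tests
therefore demonstrate the correctness of the annotation machinery on
well-formed structured input, not robustness to the messiness of real
curated datasets.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale inputs: the 90-node fixture schema,
designs of 2 × 3 to 2 × 10 trials, a 200-trial run for the condition-label
frequency check (asserted within the two-sided 99% binomial band around
0.5), and a 1000-event × 50-interval random corpus for the context-insertion
oracle, which is compared member-for-member against an all-pairs overlap
check. Times are plain floats in seconds; no tolerance is applied to
interval arithmetic since all generated onsets are exactly representable to
three decimals.

## Known limitations

- Orthogonality ("terms used independently live in different subtrees")
  is not machine-checkable without usage data; the linter covers
  uniqueness, sparsity, descriptions, and term characters only.
- `suggestedTag`/`relatedTag` are parsed and preserved but drive no
  behavior (no autocomplete UI).
- Definitions are assumed to reference library tags with an explicit
  namespace; unprefixed references resolve only against the base schema.
- The wiki dialect is this package's own line grammar; it is not a parser
  for any external schema file format.
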