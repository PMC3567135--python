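# Methods

This note records the conventions, parameter choices and known limitations
behind each component. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Document model

Annotations are typed, feature-bearing spans over an immutable text,
grouped into named sets (the default set is named `""`). Offsets are
0-based, half-open `[start, end)`, counted in **Unicode code points** — not
bytes and not UTF-16 units. Code points are the one convention that is
unambiguous across platforms and directly testable; no claim is made that
other systems with the same architecture count the same way. Zero-length
annotations are legal (empty elements such as `<br>` need them).
Annotation ids are per-document monotone integers starting at 0; deletion
never reuses an id, so ids are stable provenance keys.

Inline markup conversion parses XML with lxml and walks the element tree,
replaying the text concatenation so each element's annotation covers
exactly its text content. Tag-soup HTML is accepted best-effort through
lxml's HTML parser with annotations restricted to a whitelist (`p`, `div`,
`b`, `i`, `a`, `span`, `br`).

The stand-off JSON schema is
`{"text", "features", "sets": {name: [{"id", "type", "start", "end",
"features"}]}}`. Feature values are scalars; date values are encoded as
`{"$date": "YYYY-MM-DD"}` so that round-tripping preserves types exactly.
Round-trip identity over randomly generated documents is enforced by a
seeded property test.

## Tokenizer and sentence splitter

The tokenizer is a total, ordered rule table: an alphanumeric run is one
token (kind `number` if all digits, else `word`), a whitespace run is one
`SpaceToken`, and any other character is a single `punctuation` token.
Keeping mixed alphanumeric runs whole is the essential biomedical choice —
`p53`, `BRCA1` and `TrkB` must not split. Word tokens carry an orthography
feature (`upperInitial` / `allCaps` / `lowercase` / `mixedCaps`). Because
the rules are total, Token+SpaceToken spans tile the text exactly, which
both the index and the gazetteer rely on.

Sentences end at `.`, `!` or `?` tokens, except a period directly between
two number tokens with no intervening space (`3.2`); trailing tokens
without a terminator form a final sentence. A single capital letter
followed by a period is treated as a boundary — a deliberate
simplification; no abbreviation dictionary is consulted.

## Gazetteer

Terms load from TSV (`term<TAB>majorType[<TAB>minorType[<TAB>inst]]`,
`#` comments). Internal whitespace runs collapse to one space for
matching; case-insensitive mode is plain case folding of both sides, with
no stemming. Matching is token-aligned (a match must start and end on
token boundaries) and leftmost-longest: from each candidate start the
longest matching term wins and scanning resumes after its end, so Lookups
never overlap. A brute-force oracle (enumerate all token-aligned
substrings, then apply the same overlap policy) pins this behaviour in a
property test.

## Pattern engine

A pattern is a regular expression over annotation constraints. The core
semantic decision is what "followed by" means when annotation types do not
tile the text: after consuming annotation A, the candidate successors are
the annotations of the input types whose start is the **minimal start ≥
A.end**, with all annotations at that start as alternatives. This is
decidable without token alignment and makes matching independent of which
annotation types happen to exist between two constraints.

Quantifiers are greedy in transduction; `match` itself enumerates *all*
successor-valid chains accepted by the expression (the brute-force oracle
in the tests enumerates chains up to length 6 and checks them against an
independent AST acceptor). Empty-width overall matches are discarded,
which also prevents `*` loops. Feature tests are limited to `==`/`!=`.

Grammar control styles: `all` fires every match of every rule; `appelt`
scans left to right and at each position fires only the longest match,
with ties broken by higher priority, then earlier rule order, then resumes
after the fired match's end. The length–priority–order tie-break is stated
explicitly because it determines which of two competing date/score
readings wins (see below).

Right-hand sides create annotations over labelled groups; feature
templates may hold literals, the bound group's covered text
(`:label@string`) or a feature copied from the group's first annotation
(`:label@feat`). Multi-phase cascades are simply sequential
`apply_grammar` calls.

## Abbreviation detection

Candidates come from parentheticals inside a sentence, preferring
innermost parentheses: if the parenthetical has ≤ 2 words it is the short
form and the long form is a window of `min(|SF| + 5, 2·|SF|)` words
(characters of the short form) to the left; otherwise the parenthetical is
the long form of the single word before the parenthesis. These window
constants are the canonical ones for this family of algorithms.

Validation requires every letter/digit of the short form to occur in order
in the long form, with the short form's first character starting one of
the long form's words; the long form is then trimmed to the shortest word
suffix that still validates *and* remains longer than the short form.
Accepted pairs are annotated in situ (`Abbrev` with `longForm` /
`shortForm` on both spans). In coreference mode, each later standalone
token equal to a known short form inherits the **most recently** defined
matching pair's long form — recency, not frequency, resolves ambiguous
short forms. Re-running the detector is a no-op (existing identical
annotations are not duplicated).

## Clinical score extraction

Two grammar phases (shipped as text files under `annokit/grammars/`)
annotate month and weekday names, assessment triggers (the token `MMSE`,
the spelled-out long form with optional hyphen), date expressions (numeric
`d/m/y` and `d-m-y`, day-month-year, month-year, day-month, bare month,
weekday) and score patterns (`number / number`). Appelt control resolves
the real ambiguities positionally: `12/03/2010` (five tokens) beats the
score reading `12/03` (three tokens) at the same start, and `12 March
2010` beats the bare-month reading.

Extraction is per sentence and deliberately favours precision over recall:

- a sentence without a non-negated trigger yields nothing, however many
  `N/M` patterns it contains;
- negation is a stop-list (`not done`, `unable`, `refused`, `declined`)
  within 3 tokens of the trigger — full negation-scope detection is out of
  scope.

Each score binds to the nearest date expression at or after it within the
sentence, else the nearest one before it, else the document instance date.
This handles coordinations ("scored 25/30 in November then 22/30 in
December") by giving each score its own following month.

Date normalization: explicit dates parse as written (day-first for numeric
forms, via dateutil); weekday names resolve to the most recent such
weekday **on or before** the anchor (clinical notes describe past events);
bare month names resolve to day 15 of the anchor year (a midpoint that
keeps month-resolution dates comparable); the anchor is the nearest
preceding explicit date in the text, else the document date. Unparseable
expressions fall back to the document date with `date_source="document"`.

Post-filter domain rules: the examination is scored out of 30, so events
with numerator > 30 or denominator ≠ 30 are dropped, as are events dated
after the parent record. Deduplication collapses events identical on
(document, numerator, denominator, date), keeping the earliest span.

The accepted trigger phrasings are the package's own rule set, documented
in the grammar files; no claim of fidelity to any deployed system's rules
is made.

## Evaluation

Alignment is greedy 1–1 in (start, end) order: exact (span + compared
features) pairs first, then — in lenient/average modes — overlap pairs
among the leftovers. Greedy order is the contract: it is deterministic and
cheap, and on strict matching it provably pairs as many as an optimal
assignment (the acceptance test verifies this by exhaustive enumeration);
on overlap matching rare configurations exist where an optimal matcher
would pair more, and the property test surfaces them while asserting the
greedy count never exceeds the optimal one. Average mode weights partial
(overlapping) pairs ½ in both precision and recall. F1 is defined as 0
when P + R = 0. Inter-annotator agreement is mean pairwise F1; no
chance-corrected statistic is offered because span annotation has no
natural chance baseline.

## Hybrid index

Annotations are mapped to token positions by the containing-token rule:
first = token containing the start offset, last = token containing
end − 1. Zero-length annotations and annotations falling entirely in
whitespace align to no token and are skipped (counted in
`skipped_annotations`). Sequence adjacency is token-level (the next hit
starts at the previous hit's last + 1). `And` returns minimal covering
spans so it composes with `IN`/`OVER`; `Or` merges hit lists. The KB is a
plain triple set with `type`/`subClassOf` closure only — class expansion
returns Lookup hits whose `inst` is an instance of any subclass of the
queried class. Results are deduplicated and ordered by (document id,
first, last); federation is the multiset union of per-shard results
re-sorted, required (and tested) to be identical to a single index over
the union corpus, with overlapping document ids rejected.

## Synthetic fixtures

`gen_notes` emulates short clinical-note phrasing with one template
instance per document plus optional filler sentences: a plain mention with
an explicit past date, a weekday-relative mention, a two-score month
coordination, a negated mention, and — at `error_rate` — an invalid score
(numerator 31–99, or denominator in {10, 20, 25, 28}) or a future-dated
assessment. Document instance dates are drawn from the configured date range
with month ≥ 3 so that coordination months (two consecutive months
strictly before the instance month) always normalize to past dates. Gold
events are computed with the text at generation time, never re-derived by
the system under test. One filler sentence (`BP 120/80 recorded.`)
contains a score-like pattern with no trigger, exercising the precision
rule.

What the fixtures do **not** emulate: real clinical spelling noise,
formatting artefacts, template diversity or the distribution of real
clinical language. Passing the end-to-end recovery test therefore shows
the rules compose correctly on the stated phrasings; it is not an accuracy
claim about real records.

`gen_abstracts` embeds gazetteer terms and one `long form (SF)` definition
followed by a standalone short-form mention per document; `gen_random_graph`
produces uniformly random annotation graphs for the oracle equivalence
properties. All generators are pure functions of their seed.

## Problem sizes and numerical choices

The oracle-equivalence suites run at the sizes the properties need to be
convincing while staying cheap: 500 random documents (≤ 12 annotations,
pattern chains to length 6) for the pattern engine, 200 random corpora
(≤ 50 short documents, all ten query node types, plus 3-way federation
splits) for the index, 1000 documents for serialization/markup round
trips. All randomness is seeded; there are no tolerances anywhere —
every comparison in the package and its tests is exact (integer counts,
exact spans, exact dates).

## Known limitations

- Only `==`/`!=` feature tests in patterns and queries; no numeric ranges.
- No POS tagging, parsing, stemming or trainable models.
- Negation handling is a stop-list, not scope detection.
- The HTML reader is a whitelist subset, not a browser-grade parser.
- The KB does no reasoning beyond `type`/`subClassOf` closure.
- Greedy evaluation alignment can undercount overlap matches relative to
  an optimal assignment (surfaced, documented, accepted as the contract).
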