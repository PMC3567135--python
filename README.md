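# annokit

A desk-scale toolkit for biomedical text analytics built around **stand-off
annotation graphs**: the text of a document is stored once, immutably, and
every layer of markup — tokens, sentences, gazetteer lookups, abbreviations,
extracted clinical events — lives in named annotation sets whose members
point back into the text by character offsets. Because annotations never
touch the text, layers can overlap freely and can be produced, compared and
indexed independently.

On top of the document model the package provides:

- **Inline-markup conversion** — XML (and a tag-soup HTML subset) is
  stripped to plain text, each element becoming an annotation in the
  `"Original markups"` set, plus a JSON stand-off serialization that
  round-trips documents exactly.
- **Lexical processing** — a rule-based tokenizer tuned for biomedical text
  (gene symbols like `p53` stay one token; every punctuation character is
  its own token), a sentence splitter with numeric guards (`24/30`, `3.2`),
  and a token-aligned, leftmost-longest gazetteer producing `Lookup`
  annotations with `majorType`/`minorType`/`inst` features.
- **A pattern/transduction engine** — regular expressions whose atoms are
  annotation constraints, e.g.
  `{Person}{Token.category=="VBD"}{Organization}`, matched over the
  annotation sequence, with rules whose right-hand sides create new
  annotations (grammar files with `appelt`/`all` control styles).
- **Abbreviation detection** — `long form (SF)` definition harvesting with
  character-subsequence validation, in-situ `Abbrev` annotation, and
  coreference expansion of later short-form mentions.
- **A clinical score-extraction pipeline** — finds Mini Mental State
  Examination (MMSE) results (`N/30`) with their dates, normalizes relative
  dates ("Monday", "in March") against proximate explicit dates or the
  document instance date, applies domain sanity filters (scores are always
  out of 30; an assessment cannot post-date its record) and deduplicates.
- **Evaluation** — precision / recall / F1 against gold annotations under
  strict, lenient and average alignment, plus pairwise-F1 inter-annotator
  agreement.
- **A hybrid index** — one index answering queries that mix full-text
  terms, annotation constraints, sequence and containment operators and
  knowledge-base class expansion, with multi-shard federation.
- **Synthetic fixtures** — seeded generators for clinical-style notes with
  gold score events, gazetteer/abbreviation test texts, and random
  annotation graphs.

## Worked example

```python
import datetime as dt
import annokit as ak

text = (
    "Mini Mental State Examination (MMSE) was administered on admission. "
    "MMSE done on Monday, score 24/30. MMSE repeated, 22/30 in March. "
    "BP was 120/80."
)
doc = ak.create_document(text, {"date": dt.date(2011, 5, 20)})
for e in ak.mmse_pipeline(doc, doc_id="note-1"):
    print(e.doc_id, f"{e.numerator}/{e.denominator}", e.event_date, e.date_source, e.span)
```

prints

```
note-1 24/30 2011-05-16 relative (95, 100)
note-1 22/30 2011-03-15 relative (117, 122)
```

Two assessments are recovered. The first score, `24/30`, is dated by the
weekday expression "Monday": the note is dated Friday 2011-05-20, so the
most recent Monday on or before it is 2011-05-16. The second score binds to
the bare month name "March", which resolves to the 15th of that month in
the anchor year. `BP was 120/80` is *not* extracted — the pipeline favours
precision over recall and ignores score-like patterns in sentences without
an assessment trigger — and had a stray `45/30` appeared, the post-filter
would have dropped it because the examination is always scored out of 30.

The same machinery is scriptable from the shell:

```sh
annokit fixtures notes --n 20 --seed 7 --error-rate 0.2 notes/
annokit mmse notes/note-0000.json events.tsv
annokit query --pattern '{Token.kind=="number"}' --types Token notes/note-0000.json
```

## Layout

- `src/annokit/anno_model.py` — documents, annotation sets, serialization
- `src/annokit/lexical.py` — tokenizer, sentence splitter, gazetteer
- `src/annokit/patterns.py` — pattern language, matching, transduction
- `src/annokit/abbrev.py` — abbreviation pairs and coreference
- `src/annokit/clinical_extract.py` — the MMSE pipeline (+ `grammars/`)
- `src/annokit/evaluation.py` — P/R/F and inter-annotator agreement
- `src/annokit/hybrid_index.py` — hybrid index, KB, federation
- `src/annokit/fixtures.py` — seeded synthetic corpora
- `src/annokit/cli.py` — the `annokit` command

See `docs/methods.md` for the conventions and design choices in detail.
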