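"""Cognitive-score (MMSE) extraction from clinical free text.

The Mini Mental State Examination is scored out of 30 and is reported in
clinical notes in forms like "MMSE done on Monday, score 24/30".  The
pipeline finds assessment triggers (the short form "MMSE", its long form,
or a coreferred abbreviation), score patterns ``N/M``, and date
expressions using the pattern-grammar engine; binds each score to its
nearest date expression; normalizes relative dates against proximate
explicit dates or, as a last resort, the document instance date; then
applies domain-rule post-filters (scores are always out of 30; an
assessment cannot post-date its parent record) and deduplicates.

The pipeline deliberately favours precision over recall: a bare ``N/M``
with no assessment trigger in the same sentence is never extracted, and
a negated trigger ("MMSE not done") suppresses extraction.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from importlib import resources

from dateutil import parser as _dateparser

from .abbrev import detect_abbreviations
from .anno_model import Annotation, Document, select
from .lexical import SENTENCE, TOKEN, split_sentences, tokenize
from .patterns import Grammar, apply_grammar, parse_grammar

__all__ = [
    "ScoreEvent",
    "extract_scores",
    "normalize_date",
    "postfilter",
    "deduplicate",
    "mmse_pipeline",
    "load_mmse_grammars",
    "events_to_tsv",
]

TRIGGER = "MMSETrigger"
SCORE = "MMSEScore"
DATE_EXPR = "DateExpr"

#: the standard full score of the examination
MAX_SCORE = 30

#: negation triggers that suppress extraction near an assessment trigger
NEGATION_PHRASES = [("not", "done"), ("unable",), ("refused",), ("declined",)]
NEGATION_WINDOW = 3  # tokens on either side of the trigger


@dataclass(frozen=True)
class ScoreEvent:
    """One extracted assessment: score, normalized date and provenance."""

    numerator: int
    denominator: int
    event_date: _dt.date | None
    date_source: str  # explicit | relative | document
    doc_id: str
    span: tuple[int, int]

    def key(self) -> tuple:
        return (self.doc_id, self.numerator, self.denominator, self.event_date)


_GRAMMAR_CACHE: list[Grammar] | None = None


def load_mmse_grammars() -> list[Grammar]:
    """Load the two extraction phases shipped with the package."""
    global _GRAMMAR_CACHE
    if _GRAMMAR_CACHE is None:
        pkg = resources.files("annokit").joinpath("grammars")
        _GRAMMAR_CACHE = [
            parse_grammar(pkg.joinpath("dates_lexical.jape").read_text(encoding="utf-8")),
            parse_grammar(pkg.joinpath("mmse.jape").read_text(encoding="utf-8")),
        ]
    return _GRAMMAR_CACHE


# ---------------------------------------------------------------------------
# Date normalization

_WEEKDAYS = {
    "monday": 0, "tuesday": 1, "wednesday": 2, "thursday": 3,
    "friday": 4, "saturday": 5, "sunday": 6,
}
_MONTHS = {
    "january": 1, "jan": 1, "february": 2, "feb": 2, "march": 3, "mar": 3,
    "april": 4, "apr": 4, "may": 5, "june": 6, "jun": 6, "july": 7, "jul": 7,
    "august": 8, "aug": 8, "september": 9, "sep": 9, "sept": 9,
    "october": 10, "oct": 10, "november": 11, "nov": 11,
    "december": 12, "dec": 12,
}


def normalize_date(
    expr: str,
    context_dates: list[_dt.date],
    doc_date: _dt.date,
) -> tuple[_dt.date | None, str]:
    """Resolve a date expression to an ISO date and its provenance.

    Explicit dates parse as written (day-first for numeric forms).
    Weekday names resolve to the most recent such weekday on or before the
    anchor; bare month names resolve to the 15th of that month in the
    anchor's year.  The anchor is the nearest preceding explicit date in
    the text (the last of *context_dates*), else the document date.
    Unparseable input falls back to the document date.
    """
    anchor = context_dates[-1] if context_dates else doc_date
    expr = expr.strip()
    if not expr:
        return (doc_date, "document")

    low = expr.casefold()
    if low in _WEEKDAYS:
        target = _WEEKDAYS[low]
        delta = (anchor.weekday() - target) % 7
        return (anchor - _dt.timedelta(days=delta), "relative")

    # month-name forms: bare month, day+month, month+year, day+month+year
    words = re.findall(r"[A-Za-z]+|\d+", expr)
    month = next((_MONTHS[w.casefold()] for w in words if w.casefold() in _MONTHS), None)
    if month is not None:
        numbers = [int(w) for w in words if w.isdigit()]
        day = next((n for n in numbers if 1 <= n <= 31), None)
        year = next((n for n in numbers if n >= 1000), None)
        try:
            if day is not None and year is not None:
                return (_dt.date(year, month, day), "explicit")
            if day is not None:
                return (_dt.date(anchor.year, month, day), "relative")
            if year is not None:
                return (_dt.date(year, month, 15), "relative")
            return (_dt.date(anchor.year, month, 15), "relative")
        except ValueError:
            return (doc_date, "document")

    try:
        parsed = _dateparser.parse(expr, dayfirst=True, fuzzy=False,
                                   default=_dt.datetime(anchor.year, 1, 1))
        return (parsed.date(), "explicit")
    except (ValueError, OverflowError):
        return (doc_date, "document")


# ---------------------------------------------------------------------------
# Extraction


def _is_negated(trigger: Annotation, tokens: list[Annotation]) -> bool:
    inside = [i for i, t in enumerate(tokens) if t.end > trigger.start and t.start < trigger.end]
    if not inside:
        return False
    first, last = inside[0], inside[-1]
    lo = max(0, first - NEGATION_WINDOW)
    hi = min(len(tokens), last + 1 + NEGATION_WINDOW)
    window = [t.features.get("string", "").casefold() for t in tokens[lo:hi]]
    for phrase in NEGATION_PHRASES:
        n = len(phrase)
        for i in range(len(window) - n + 1):
            if tuple(window[i : i + n]) == phrase:
                return True
    return False


def _explicit_context_dates(
    doc: Document, before: int, doc_date: _dt.date, set_name: str = ""
) -> list[_dt.date]:
    """Explicit dates appearing in the text before offset *before*."""
    out = []
    for d in select(doc, set_name, ann_type=DATE_EXPR):
        if d.end > before:
            break
        val, src = normalize_date(d.covered_text(doc), [], doc_date)
        if src == "explicit" and val is not None:
            out.append(val)
    return out


def extract_scores(
    doc: Document,
    doc_id: str = "",
    doc_date: _dt.date | None = None,
    set_name: str = "",
) -> list[ScoreEvent]:
    """Extract one event per score mention in trigger-bearing sentences.

    Requires Token/Sentence annotations and the grammar annotations
    (MMSETrigger, MMSEScore, DateExpr).  Each score binds to the nearest
    date expression at or after it within the sentence, else the nearest
    one before it, else the document date.
    """
    if doc_date is None:
        doc_date = _doc_date(doc)
    tokens = select(doc, set_name, ann_type=TOKEN)
    events = []
    for sent in select(doc, set_name, ann_type=SENTENCE):
        rng = (sent.start, sent.end)
        triggers = select(doc, set_name, ann_type=TRIGGER, range=rng, relation="within")
        live = [t for t in triggers if not _is_negated(t, tokens)]
        if not live:
            continue  # precision rule: no (non-negated) trigger, no event
        dates = select(doc, set_name, ann_type=DATE_EXPR, range=rng, relation="within")
        for score in select(doc, set_name, ann_type=SCORE, range=rng, relation="within"):
            num = int(score.features["num"])
            den = int(score.features["den"])
            bound = _bind_date(score, dates)
            if bound is None:
                event_date, source = doc_date, "document"
            else:
                ctx = _explicit_context_dates(doc, bound.start, doc_date, set_name)
                event_date, source = normalize_date(bound.covered_text(doc), ctx, doc_date)
            events.append(
                ScoreEvent(num, den, event_date, source, doc_id, (score.start, score.end))
            )
    return events


def _bind_date(score: Annotation, dates: list[Annotation]) -> Annotation | None:
    after = [d for d in dates if d.start >= score.end]
    if after:
        return min(after, key=lambda d: d.start)
    before = [d for d in dates if d.end <= score.start]
    if before:
        return max(before, key=lambda d: d.end)
    return None


def _doc_date(doc: Document) -> _dt.date:
    val = doc.features.get("date")
    if isinstance(val, _dt.date):
        return val
    if isinstance(val, str):
        return _dt.date.fromisoformat(val)
    raise ValueError("document has no 'date' feature (instance date required)")


# ---------------------------------------------------------------------------
# Post-filtering and deduplication


def postfilter(events: list[ScoreEvent], doc_date: _dt.date) -> list[ScoreEvent]:
    """Apply the domain sanity rules; survivors pass through unchanged.

    The examination is always scored out of 30, so a numerator above 30 or
    a denominator other than 30 marks an error; so does an event date in
    the future relative to the parent record date.
    """
    out = []
    for e in events:
        if e.numerator > MAX_SCORE or e.denominator != MAX_SCORE:
            continue
        if e.event_date is not None and e.event_date > doc_date:
            continue
        out.append(e)
    return out


def deduplicate(events: list[ScoreEvent]) -> list[ScoreEvent]:
    """Collapse events identical on (doc, score, date); keep the earliest span."""
    best: dict[tuple, ScoreEvent] = {}
    for e in events:
        k = e.key()
        if k not in best or e.span < best[k].span:
            best[k] = e
    return sorted(best.values(), key=lambda e: (e.doc_id, e.span))


# ---------------------------------------------------------------------------
# End-to-end pipeline


def mmse_pipeline(
    doc: Document,
    doc_id: str = "",
    doc_date: _dt.date | None = None,
    set_name: str = "",
) -> list[ScoreEvent]:
    """Run the whole pipeline on one document and return surviving events.

    Applies tokenize/sentence-split/abbreviation steps if missing, runs
    the extraction grammars, extracts, post-filters and deduplicates.
    """
    if doc_date is None:
        doc_date = _doc_date(doc)
    if not select(doc, set_name, ann_type=TOKEN) and doc.text:
        tokenize(doc, set_name)
    if not select(doc, set_name, ann_type=SENTENCE) and doc.text.strip():
        split_sentences(doc, set_name)
    detect_abbreviations(doc, set_name)
    if not doc.features.get("_mmse_grammar_applied"):
        for grammar in load_mmse_grammars():
            apply_grammar(doc, grammar, set_name)
        doc.features["_mmse_grammar_applied"] = True
    events = extract_scores(doc, doc_id, doc_date, set_name)
    return deduplicate(postfilter(events, doc_date))


def events_to_tsv(events: list[ScoreEvent]) -> str:
    """Serialize events as TSV: doc_id, numerator, denominator, date, source, span."""
    lines = ["doc_id\tnumerator\tdenominator\tevent_date\tdate_source\tstart\tend"]
    for e in events:
        date = e.event_date.isoformat() if e.event_date else ""
        lines.append(
            f"{e.doc_id}\t{e.numerator}\t{e.denominator}\t{date}\t{e.date_source}"
            f"\t{e.span[0]}\t{e.span[1]}"
        )
    return "\n".join(lines) + "\n"
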