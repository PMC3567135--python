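"""Seeded synthetic corpora: clinical-style notes with gold score events,
abstract-like gazetteer/abbreviation texts, and random annotation graphs.

Everything here is a pure function of its arguments (one ``random.Random``
per call), so generated corpora are byte-identical across runs.  Gold
annotations are emitted alongside the text at generation time — they are
never re-derived by the system under test — which keeps evaluation tests
circularity-free.  The notes emulate short clinical-note phrasing (plain
mentions, weekday-relative dates, month coordinations, negations and
deliberate errors); they make no claim to the distribution of real
clinical language.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import random
import string
from dataclasses import dataclass

from .anno_model import Corpus, Document, create_document
from .clinical_extract import ScoreEvent
from .lexical import Lexicon

__all__ = ["NoteSpec", "gen_notes", "gen_abstracts", "gen_random_graph"]

_MONTH_NAMES = [calendar.month_name[m] for m in range(13)]  # 1-based
_WEEKDAY_NAMES = list(calendar.day_name)  # Monday..Sunday


@dataclass(frozen=True)
class NoteSpec:
    """Conditions for the clinical-note generator."""

    n_docs: int = 50
    seed: int = 0
    error_rate: float = 0.0
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2010, 1, 1), _dt.date(2012, 12, 31))
    template_set: str = "default"

    def validate(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("empty date_range")
        if self.template_set != "default":
            raise ValueError(f"unknown template set {self.template_set!r}")


def _rand_date(rng: random.Random, lo: _dt.date, hi: _dt.date) -> _dt.date:
    return lo + _dt.timedelta(days=rng.randrange((hi - lo).days + 1))


def _doc_instance_date(rng: random.Random, spec: NoteSpec) -> _dt.date:
    # keep month >= 3 so month-name coordinations can use two earlier months
    while True:
        d = _rand_date(rng, *spec.date_range)
        if d.month >= 3:
            return d


_FILLERS = [
    "Patient seen in clinic.",
    "Routine review today.",
    "BP 120/80 recorded.",
    "Bloods taken and sent.",
]


def gen_notes(spec: NoteSpec) -> tuple[Corpus, list[ScoreEvent]]:
    """Generate clinical-style notes plus the gold score events.

    Each document carries a ``date`` feature (the instance date).  Valid
    templates produce gold events (plain mention with an explicit past
    date, weekday-relative date, two-score month coordination); negated
    mentions and — at ``error_rate`` — invalid scores (numerator > 30,
    denominator != 30) and future-dated assessments produce none.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    corpus = Corpus()
    gold: list[ScoreEvent] = []
    for i in range(spec.n_docs):
        doc_id = f"note-{i:04d}"
        doc_date = _doc_instance_date(rng, spec)
        parts: list[str] = []
        events: list[ScoreEvent] = []
        if rng.random() < 0.5:
            parts.append(rng.choice(_FILLERS) + " ")
        offset = sum(len(p) for p in parts)
        erroneous = rng.random() < spec.error_rate
        if erroneous:
            text = _error_sentence(rng, offset, doc_date)
        else:
            text, events = _valid_sentence(rng, offset, doc_id, doc_date)
        parts.append(text)
        if rng.random() < 0.4:
            parts.append(" " + rng.choice(_FILLERS))
        doc = create_document("".join(parts), {"date": doc_date})
        corpus.add(doc_id, doc)
        gold.extend(events)
    return corpus, gold


def _score_text(num: int, den: int) -> str:
    return f"{num}/{den}"


def _valid_sentence(
    rng: random.Random, offset: int, doc_id: str, doc_date: _dt.date
) -> tuple[str, list[ScoreEvent]]:
    kind = rng.choice(["plain", "weekday", "coordination", "negated"])
    if kind == "negated":
        return rng.choice([
            "MMSE not done, patient refused.",
            "Patient was unable to complete MMSE today.",
            "MMSE refused by patient.",
        ]), []
    num = rng.randrange(0, 31)
    if kind == "plain":
        when = doc_date - _dt.timedelta(days=rng.randrange(10, 300))
        prefix = f"MMSE done on {when.day} {_MONTH_NAMES[when.month]} {when.year}, score "
        text = prefix + _score_text(num, 30) + "."
        span = (offset + len(prefix), offset + len(prefix) + len(_score_text(num, 30)))
        return text, [ScoreEvent(num, 30, when, "explicit", doc_id, span)]
    if kind == "weekday":
        dow = rng.randrange(7)
        when = doc_date - _dt.timedelta(days=(doc_date.weekday() - dow) % 7)
        prefix = f"MMSE done on {_WEEKDAY_NAMES[dow]}, score "
        text = prefix + _score_text(num, 30) + "."
        span = (offset + len(prefix), offset + len(prefix) + len(_score_text(num, 30)))
        return text, [ScoreEvent(num, 30, when, "relative", doc_id, span)]
    # coordination: two scores bound to two earlier months of the doc year
    num2 = (num + 1 + rng.randrange(29)) % 31  # always different from num
    m1 = rng.randrange(1, doc_date.month - 1)  # m1 + 1 < doc month
    m2 = m1 + 1
    prefix = "MMSE: patient scored "
    mid = f" in {_MONTH_NAMES[m1]} then "
    tail = f" in {_MONTH_NAMES[m2]}."
    s1, s2 = _score_text(num, 30), _score_text(num2, 30)
    text = prefix + s1 + mid + s2 + tail
    span1 = (offset + len(prefix), offset + len(prefix) + len(s1))
    start2 = offset + len(prefix) + len(s1) + len(mid)
    span2 = (start2, start2 + len(s2))
    return text, [
        ScoreEvent(num, 30, _dt.date(doc_date.year, m1, 15), "relative", doc_id, span1),
        ScoreEvent(num2, 30, _dt.date(doc_date.year, m2, 15), "relative", doc_id, span2),
    ]


def _error_sentence(rng: random.Random, offset: int, doc_date: _dt.date) -> str:
    kind = rng.choice(["high_numerator", "bad_denominator", "future_date"])
    if kind == "high_numerator":
        return f"MMSE today, score {rng.randrange(31, 100)}/30."
    if kind == "bad_denominator":
        den = rng.choice([10, 20, 25, 28])
        return f"MMSE today, score {rng.randrange(0, den + 1)}/{den}."
    when = doc_date + _dt.timedelta(days=rng.randrange(30, 400))
    return (
        f"MMSE done on {when.day} {_MONTH_NAMES[when.month]} {when.year}, "
        f"score {rng.randrange(0, 31)}/30."
    )


# ---------------------------------------------------------------------------
# Abstract-like texts for gazetteer / abbreviation testing

_DEFINITIONS = [
    ("magnetic resonance imaging", "MRI"),
    ("chronic obstructive pulmonary disease", "COPD"),
    ("Mini Mental State Examination", "MMSE"),
    ("central nervous system", "CNS"),
    ("deep brain stimulation", "DBS"),
]


def gen_abstracts(n: int, seed: int, lexicon: Lexicon) -> tuple[Corpus, dict]:
    """Generate abstract-like documents embedding gazetteer terms.

    Every document contains at least one lexicon term (gold Lookup span)
    and one ``long form (SF)`` definition followed by a standalone
    short-form mention (gold Abbrev spans for the coreference step).
    Returns (corpus, gold) where gold maps "lookups" / "abbrev_pairs" /
    "coref_mentions" to lists of (doc_id, span, text) tuples.
    """
    if len(lexicon) == 0:
        raise ValueError("gen_abstracts requires a non-empty lexicon")
    rng = random.Random(seed)
    corpus = Corpus()
    gold = {"lookups": [], "abbrev_pairs": [], "coref_mentions": []}
    terms = [e.term for e in lexicon.entries]
    for i in range(n):
        doc_id = f"abs-{i:04d}"
        term = rng.choice(terms)
        long_form, short = _DEFINITIONS[rng.randrange(len(_DEFINITIONS))]
        p1 = "This report considers "
        s1 = p1 + term + " in a cohort study. "
        gold["lookups"].append((doc_id, (len(p1), len(p1) + len(term)), term))
        p2 = s1 + "Assessment used "
        s2 = p2 + f"{long_form} ({short}) at baseline. "
        long_span = (len(p2), len(p2) + len(long_form))
        short_span = (len(p2) + len(long_form) + 2, len(p2) + len(long_form) + 2 + len(short))
        gold["abbrev_pairs"].append((doc_id, long_span, short_span, long_form, short))
        p3 = s2 + "Follow-up "
        text = p3 + f"{short} readings were stable."
        gold["coref_mentions"].append(
            (doc_id, (len(p3), len(p3) + len(short)), long_form)
        )
        corpus.add(doc_id, create_document(text, {"date": _dt.date(2011, 5, 20)}))
    return corpus, gold


# ---------------------------------------------------------------------------
# Random annotation graphs for oracle tests


def gen_random_graph(
    text_len: int,
    n_ann: int,
    type_alphabet: tuple[str, ...] = ("A", "B", "C"),
    seed: int = 0,
    feature_pool: dict | None = None,
) -> Document:
    """A document with uniformly random valid spans, types and features."""
    if n_ann < 0:
        raise ValueError("n_ann must be >= 0")
    rng = random.Random(seed)
    text = "".join(
        rng.choice(string.ascii_lowercase + "    ") for _ in range(text_len)
    )
    doc = create_document(text)
    pool = feature_pool or {"f": ["x", "y"], "g": ["1", "2"]}
    for _ in range(n_ann):
        a = rng.randrange(text_len + 1)
        b = rng.randrange(text_len + 1)
        start, end = min(a, b), max(a, b)
        feats = {
            name: rng.choice(vals)
            for name, vals in pool.items()
            if rng.random() < 0.7
        }
        doc.add_annotation("", start, end, rng.choice(type_alphabet), feats)
    return doc
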