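"""In-situ abbreviation detection and coreference expansion.

Definition patterns of the forms ``long form (SF)`` and ``SF (long form)``
are harvested per sentence, validated with a character-subsequence test
(every letter/digit of the short form must appear in the long form in
order, and the short form's first character must begin one of the long
form's words), and the long form is trimmed to the shortest word suffix
that still validates.  Accepted pairs are annotated in place with
``longForm``/``shortForm`` features, and in coreference mode every later
standalone occurrence of a known short form inherits the long form of the
most recently defined matching pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .anno_model import Annotation, Document, select
from .lexical import SENTENCE, TOKEN

__all__ = [
    "AbbrevCandidate",
    "AbbrevPair",
    "find_candidates",
    "validate_pair",
    "annotate_and_corefer",
    "detect_abbreviations",
]

ABBREV = "Abbrev"

#: max words allowed on the parenthesized short-form side
MAX_SHORT_WORDS = 2


@dataclass(frozen=True)
class AbbrevCandidate:
    long_span: tuple[int, int]
    short_span: tuple[int, int]
    long_text: str
    short_text: str


@dataclass(frozen=True)
class AbbrevPair:
    long_span: tuple[int, int]
    short_span: tuple[int, int]
    long_text: str
    short_text: str


def _word_tokens(doc: Document, span: tuple[int, int], set_name: str = "") -> list[Annotation]:
    return [
        t
        for t in select(doc, set_name, ann_type=TOKEN, range=span, relation="within")
        if t.features.get("kind") in ("word", "number")
    ]


def _long_window_words(short_text: str) -> int:
    # window = min(|SF| + 5, 2*|SF|) words, |SF| in characters
    k = len(short_text)
    return max(1, min(k + 5, 2 * k))


def find_candidates(doc: Document, set_name: str = "") -> list[AbbrevCandidate]:
    """Harvest (long, short) definition candidates from parentheticals.

    Innermost parentheticals are preferred; a parenthetical of more than
    two words is instead treated as the long form of the single word that
    precedes the parenthesis.
    """
    sentences = select(doc, set_name, ann_type=SENTENCE)
    out = []
    for sent in sentences:
        text = doc.text
        for m in re.finditer(r"\(([^()]*)\)", text[sent.start : sent.end]):
            open_at = sent.start + m.start()
            inner_span = (sent.start + m.start(1), sent.start + m.end(1))
            inner = m.group(1).strip()
            if not inner:
                continue
            inner_words = _word_tokens(doc, inner_span, set_name)
            before = _word_tokens(doc, (sent.start, open_at), set_name)
            if not before:
                continue
            if len(inner_words) <= MAX_SHORT_WORDS:
                # LONG (SHORT): window of words left of the parenthesis
                window = _long_window_words(inner)
                chosen = before[-window:]
                long_span = (chosen[0].start, chosen[-1].end)
                out.append(
                    AbbrevCandidate(
                        long_span,
                        inner_span,
                        text[long_span[0] : long_span[1]],
                        text[inner_span[0] : inner_span[1]],
                    )
                )
            else:
                # SHORT (LONG): the word immediately before the parenthesis
                short_tok = before[-1]
                out.append(
                    AbbrevCandidate(
                        inner_span,
                        (short_tok.start, short_tok.end),
                        text[inner_span[0] : inner_span[1]],
                        short_tok.covered_text(doc),
                    )
                )
    return out


def _alnum_chars(s: str) -> list[str]:
    return [c.casefold() for c in s if c.isalnum()]


def _subsequence_word_initial(short: str, long_words: list[str]) -> bool:
    """True iff short's letters/digits occur in order in the long text and
    the first one starts some long-form word."""
    chars = _alnum_chars(short)
    if not chars:
        return False
    word_initials = {w[0].casefold() for w in long_words if w}
    if chars[0] not in word_initials:
        return False
    stream = [c.casefold() for w in long_words for c in w if c.isalnum()]
    # also require the first char to be matchable at a word start position:
    # try each word whose initial matches, then greedy subsequence onward
    for wi, w in enumerate(long_words):
        if not w or w[0].casefold() != chars[0]:
            continue
        tail = [c.casefold() for ww in long_words[wi:] for c in ww if c.isalnum()]
        it = iter(tail)
        if all(c in it for c in chars):
            return True
    return False


def validate_pair(candidate: AbbrevCandidate) -> AbbrevPair | None:
    """Validate a candidate; returns the pair with the long form trimmed to
    the shortest satisfying word suffix, or None on rejection."""
    short = candidate.short_text.strip()
    long_text = candidate.long_text
    if not short or len(short) >= len(long_text.strip()):
        return None
    words = []
    for wm in re.finditer(r"\S+", long_text):
        words.append((wm.start(), wm.end(), wm.group()))
    if not words:
        return None
    # shortest suffix: scan word starts right-to-left, accept the first
    # suffix that validates and is still longer than the short form
    for k in range(len(words) - 1, -1, -1):
        suffix_words = [w for _, _, w in words[k:]]
        trimmed = long_text[words[k][0] : words[-1][1]]
        if len(short) >= len(trimmed):
            continue
        if _subsequence_word_initial(short, suffix_words):
            start = candidate.long_span[0] + words[k][0]
            end = candidate.long_span[0] + words[-1][1]
            return AbbrevPair(
                (start, end), candidate.short_span, trimmed, short
            )
    return None


def annotate_and_corefer(
    doc: Document, pairs: list[AbbrevPair], set_name: str = ""
) -> int:
    """Annotate validated pairs in situ and expand later mentions.

    Long and short spans each receive an ``Abbrev`` annotation with
    ``longForm``/``shortForm`` features.  Every later standalone token
    whose text equals a known short form gets an ``Abbrev`` annotation
    carrying the most recently defined matching pair's long form.
    """
    created = 0
    existing = {
        (a.start, a.end, a.features.get("longForm"), a.features.get("shortForm"))
        for a in select(doc, set_name, ann_type=ABBREV)
    }

    def _add(start: int, end: int, feats: dict) -> int:
        key = (start, end, feats["longForm"], feats["shortForm"])
        if key in existing:  # re-running is a no-op
            return 0
        existing.add(key)
        doc.add_annotation(set_name, start, end, ABBREV, feats)
        return 1

    defined_spans = set()
    for p in sorted(pairs, key=lambda p: p.short_span):
        feats = {"longForm": p.long_text, "shortForm": p.short_text}
        created += _add(p.long_span[0], p.long_span[1], dict(feats))
        created += _add(p.short_span[0], p.short_span[1], dict(feats))
        defined_spans.add(p.short_span)
        defined_spans.add(p.long_span)

    # coreference: walk tokens in document order, tracking the most recent
    # definition of each short form seen so far
    pairs_by_pos = sorted(pairs, key=lambda p: p.short_span[0])
    tokens = select(doc, set_name, ann_type=TOKEN)
    pi = 0
    active: dict[str, AbbrevPair] = {}
    for tok in tokens:
        while pi < len(pairs_by_pos) and pairs_by_pos[pi].short_span[0] <= tok.start:
            p = pairs_by_pos[pi]
            if p.short_span[1] <= tok.start:  # definition fully precedes token
                active[p.short_text] = p
                pi += 1
            else:
                break
        text = tok.covered_text(doc)
        if text in active and (tok.start, tok.end) not in defined_spans:
            p = active[text]
            created += _add(
                tok.start, tok.end, {"longForm": p.long_text, "shortForm": p.short_text}
            )
    return created


def detect_abbreviations(doc: Document, set_name: str = "") -> list[AbbrevPair]:
    """Full pass: candidates -> validation -> in-situ annotation + coreference."""
    pairs = [p for p in (validate_pair(c) for c in find_candidates(doc, set_name)) if p]
    annotate_and_corefer(doc, pairs, set_name)
    return pairs
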