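"""Tokenization, sentence splitting and gazetteer lookup.

The tokenizer is rule-based and tuned for biomedical text: mixed
alphanumeric runs such as gene symbols ("p53", "BRCA1") stay single word
tokens, pure digit runs are number tokens, every punctuation character is
its own token, and whitespace runs become SpaceToken annotations, so the
Token/SpaceToken spans jointly tile the text.

The sentence splitter breaks after sentence-final punctuation (. ! ?)
with a guard against numeric constructs such as "3.2" or "24/30".  The
gazetteer matches a term list against the text with token-aligned,
leftmost-longest, non-overlapping semantics and emits Lookup annotations
carrying majorType/minorType/inst features.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable

from .anno_model import Annotation, Document, select

__all__ = [
    "tokenize",
    "split_sentences",
    "GazetteerEntry",
    "Lexicon",
    "load_gazetteer",
    "gazetteer_annotate",
    "GazetteerLoadError",
]

TOKEN = "Token"
SPACE_TOKEN = "SpaceToken"
SENTENCE = "Sentence"
LOOKUP = "Lookup"

# Ordered, total rule table: alphanumeric run | whitespace run | any single
# other character.  Every character is consumed by exactly one rule.
_TOKEN_RE = re.compile(r"(?P<alnum>[^\W_]+)|(?P<space>\s+)|(?P<punct>.)", re.DOTALL)

_SENT_FINAL = {".", "!", "?"}


def _orth(s: str) -> str:
    letters = [c for c in s if c.isalpha()]
    if not letters:
        return "other"
    if all(c.isupper() for c in letters):
        return "allCaps" if len(letters) > 1 else "upperInitial"
    if all(c.islower() for c in letters):
        return "lowercase"
    if letters[0].isupper() and all(c.islower() for c in letters[1:]):
        return "upperInitial"
    return "mixedCaps"


def tokenize(doc: Document, set_name: str = "") -> int:
    """Annotate *doc* with Token and SpaceToken spans; returns the count.

    Token features: ``string`` (covered text), ``kind`` (word | number |
    punctuation), ``orth`` (upperInitial | allCaps | lowercase | mixedCaps
    | other, words only), ``length``.
    """
    n = 0
    for m in _TOKEN_RE.finditer(doc.text):
        s, e = m.span()
        text = m.group()
        if m.lastgroup == "space":
            doc.add_annotation(set_name, s, e, SPACE_TOKEN, {"length": e - s})
        else:
            if m.lastgroup == "alnum":
                kind = "number" if text.isdigit() else "word"
            else:
                kind = "punctuation"
            feats = {"string": text, "kind": kind, "length": e - s}
            if kind == "word":
                feats["orth"] = _orth(text)
            doc.add_annotation(set_name, s, e, TOKEN, feats)
        n += 1
    return n


def _tokens(doc: Document, set_name: str = "") -> list[Annotation]:
    return select(doc, set_name, ann_type=TOKEN)


def split_sentences(doc: Document, set_name: str = "") -> int:
    """Annotate Sentence spans over the already-tokenized document.

    A sentence ends at a ``. ! ?`` token unless the period sits inside a
    decimal number (digit ``.`` digit with no intervening space).  Tokens
    after the last terminator form a final sentence.  Sentence spans run
    from the first token after the previous boundary to the terminator
    (whitespace between sentences is not covered).
    """
    toks = _tokens(doc, set_name)
    if not toks and doc.text.strip():
        raise ValueError("split_sentences requires Token annotations (run tokenize first)")
    n = 0
    sent_start: int | None = None
    last_end: int | None = None
    for i, t in enumerate(toks):
        if sent_start is None:
            sent_start = t.start
        last_end = t.end
        if t.features.get("string") in _SENT_FINAL:
            if t.features["string"] == "." and _inside_number(toks, i):
                continue
            doc.add_annotation(set_name, sent_start, t.end, SENTENCE, {})
            n += 1
            sent_start = None
    if sent_start is not None and last_end is not None:
        doc.add_annotation(set_name, sent_start, last_end, SENTENCE, {})
        n += 1
    return n


def _inside_number(toks: list[Annotation], i: int) -> bool:
    # guard: "3.2" — a period directly between two number tokens
    if 0 < i < len(toks) - 1:
        prev, nxt = toks[i - 1], toks[i + 1]
        return (
            prev.features.get("kind") == "number"
            and nxt.features.get("kind") == "number"
            and prev.end == toks[i].start
            and toks[i].end == nxt.start
        )
    return False


# ---------------------------------------------------------------------------
# Gazetteer


class GazetteerLoadError(ValueError):
    """Malformed gazetteer TSV; message carries the line number."""


@dataclass(frozen=True)
class GazetteerEntry:
    term: str
    major_type: str
    minor_type: str | None = None
    inst_uri: str | None = None


def _normalize_term(term: str) -> str:
    return re.sub(r"\s+", " ", term.strip())


class Lexicon:
    """A gazetteer term list indexed for token-aligned matching."""

    def __init__(self, entries: Iterable[GazetteerEntry] = ()):
        self.entries: list[GazetteerEntry] = []
        self._by_term: dict[str, GazetteerEntry] = {}
        self._by_term_folded: dict[str, GazetteerEntry] = {}
        self.max_tokens = 0
        for e in entries:
            self.add(e)

    def add(self, entry: GazetteerEntry) -> None:
        term = _normalize_term(entry.term)
        if not term:
            raise ValueError("gazetteer term empty after whitespace normalization")
        entry = GazetteerEntry(term, entry.major_type, entry.minor_type, entry.inst_uri)
        self.entries.append(entry)
        # last entry wins on duplicate terms (deterministic)
        self._by_term[term] = entry
        self._by_term_folded[term.casefold()] = entry
        self.max_tokens = max(self.max_tokens, len(_TOKEN_RE.findall(term)))

    def lookup(self, text: str, case_sensitive: bool) -> GazetteerEntry | None:
        key = _normalize_term(text)
        if case_sensitive:
            return self._by_term.get(key)
        return self._by_term_folded.get(key.casefold())

    def __len__(self) -> int:
        return len(self.entries)


def load_gazetteer(source) -> Lexicon:
    """Load a gazetteer from TSV: term<TAB>majorType[<TAB>minorType[<TAB>inst]].

    '#'-prefixed lines and blank lines are ignored.  *source* is a path or
    a text file object.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with io.open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    lex = Lexicon()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip():
            raise GazetteerLoadError(
                f"line {lineno}: expected term<TAB>majorType, got {line!r}"
            )
        term, major = parts[0], parts[1].strip()
        minor = parts[2].strip() or None if len(parts) > 2 else None
        inst = parts[3].strip() or None if len(parts) > 3 else None
        try:
            lex.add(GazetteerEntry(term, major, minor, inst))
        except ValueError as exc:
            raise GazetteerLoadError(f"line {lineno}: {exc}") from exc
    return lex


def gazetteer_annotate(
    doc: Document,
    lexicon: Lexicon,
    case_sensitive: bool = False,
    set_name: str = "",
) -> int:
    """Emit Lookup annotations for leftmost-longest, non-overlapping matches.

    Matching is token-aligned: a match starts at a token start and ends at
    a token end.  From each candidate start the longest matching term wins
    and matching resumes after its end, so Lookups never overlap.
    Case-insensitive matching is plain case folding of both sides.
    """
    toks = [t for t in _tokens(doc, set_name)]
    n = 0
    i = 0
    while i < len(toks):
        best: tuple[int, GazetteerEntry] | None = None
        for j in range(i, min(i + lexicon.max_tokens, len(toks))):
            cand = doc.text[toks[i].start : toks[j].end]
            entry = lexicon.lookup(cand, case_sensitive)
            if entry is not None:
                best = (j, entry)  # longer j overrides: leftmost-longest
        if best is None:
            i += 1
            continue
        j, entry = best
        feats = {"majorType": entry.major_type}
        if entry.minor_type is not None:
            feats["minorType"] = entry.minor_type
        if entry.inst_uri is not None:
            feats["inst"] = entry.inst_uri
        doc.add_annotation(set_name, toks[i].start, toks[j].end, LOOKUP, feats)
        n += 1
        i = j + 1
    return n
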