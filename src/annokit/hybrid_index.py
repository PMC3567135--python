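"""Hybrid full-text / annotation / knowledge-base index with federation.

One shard indexes a document partition three ways: token postings (term ->
(doc, position)), annotation postings (type -> (doc, first-token,
last-token, features)) and an optional knowledge base of (subject,
predicate, object) triples supporting ``type``/``subClassOf`` closure.
Queries mix term literals, annotation constraints, sequence (token
adjacency), boolean OR/AND, containment (IN / OVER) and semantic class
expansion; hits are exhaustive and positionally ordered — retrieval, not
relevance ranking, is the contract.

Query string language::

    "score" {Token.kind=="number"}     sequence (juxtaposition)
    {MMSEScore} IN {Sentence}          containment
    {Sentence} OVER {MMSEScore}        reverse containment
    "aspirin" | "ibuprofen"            union
    "aspirin" & {Lookup}               same-document co-occurrence
    CLASS(<http://x/Drug>)             Lookup instances of a KB class
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .anno_model import Corpus, Document, select
from .lexical import LOOKUP, TOKEN
from .patterns import Constraint, PatternParseError, _Parser, _lex

__all__ = [
    "IndexShard",
    "Hit",
    "TermLiteral",
    "AnnConstraint",
    "QSeq",
    "QOr",
    "QAnd",
    "QIn",
    "QOver",
    "ClassExpansion",
    "KnowledgeBase",
    "load_kb",
    "parse_query",
    "build_index",
    "eval_query",
    "federate",
    "FederationError",
]

RDF_TYPE = "type"
SUBCLASS = "subClassOf"


class FederationError(ValueError):
    """Shards passed to federate() must index disjoint document sets."""


# ---------------------------------------------------------------------------
# Knowledge base


class KnowledgeBase:
    """A set of triples with type/subClassOf closure."""

    def __init__(self, triples: Iterable[tuple[str, str, str]] = ()):
        self.triples: set[tuple[str, str, str]] = set(tuples3(triples))

    def subclasses(self, cls: str) -> set[str]:
        """*cls* plus every class reachable down the subClassOf hierarchy."""
        down: dict[str, set[str]] = {}
        for s, p, o in self.triples:
            if p == SUBCLASS:
                down.setdefault(o, set()).add(s)
        seen = {cls}
        frontier = [cls]
        while frontier:
            c = frontier.pop()
            for sub in down.get(c, ()):
                if sub not in seen:
                    seen.add(sub)
                    frontier.append(sub)
        return seen

    def instances_of(self, cls: str) -> set[str]:
        classes = self.subclasses(cls)
        return {s for s, p, o in self.triples if p == RDF_TYPE and o in classes}

    def objects(self, subject: str, predicate: str) -> set[str]:
        return {o for s, p, o in self.triples if s == subject and p == predicate}


def tuples3(items) -> Iterable[tuple[str, str, str]]:
    for t in items:
        s, p, o = t
        yield (str(s), str(p), str(o))


def load_kb(source) -> KnowledgeBase:
    """Load a KB from TSV: subject<TAB>predicate<TAB>object per line."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with io.open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    triples = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        triples.append(tuple(p.strip() for p in parts))
    return KnowledgeBase(triples)


# ---------------------------------------------------------------------------
# Query AST


@dataclass(frozen=True)
class TermLiteral:
    text: str


@dataclass(frozen=True)
class AnnConstraint:
    ann_type: str
    feature_tests: tuple = ()


@dataclass(frozen=True)
class QSeq:
    children: tuple


@dataclass(frozen=True)
class QOr:
    children: tuple


@dataclass(frozen=True)
class QAnd:
    children: tuple


@dataclass(frozen=True)
class QIn:
    inner: object
    outer: object


@dataclass(frozen=True)
class QOver:
    inner: object
    outer: object


@dataclass(frozen=True)
class ClassExpansion:
    kb_class: str


def parse_query(src: str):
    """Parse the query string language into a query AST."""
    # CLASS(<uri>) literals are extracted before lexing: URIs contain
    # characters the pattern lexer rejects
    placeholders: list[str] = []

    def _stash(m):
        placeholders.append(m.group(1))
        return f" CLASSREF_{len(placeholders) - 1} "

    src2 = re.sub(r"CLASS\(\s*<([^>]*)>\s*\)", _stash, src)
    toks = _lex(src2)
    p = _QueryParser(toks, placeholders)
    node = p.parse_query()
    if p.peek() is not None:
        p.error(f"trailing input starting at {p.peek().value!r}")
    return node


class _QueryParser(_Parser):
    def __init__(self, toks, placeholders):
        super().__init__(toks)
        self.placeholders = placeholders

    # query := and (('IN'|'OVER') and)? ; and := or ('&' or)* ;
    # or := seq ('|' seq)* ; seq := atom+
    def parse_query(self):
        node = self.parse_and()
        tok = self.peek()
        if tok is not None and tok.value in ("IN", "OVER"):
            self.next()
            right = self.parse_and()
            node = QIn(node, right) if tok.value == "IN" else QOver(node, right)
        return node

    def parse_and(self):
        children = [self.parse_or()]
        while self.peek() is not None and self.peek().value == "&":
            self.next()
            children.append(self.parse_or())
        return children[0] if len(children) == 1 else QAnd(tuple(children))

    def parse_or(self):
        children = [self.parse_qseq()]
        while self.peek() is not None and self.peek().value == "|":
            self.next()
            children.append(self.parse_qseq())
        return children[0] if len(children) == 1 else QOr(tuple(children))

    def parse_qseq(self):
        items = [self.parse_qatom()]
        while True:
            tok = self.peek()
            if tok is None:
                break
            if tok.value == "{" or tok.kind == "STRING" or (
                tok.kind == "IDENT" and tok.value.startswith("CLASSREF_")
            ) or tok.value == "(":
                items.append(self.parse_qatom())
            else:
                break
        return items[0] if len(items) == 1 else QSeq(tuple(items))

    def parse_qatom(self):
        tok = self.peek()
        if tok is None:
            self.error("expected a query atom")
        if tok.kind == "STRING":
            self.next()
            return TermLiteral(re.sub(r"\\(.)", r"\1", tok.value[1:-1]))
        if tok.value == "(":
            self.next()
            node = self.parse_query()
            self.expect(")")
            return node
        if tok.value == "{":
            c = self.parse_constraint()
            return AnnConstraint(c.ann_type, c.feature_tests)
        if tok.kind == "IDENT" and tok.value.startswith("CLASSREF_"):
            self.next()
            return ClassExpansion(self.placeholders[int(tok.value.rsplit("_", 1)[1])])
        self.error(f"unexpected {tok.value!r} in query")


# ---------------------------------------------------------------------------
# Index construction


@dataclass(frozen=True)
class Hit:
    doc_id: str
    first: int  # token positions, inclusive
    last: int
    char_span: tuple[int, int]

    def order_key(self):
        return (self.doc_id, self.first, self.last)


@dataclass
class IndexShard:
    doc_tokens: dict = field(default_factory=dict)  # doc_id -> [(start, end), ...]
    token_postings: dict = field(default_factory=dict)  # term -> [(doc_id, pos)]
    ann_postings: dict = field(default_factory=dict)  # type -> [(doc, first, last, features)]
    kb: KnowledgeBase | None = None
    skipped_annotations: int = 0

    @property
    def doc_table(self) -> dict:
        return {d: len(toks) for d, toks in self.doc_tokens.items()}

    def char_span(self, doc_id: str, first: int, last: int) -> tuple[int, int]:
        toks = self.doc_tokens[doc_id]
        return (toks[first][0], toks[last][1])


def build_index(
    corpus: Corpus,
    ann_types: Iterable[str] = (),
    kb: KnowledgeBase | None = None,
    set_name: str = "",
) -> IndexShard:
    """Index a tokenized, annotated corpus.

    Annotations of the requested types are mapped to token spans: first =
    token containing the start offset, last = token containing end-1.
    Annotations aligned to no token (zero-length, or inside whitespace)
    are skipped and counted in ``skipped_annotations``.
    """
    shard = IndexShard(kb=kb)
    want = set(ann_types)
    for doc_id, doc in corpus:
        toks = select(doc, set_name, ann_type=TOKEN)
        if not toks and doc.text.strip():
            raise ValueError(f"document {doc_id!r} is not tokenized")
        spans = [(t.start, t.end) for t in toks]
        shard.doc_tokens[doc_id] = spans
        for pos, t in enumerate(toks):
            term = t.features.get("string", "").casefold()
            shard.token_postings.setdefault(term, []).append((doc_id, pos))
        if not want:
            continue
        for aset_name in doc.sets:
            if aset_name != set_name:
                continue
            for ann in doc.sets[aset_name]:
                if ann.ann_type not in want:
                    continue
                first = _token_containing(spans, ann.start)
                last = _token_containing(spans, ann.end - 1) if ann.end > ann.start else None
                if first is None or last is None or last < first:
                    shard.skipped_annotations += 1
                    continue
                shard.ann_postings.setdefault(ann.ann_type, []).append(
                    (doc_id, first, last, dict(ann.features))
                )
    # deterministic postings order
    for lst in shard.token_postings.values():
        lst.sort(key=lambda x: (x[0], x[1]))
    for lst in shard.ann_postings.values():
        lst.sort(key=lambda x: (x[0], x[1], x[2], sorted(x[3].items(), key=str)))
    return shard


def _token_containing(spans: Sequence[tuple[int, int]], offset: int) -> int | None:
    for i, (s, e) in enumerate(spans):
        if s <= offset < e:
            return i
    return None


# ---------------------------------------------------------------------------
# Query evaluation


def _feature_tests_ok(features: dict, tests) -> bool:
    for name, op, value in tests:
        present = name in features
        if op == "==":
            if not present or features[name] != value:
                return False
        else:
            if present and features[name] == value:
                return False
    return True


def eval_query(shard: IndexShard, q) -> list[Hit]:
    """Evaluate a query AST (or query string) against one shard."""
    if isinstance(q, str):
        q = parse_query(q)
    hits = _eval(shard, q)
    uniq = {(h.doc_id, h.first, h.last): h for h in hits}
    return sorted(uniq.values(), key=Hit.order_key)


def _mk_hit(shard: IndexShard, doc_id: str, first: int, last: int) -> Hit:
    return Hit(doc_id, first, last, shard.char_span(doc_id, first, last))


def _eval(shard: IndexShard, q) -> list[Hit]:
    if isinstance(q, TermLiteral):
        term = q.text.casefold()
        return [
            _mk_hit(shard, d, p, p) for d, p in shard.token_postings.get(term, [])
        ]
    if isinstance(q, AnnConstraint):
        out = []
        for d, first, last, feats in shard.ann_postings.get(q.ann_type, []):
            if _feature_tests_ok(feats, q.feature_tests):
                out.append(_mk_hit(shard, d, first, last))
        return out
    if isinstance(q, QSeq):
        parts = [_eval(shard, c) for c in q.children]
        current = parts[0]
        for nxt in parts[1:]:
            by_start: dict[tuple[str, int], list[Hit]] = {}
            for h in nxt:
                by_start.setdefault((h.doc_id, h.first), []).append(h)
            merged = []
            for h in current:
                for h2 in by_start.get((h.doc_id, h.last + 1), []):
                    merged.append(_mk_hit(shard, h.doc_id, h.first, h2.last))
            current = merged
        return current
    if isinstance(q, QOr):
        out = []
        for c in q.children:
            out.extend(_eval(shard, c))
        return out
    if isinstance(q, QAnd):
        parts = [_eval(shard, c) for c in q.children]
        current = parts[0]
        for nxt in parts[1:]:
            by_doc: dict[str, list[Hit]] = {}
            for h in nxt:
                by_doc.setdefault(h.doc_id, []).append(h)
            merged = []
            for h in current:
                for h2 in by_doc.get(h.doc_id, []):
                    merged.append(
                        _mk_hit(
                            shard, h.doc_id, min(h.first, h2.first), max(h.last, h2.last)
                        )
                    )
            current = merged
        return current
    if isinstance(q, QIn):
        inner = _eval(shard, q.inner)
        outer = _eval(shard, q.outer)
        return [
            h
            for h in inner
            if any(
                o.doc_id == h.doc_id and o.first <= h.first and h.last <= o.last
                for o in outer
            )
        ]
    if isinstance(q, QOver):
        inner = _eval(shard, q.inner)
        outer = _eval(shard, q.outer)
        return [
            h
            for h in inner
            if any(
                o.doc_id == h.doc_id and h.first <= o.first and o.last <= h.last
                for o in outer
            )
        ]
    if isinstance(q, ClassExpansion):
        if shard.kb is None:
            return []
        insts = shard.kb.instances_of(q.kb_class)
        out = []
        for d, first, last, feats in shard.ann_postings.get(LOOKUP, []):
            if feats.get("inst") in insts:
                out.append(_mk_hit(shard, d, first, last))
        return out
    raise TypeError(f"unknown query node {q!r}")


# ---------------------------------------------------------------------------
# Federation


def federate(shards: Sequence[IndexShard], q) -> list[Hit]:
    """Evaluate *q* on every shard and merge, as if over the union corpus.

    Shards must index disjoint document sets.
    """
    seen: set[str] = set()
    for shard in shards:
        ids = set(shard.doc_tokens)
        dup = seen & ids
        if dup:
            raise FederationError(f"document ids indexed in several shards: {sorted(dup)}")
        seen |= ids
    if isinstance(q, str):
        q = parse_query(q)
    hits: list[Hit] = []
    for shard in shards:
        hits.extend(eval_query(shard, q))
    return sorted(hits, key=Hit.order_key)
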