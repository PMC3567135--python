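"""Hybrid index: construction, query semantics, KB expansion, federation."""

import random

import pytest

from annokit import anno_model as am
from annokit import hybrid_index as hx
from annokit import lexical as lx


def _mk_corpus(docs: dict) -> am.Corpus:
    corpus = am.Corpus()
    for doc_id, text in docs.items():
        doc = am.create_document(text)
        lx.tokenize(doc)
        corpus.add(doc_id, doc)
    return corpus


class TestBuild:
    def test_token_postings(self):
        shard = hx.build_index(_mk_corpus({"d": "a b"}))
        assert shard.token_postings["a"] == [("d", 0)]
        assert shard.token_postings["b"] == [("d", 1)]
        assert shard.doc_table == {"d": 2}

    def test_annotation_token_alignment(self):
        corpus = _mk_corpus({"d": "take an aspirin now"})
        doc = corpus.documents["d"]
        start = doc.text.index("aspirin")
        doc.add_annotation("", start, start + 7, lx.LOOKUP, {"inst": "uri:A"})
        shard = hx.build_index(corpus, {lx.LOOKUP})
        assert shard.ann_postings[lx.LOOKUP] == [("d", 2, 2, {"inst": "uri:A"})]

    def test_zero_length_annotation_skipped_with_warning(self):
        corpus = _mk_corpus({"d": "a b"})
        corpus.documents["d"].add_annotation("", 1, 1, "Z")
        shard = hx.build_index(corpus, {"Z"})
        assert shard.skipped_annotations == 1
        assert "Z" not in shard.ann_postings

    def test_untokenized_document_rejected(self):
        corpus = am.Corpus()
        corpus.add("d", am.create_document("plain text"))
        with pytest.raises(ValueError):
            hx.build_index(corpus)

    def test_deterministic_build(self):
        c1 = _mk_corpus({"d1": "a b c", "d2": "b c d"})
        c2 = _mk_corpus({"d1": "a b c", "d2": "b c d"})
        assert hx.build_index(c1).token_postings == hx.build_index(c2).token_postings


class TestQuerySemantics:
    @pytest.fixture()
    def shard(self):
        corpus = _mk_corpus({"d": "MMSE score 24 /30 noted"})
        doc = corpus.documents["d"]
        doc.add_annotation("", 0, len(doc.text), lx.SENTENCE)
        doc.add_annotation("", 11, 17, "MMSEScore", {"num": "24"})
        return hx.build_index(corpus, {lx.SENTENCE, "MMSEScore"})

    def test_sequence_token_adjacency(self, shard):
        hits = hx.eval_query(shard, '"score" {Token.kind=="number"}')
        # annotation postings were not built for Token; use term + term form
        hits2 = hx.eval_query(shard, '"score" "24"')
        assert [(h.first, h.last) for h in hits2] == [(1, 2)]
        assert hits == []  # Token annotations were not indexed in this shard

    def test_containment(self, shard):
        hits = hx.eval_query(shard, "{MMSEScore} IN {Sentence}")
        assert len(hits) == 1
        assert hx.eval_query(shard, "{Sentence} OVER {MMSEScore}")[0].first == 0

    def test_unknown_type_empty_not_error(self, shard):
        assert hx.eval_query(shard, "{Nope}") == []

    def test_or_and(self):
        shard = hx.build_index(_mk_corpus({"d1": "aspirin daily", "d2": "ibuprofen daily"}))
        assert {h.doc_id for h in hx.eval_query(shard, '"aspirin" | "ibuprofen"')} == {"d1", "d2"}
        hits = hx.eval_query(shard, '"aspirin" & "daily"')
        assert [(h.doc_id, h.first, h.last) for h in hits] == [("d1", 0, 1)]

    def test_class_expansion_via_kb(self):
        corpus = _mk_corpus({"d": "took aspirin today"})
        doc = corpus.documents["d"]
        s = doc.text.index("aspirin")
        doc.add_annotation("", s, s + 7, lx.LOOKUP, {"inst": "uri:asa"})
        kb = hx.KnowledgeBase(
            [
                ("uri:asa", "type", "uri:NSAID"),
                ("uri:NSAID", "subClassOf", "uri:Drug"),
            ]
        )
        shard = hx.build_index(corpus, {lx.LOOKUP}, kb=kb)
        hits = hx.eval_query(shard, "CLASS(<uri:Drug>)")
        assert [(h.first, h.last) for h in hits] == [(1, 1)]
        assert hx.eval_query(shard, "CLASS(<uri:Other>)") == []

    def test_kb_closure_is_transitive(self):
        kb = hx.KnowledgeBase(
            [
                ("a", "subClassOf", "b"),
                ("b", "subClassOf", "c"),
                ("x", "type", "a"),
            ]
        )
        assert kb.instances_of("c") == {"x"}


class TestFederation:
    def _corpora(self):
        texts = {"d1": "a b", "d2": "b c", "d3": "c a", "d4": "a c b"}
        return texts

    def test_federated_equals_merged(self):
        texts = self._corpora()
        full = hx.build_index(_mk_corpus(texts))
        s1 = hx.build_index(_mk_corpus({k: texts[k] for k in ("d1", "d3")}))
        s2 = hx.build_index(_mk_corpus({k: texts[k] for k in ("d2", "d4")}))
        for q in ['"a"', '"a" "b"', '"a" | "c"']:
            assert hx.federate([s1, s2], q) == hx.eval_query(full, q)

    def test_empty_shard_contributes_nothing(self):
        s1 = hx.build_index(_mk_corpus({"d1": "a"}))
        s2 = hx.build_index(_mk_corpus({}))
        assert hx.federate([s1, s2], '"a"') == hx.eval_query(s1, '"a"')

    def test_duplicate_doc_id_is_error(self):
        s1 = hx.build_index(_mk_corpus({"d1": "a"}))
        s2 = hx.build_index(_mk_corpus({"d1": "b"}))
        with pytest.raises(hx.FederationError):
            hx.federate([s1, s2], '"a"')


# ---------------------------------------------------------------------------
# Oracle: per-document scan without the index


def scan_oracle(corpus, q, ann_types, kb=None):
    """Re-evaluate a query by walking each document directly."""
    hits = []
    for doc_id, doc in corpus:
        toks = am.select(doc, ann_type=lx.TOKEN)
        spans = [(t.start, t.end) for t in toks]
        hits.extend(_scan(doc, doc_id, toks, spans, q, ann_types, kb))
    uniq = sorted({(h.doc_id, h.first, h.last): h for h in hits}.values(),
                  key=hx.Hit.order_key)
    return uniq


def _ann_token_span(spans, ann):
    def containing(off):
        for i, (s, e) in enumerate(spans):
            if s <= off < e:
                return i
        return None

    if ann.end <= ann.start:
        return None
    first = containing(ann.start)
    last = containing(ann.end - 1)
    if first is None or last is None or last < first:
        return None
    return (first, last)


def _scan(doc, doc_id, toks, spans, q, ann_types, kb):
    mk = lambda f, l: hx.Hit(doc_id, f, l, (spans[f][0], spans[l][1]))
    if isinstance(q, hx.TermLiteral):
        return [
            mk(i, i)
            for i, t in enumerate(toks)
            if t.features.get("string", "").casefold() == q.text.casefold()
        ]
    if isinstance(q, hx.AnnConstraint):
        out = []
        for ann in doc.annotation_set(""):
            if ann.ann_type != q.ann_type or ann.ann_type not in ann_types:
                continue
            if not hx._feature_tests_ok(ann.features, q.feature_tests):
                continue
            ts = _ann_token_span(spans, ann)
            if ts:
                out.append(mk(*ts))
        return out
    if isinstance(q, hx.QSeq):
        parts = [_scan(doc, doc_id, toks, spans, c, ann_types, kb) for c in q.children]
        cur = parts[0]
        for nxt in parts[1:]:
            cur = [
                mk(h.first, h2.last)
                for h in cur
                for h2 in nxt
                if h2.first == h.last + 1
            ]
        return cur
    if isinstance(q, hx.QOr):
        return [h for c in q.children for h in _scan(doc, doc_id, toks, spans, c, ann_types, kb)]
    if isinstance(q, hx.QAnd):
        parts = [_scan(doc, doc_id, toks, spans, c, ann_types, kb) for c in q.children]
        cur = parts[0]
        for nxt in parts[1:]:
            cur = [
                mk(min(h.first, h2.first), max(h.last, h2.last))
                for h in cur
                for h2 in nxt
            ]
        return cur
    if isinstance(q, hx.QIn):
        inner = _scan(doc, doc_id, toks, spans, q.inner, ann_types, kb)
        outer = _scan(doc, doc_id, toks, spans, q.outer, ann_types, kb)
        return [h for h in inner if any(o.first <= h.first and h.last <= o.last for o in outer)]
    if isinstance(q, hx.QOver):
        inner = _scan(doc, doc_id, toks, spans, q.inner, ann_types, kb)
        outer = _scan(doc, doc_id, toks, spans, q.outer, ann_types, kb)
        return [h for h in inner if any(h.first <= o.first and o.last <= h.last for o in outer)]
    if isinstance(q, hx.ClassExpansion):
        if kb is None:
            return []
        insts = kb.instances_of(q.kb_class)
        out = []
        for ann in doc.annotation_set(""):
            if ann.ann_type == lx.LOOKUP and lx.LOOKUP in ann_types and ann.features.get("inst") in insts:
                ts = _ann_token_span(spans, ann)
                if ts:
                    out.append(mk(*ts))
        return out
    raise TypeError(q)


def random_corpus(rng, n_docs):
    words = ["mmse", "score", "24", "30", "aspirin", "drug", "done", "on"]
    corpus = am.Corpus()
    kb = hx.KnowledgeBase(
        [("uri:asa", "type", "uri:NSAID"), ("uri:NSAID", "subClassOf", "uri:Drug"),
         ("uri:ibu", "type", "uri:Drug")]
    )
    for i in range(n_docs):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(1, 10)))
        doc = am.create_document(text)
        lx.tokenize(doc)
        toks = am.select(doc, ann_type=lx.TOKEN)
        for _ in range(rng.randint(0, 3)):
            a = rng.randrange(len(toks))
            b = min(len(toks) - 1, a + rng.randint(0, 2))
            ann_type = rng.choice([lx.LOOKUP, "Mention"])
            feats = {"inst": rng.choice(["uri:asa", "uri:ibu", "uri:x"])} if ann_type == lx.LOOKUP else {"f": rng.choice(["x", "y"])}
            doc.add_annotation("", toks[a].start, toks[b].end, ann_type, feats)
        corpus.add(f"d{i:03d}", doc)
    return corpus, kb


QUERIES = [
    hx.TermLiteral("mmse"),
    hx.AnnConstraint("Mention", (("f", "==", "x"),)),
    hx.AnnConstraint("Mention", (("f", "!=", "x"),)),
    hx.QSeq((hx.TermLiteral("score"), hx.TermLiteral("24"))),
    hx.QOr((hx.TermLiteral("aspirin"), hx.TermLiteral("drug"))),
    hx.QAnd((hx.TermLiteral("mmse"), hx.TermLiteral("30"))),
    hx.QIn(hx.TermLiteral("mmse"), hx.AnnConstraint("Mention", ())),
    hx.QOver(hx.AnnConstraint("Mention", ()), hx.TermLiteral("aspirin")),
    hx.ClassExpansion("uri:Drug"),
    hx.ClassExpansion("uri:NSAID"),
]


@pytest.mark.parametrize("seed", range(20))
def test_eval_query_equals_scan_oracle(seed):
    rng = random.Random(seed)
    corpus, kb = random_corpus(rng, rng.randint(1, 10))
    ann_types = {lx.LOOKUP, "Mention"}
    shard = hx.build_index(corpus, ann_types, kb=kb)
    for q in QUERIES:
        assert hx.eval_query(shard, q) == scan_oracle(corpus, q, ann_types, kb), q


@pytest.mark.parametrize("seed", range(10))
def test_federate_random_split_equals_unsplit(seed):
    rng = random.Random(seed)
    corpus, kb = random_corpus(rng, rng.randint(3, 12))
    ann_types = {lx.LOOKUP, "Mention"}
    full = hx.build_index(corpus, ann_types, kb=kb)
    buckets = [am.Corpus(), am.Corpus(), am.Corpus()]
    for doc_id, doc in corpus:
        buckets[rng.randrange(3)].add(doc_id, doc)
    shards = [hx.build_index(b, ann_types, kb=kb) for b in buckets]
    for q in QUERIES:
        assert hx.federate(shards, q) == hx.eval_query(full, q), q


class TestQueryParser:
    def test_precedence_and_forms(self):
        q = hx.parse_query('"a" "b" | "c" & {T.f=="v"} IN {S}')
        assert isinstance(q, hx.QIn)
        assert isinstance(q.inner, hx.QAnd)

    def test_bad_query_rejected(self):
        with pytest.raises(hx.PatternParseError):
            hx.parse_query('"unclosed')
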