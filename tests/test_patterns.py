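"""Pattern language: parsing, annotation-sequence matching, transduction."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from annokit import anno_model as am
from annokit import patterns as pt
from annokit.fixtures import gen_random_graph


class TestParsing:
    def test_three_constraint_sequence(self):
        node = pt.parse_pattern('{Person}{Token.category=="VBD"}{Organization}')
        assert isinstance(node, pt.Seq)
        assert [c.ann_type for c in node.children] == ["Person", "Token", "Organization"]
        assert node.children[1].feature_tests == (("category", "==", "VBD"),)

    def test_optional_group(self):
        node = pt.parse_pattern("({Token})?")
        assert node == pt.Quant(pt.Constraint("Token"), 0, 1)

    def test_star_plus_alternation_labels(self):
        node = pt.parse_pattern('({A}|{B.f!="x"})+:g')
        assert isinstance(node, pt.Group) and node.label == "g"
        assert isinstance(node.expr, pt.Quant) and node.expr.min == 1

    @pytest.mark.parametrize("bad", ["{Token.kind==}", "{Token", "({A}", "{}", "{A.f=>1}"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(pt.PatternParseError):
            pt.parse_pattern(bad)

    def test_grammar_file_round(self):
        g = pt.parse_grammar(
            "Phase: P\nInput: Person Token Organization\nOptions: control=all\n"
            "Rule: R1\nPriority: 5\n"
            '({Person}{Token.category=="VBD"}{Organization}):pv\n'
            '--> :pv.PV = {kind = "pvo", text = :pv@string}\n'
        )
        assert g.name == "P" and g.control == "all"
        assert g.rules[0].priority == 5
        assert g.rules[0].rhs[0][:2] == ("pv", "PV")

    def test_rhs_unbound_label_is_rule_error(self):
        with pytest.raises(pt.RuleError):
            pt.parse_grammar(
                "Phase: P\nInput: A\nRule: R\n({A}):x --> :nope.T = {}\n"
            )

    def test_grammar_without_input_rejected(self):
        with pytest.raises(pt.PatternParseError):
            pt.parse_grammar("Phase: P\nRule: R\n({A}):x --> :x.T = {}\n")


def _fig5_doc():
    doc = am.create_document("Jim  founded Acme Corp.")
    doc.add_annotation("", 0, 3, "Person", {})
    doc.add_annotation("", 5, 12, "Token", {"category": "VBD"})
    doc.add_annotation("", 13, 22, "Organization", {})
    return doc


INPUTS = {"Person", "Token", "Organization"}


class TestMatch:
    def test_person_verb_org(self):
        doc = _fig5_doc()
        expr = pt.parse_pattern('{Person}{Token.category=="VBD"}{Organization}')
        ms = pt.match(doc, expr, INPUTS)
        assert [(m.start, m.end) for m in ms] == [(0, 22)]

    def test_order_matters(self):
        doc = _fig5_doc()
        assert pt.match(doc, "{Organization}{Person}", INPUTS) == []

    def test_empty_width_matches_suppressed(self):
        doc = am.create_document("")
        assert pt.match(doc, "({Token})*", {"Token"}) == []

    def test_group_bindings_report_spans(self):
        doc = _fig5_doc()
        ms = pt.match(doc, "({Person}):p({Token})({Organization}):o", INPUTS)
        assert ms[0].binding_span("p") == (0, 3)
        assert ms[0].binding_span("o") == (13, 22)

    def test_successor_skips_to_minimal_next_start(self):
        doc = am.create_document("x" * 30)
        doc.add_annotation("", 0, 5, "A")
        doc.add_annotation("", 10, 12, "B")   # nearest start after 5
        doc.add_annotation("", 20, 25, "B")   # not a successor of A
        assert [(m.start, m.end) for m in pt.match(doc, "{A}{B}", {"A", "B"})] == [(0, 12)]


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate annotation subsequences (successor chains)
# and test each against an independent AST acceptor.


def oracle_accepts(node, seq) -> bool:
    if isinstance(node, pt.Constraint):
        return len(seq) == 1 and node.accepts(seq[0])
    if isinstance(node, pt.Group):
        return oracle_accepts(node.expr, seq)
    if isinstance(node, pt.Alt):
        return any(oracle_accepts(c, seq) for c in node.children)
    if isinstance(node, pt.Seq):
        def split(i, rest):
            if i == len(node.children) - 1:
                return oracle_accepts(node.children[i], rest)
            return any(
                oracle_accepts(node.children[i], rest[:k]) and split(i + 1, rest[k:])
                for k in range(len(rest) + 1)
            )
        if not node.children:
            return not seq
        return split(0, tuple(seq))
    if isinstance(node, pt.Quant):
        def reps(rest, count):
            if not rest:
                return count >= node.min
            if count >= node.max:
                return False
            return any(
                oracle_accepts(node.expr, rest[:k]) and reps(rest[k:], count + 1)
                for k in range(1, len(rest) + 1)
            )
        return reps(tuple(seq), 0)
    raise TypeError(node)


def oracle_chains(anns, max_len=6):
    """All successor-valid chains of annotations up to max_len."""
    chains = []

    def successors(end):
        starts = [a.start for a in anns if a.start >= end]
        if not starts:
            return []
        s = min(starts)
        return [a for a in anns if a.start == s]

    def extend(chain):
        if len(chain) >= max_len:
            return
        for nxt in successors(chain[-1].end):
            chains.append(chain + [nxt])
            extend(chain + [nxt])

    for a in anns:
        chains.append([a])
        extend([a])
    return chains


def oracle_match(doc, expr, input_types):
    anns = [a for a in doc.annotation_set("") if a.ann_type in input_types]
    hits = set()
    for chain in oracle_chains(anns):
        if oracle_accepts(expr, chain):
            hits.add(tuple(a.id for a in chain))
    return hits


def random_pattern(rng, depth=0):
    types = ["A", "B", "C"]
    choice = rng.random()
    if depth >= 2 or choice < 0.45:
        tests = ()
        if rng.random() < 0.4:
            tests = (("f", rng.choice(["==", "!="]), rng.choice(["x", "y"])),)
        return pt.Constraint(rng.choice(types), tests)
    if choice < 0.65:
        return pt.Seq(tuple(random_pattern(rng, depth + 1) for _ in range(rng.randint(2, 3))))
    if choice < 0.8:
        return pt.Alt(tuple(random_pattern(rng, depth + 1) for _ in range(2)))
    return pt.Quant(random_pattern(rng, depth + 1), rng.choice([0, 1]), rng.choice([1, 2, 3]))


def engine_vs_oracle(seed):
    rng = random.Random(seed)
    doc = gen_random_graph(
        text_len=rng.randint(5, 25),
        n_ann=rng.randint(0, 12),
        type_alphabet=("A", "B", "C"),
        seed=seed + 1,
    )
    expr = random_pattern(rng)
    got = {
        tuple(a.id for a in m.annotations)
        for m in pt.match(doc, expr, {"A", "B", "C"})
        if len(m.annotations) <= 6
    }
    want = oracle_match(doc, expr, {"A", "B", "C"})
    return got, want


@pytest.mark.parametrize("seed", range(60))
def test_match_equals_brute_force(seed):
    """Engine matches = brute-force subsequence enumeration (≤ 6 long)."""
    got, want = engine_vs_oracle(seed)
    assert got == want


# ---------------------------------------------------------------------------
# Transduction


GRAMMAR = (
    "Phase: P\nInput: Person Token Organization\nOptions: control={control}\n"
    "Rule: PV\nPriority: 1\n"
    '({{Person}}{{Token.category=="VBD"}}{{Organization}}):pv\n'
    "--> :pv.PV = {{source = :pv@string}}\n"
)


class TestApplyGrammar:
    def test_rule_creates_annotation(self):
        doc = _fig5_doc()
        g = pt.parse_grammar(GRAMMAR.format(control="appelt"))
        assert pt.apply_grammar(doc, g) == 1
        (pv,) = am.select(doc, ann_type="PV")
        assert pv.span == (0, 22)
        assert pv.features["source"] == doc.text[0:22]

    def _overlap_doc(self):
        doc = am.create_document("x" * 10)
        doc.add_annotation("", 0, 5, "A")
        doc.add_annotation("", 0, 8, "A")
        return doc

    def test_appelt_fires_longest_only(self):
        doc = self._overlap_doc()
        g = pt.parse_grammar(
            "Phase: P\nInput: A\nOptions: control=appelt\n"
            "Rule: R\n({A}):x --> :x.Out = {}\n"
        )
        pt.apply_grammar(doc, g)
        assert [(a.start, a.end) for a in am.select(doc, ann_type="Out")] == [(0, 8)]

    def test_all_fires_every_match(self):
        doc = self._overlap_doc()
        g = pt.parse_grammar(
            "Phase: P\nInput: A\nOptions: control=all\n"
            "Rule: R\n({A}):x --> :x.Out = {}\n"
        )
        pt.apply_grammar(doc, g)
        assert len(am.select(doc, ann_type="Out")) == 2

    def test_appelt_tie_priority_breaks(self):
        doc = am.create_document("x" * 10)
        doc.add_annotation("", 0, 5, "A")
        g = pt.parse_grammar(
            "Phase: P\nInput: A\nOptions: control=appelt\n"
            "Rule: Low\nPriority: 1\n({A}):x --> :x.Low = {}\n"
            "Rule: High\nPriority: 9\n({A}):x --> :x.High = {}\n"
        )
        pt.apply_grammar(doc, g)
        assert len(am.select(doc, ann_type="High")) == 1
        assert am.select(doc, ann_type="Low") == []

    def test_idempotent_when_output_not_input(self):
        doc = _fig5_doc()
        g = pt.parse_grammar(GRAMMAR.format(control="appelt"))
        pt.apply_grammar(doc, g)
        pt.apply_grammar(doc, g)
        # matches are identical both times; annotations duplicate but the
        # match set itself is unchanged
        expr = g.rules[0].lhs
        assert len(pt.match(doc, expr, g.input_types)) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_appelt_output_subset_of_all(self, seed):
        rng = random.Random(seed)
        text = "x" * 30
        spans = sorted(
            (min(a, b), max(a, b))
            for a, b in (
                (rng.randint(0, 29), rng.randint(0, 29)) for _ in range(6)
            )
        )
        base_a = am.create_document(text)
        base_b = am.create_document(text)
        for s, e in spans:
            base_a.add_annotation("", s, e + 1, "A")
            base_b.add_annotation("", s, e + 1, "A")
        src = "Phase: P\nInput: A\nOptions: control={}\nRule: R\n({{A}}({{A}})?):x --> :x.Out = {{}}\n"
        pt.apply_grammar(base_a, pt.parse_grammar(src.format("appelt")))
        pt.apply_grammar(base_b, pt.parse_grammar(src.format("all")))
        out_a = {(a.start, a.end) for a in am.select(base_a, ann_type="Out")}
        out_b = {(a.start, a.end) for a in am.select(base_b, ann_type="Out")}
        assert out_a <= out_b
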