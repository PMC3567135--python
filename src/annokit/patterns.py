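"""Finite-state pattern matching and transduction over annotation graphs.

A pattern is a regular expression whose atoms are *annotation constraints*
(``{Person}``, ``{Token.category=="VBD"}``) rather than characters.
Matching walks the annotation sequence: after consuming an annotation A,
the candidate successors are the annotations of the input types whose
start offset is the smallest start >= A.end; all annotations at that
start are alternatives.  This makes "followed by" well defined even when
annotation types do not tile the text.

Rules attach a transduction right-hand side that creates new annotations
over labelled groups of the match; grammars bundle rules with a control
style: ``all`` (every match fires) or ``appelt`` (at each position only
the longest match fires — ties broken by priority, then rule order — and
matching resumes after its end).

Grammar file format::

    Phase: FindPV
    Input: Person Token Organization
    Options: control=appelt
    Rule: PV
    Priority: 10
    ({Person}{Token.category=="VBD"}{Organization}):pv
    --> :pv.PersonVerbOrg = {kind = "pvo", text = :pv@string}

RHS feature values may be quoted literals, integers, ``:label@string``
(the covered text of the bound group) or ``:label@feat`` (the value of
feature ``feat`` on the first annotation of the bound group).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .anno_model import Annotation, Document

__all__ = [
    "Constraint",
    "Seq",
    "Alt",
    "Quant",
    "Group",
    "Rule",
    "Grammar",
    "Match",
    "PatternParseError",
    "RuleError",
    "parse_pattern",
    "parse_grammar",
    "match",
    "apply_grammar",
]

INFINITY = float("inf")


class PatternParseError(ValueError):
    """Syntax error in a pattern or grammar, with line/column info."""


class RuleError(ValueError):
    """A rule RHS references a label not bound on its LHS."""


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Constraint:
    ann_type: str
    feature_tests: tuple = ()  # of (name, op, value), op in {"==", "!="}

    def accepts(self, ann: Annotation) -> bool:
        if ann.ann_type != self.ann_type:
            return False
        for name, op, value in self.feature_tests:
            present = name in ann.features
            if op == "==":
                if not present or ann.features[name] != value:
                    return False
            else:  # "!="
                if present and ann.features[name] == value:
                    return False
        return True


@dataclass(frozen=True)
class Seq:
    children: tuple


@dataclass(frozen=True)
class Alt:
    children: tuple


@dataclass(frozen=True)
class Quant:
    expr: object
    min: int
    max: float  # int or INFINITY


@dataclass(frozen=True)
class Group:
    label: str
    expr: object


@dataclass
class Rule:
    name: str
    priority: int
    lhs: object
    # rhs: list of (label, new_type, feature template); template values are
    # ("lit", value) | ("text", label) | ("feat", label, feature-name)
    rhs: list = field(default_factory=list)


@dataclass
class Grammar:
    name: str
    input_types: set
    rules: list
    control: str = "appelt"  # appelt | all


@dataclass(frozen=True)
class Match:
    start: int
    end: int
    annotations: tuple  # consumed annotations in order
    bindings: tuple  # of (label, start, end) for bound groups

    def binding_span(self, label: str) -> tuple[int, int] | None:
        for lab, s, e in self.bindings:
            if lab == label:
                return (s, e)
        return None

    def binding_annotations(self, label: str) -> tuple:
        span = self.binding_span(label)
        if span is None:
            return ()
        return tuple(a for a in self.annotations if span[0] <= a.start and a.end <= span[1])


# ---------------------------------------------------------------------------
# Pattern parser (recursive descent)

_TOKEN_SPEC = [
    ("STRING", r'"(?:[^"\\]|\\.)*"'),
    ("NUMBER", r"-?\d+"),
    ("OP", r"==|!=|[{}()|&?*+:.,=]|-->"),
    ("ARROW", r"-->"),
    ("IDENT", r"[A-Za-z_][A-Za-z0-9_]*"),
    ("WS", r"\s+"),
    ("BAD", r"."),
]
_LEX_RE = re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC))


@dataclass
class _Tok:
    kind: str
    value: str
    line: int
    col: int


def _lex(src: str) -> list[_Tok]:
    toks = []
    line, col = 1, 1
    for m in _LEX_RE.finditer(src):
        kind, value = m.lastgroup, m.group()
        if kind == "BAD":
            raise PatternParseError(f"line {line}, col {col}: unexpected character {value!r}")
        if kind != "WS":
            toks.append(_Tok(kind, value, line, col))
        nl = value.count("\n")
        if nl:
            line += nl
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
    return toks


class _Parser:
    def __init__(self, toks: list[_Tok]):
        self.toks = toks
        self.pos = 0

    def peek(self) -> _Tok | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise PatternParseError("unexpected end of input")
        self.pos += 1
        return tok

    def expect(self, value: str) -> _Tok:
        tok = self.peek()
        if tok is None or tok.value != value:
            got = "end of input" if tok is None else repr(tok.value)
            where = "" if tok is None else f"line {tok.line}, col {tok.col}: "
            raise PatternParseError(f"{where}expected {value!r}, got {got}")
        return self.next()

    def error(self, msg: str):
        tok = self.peek()
        where = "" if tok is None else f"line {tok.line}, col {tok.col}: "
        raise PatternParseError(where + msg)

    # pattern := alt ; alt := seq ('|' seq)* ; seq := postfixed+
    def parse_alt(self):
        branches = [self.parse_seq()]
        while self.peek() is not None and self.peek().value == "|":
            self.next()
            branches.append(self.parse_seq())
        return branches[0] if len(branches) == 1 else Alt(tuple(branches))

    def parse_seq(self):
        items = [self.parse_postfixed()]
        while True:
            tok = self.peek()
            if tok is None or tok.value not in ("{", "("):
                break
            items.append(self.parse_postfixed())
        return items[0] if len(items) == 1 else Seq(tuple(items))

    def parse_postfixed(self):
        node = self.parse_atom()
        while True:
            tok = self.peek()
            if tok is None:
                break
            if tok.value == "?":
                self.next()
                node = Quant(node, 0, 1)
            elif tok.value == "*":
                self.next()
                node = Quant(node, 0, INFINITY)
            elif tok.value == "+":
                self.next()
                node = Quant(node, 1, INFINITY)
            elif tok.value == ":":
                # group label binds the preceding atom/group
                self.next()
                label = self.next()
                if label.kind != "IDENT":
                    self.error("expected a label name after ':'")
                node = Group(label.value, node)
            else:
                break
        return node

    def parse_atom(self):
        tok = self.peek()
        if tok is None:
            self.error("expected a constraint or group")
        if tok.value == "(":
            self.next()
            node = self.parse_alt()
            self.expect(")")
            return node
        if tok.value == "{":
            return self.parse_constraint()
        self.error(f"expected '{{' or '(', got {tok.value!r}")

    def parse_constraint(self):
        self.expect("{")
        tok = self.next()
        if tok.kind != "IDENT":
            raise PatternParseError(
                f"line {tok.line}, col {tok.col}: expected an annotation type name"
            )
        ann_type = tok.value
        tests = []
        while self.peek() is not None and self.peek().value in (".", ","):
            if self.peek().value == ",":
                self.next()
                t = self.next()
                if t.kind != "IDENT" or t.value != ann_type:
                    # only single-type constraints are supported
                    raise PatternParseError(
                        f"line {t.line}, col {t.col}: constraint lists one annotation type; "
                        f"got {t.value!r} after {ann_type!r}"
                    )
                continue
            self.next()  # '.'
            name = self.next()
            if name.kind != "IDENT":
                raise PatternParseError(
                    f"line {name.line}, col {name.col}: expected a feature name"
                )
            op = self.next()
            if op.value not in ("==", "!="):
                raise PatternParseError(
                    f"line {op.line}, col {op.col}: expected '==' or '!=', got {op.value!r}"
                )
            val = self.next()
            if val.kind == "STRING":
                value = _unquote(val.value)
            elif val.kind == "NUMBER":
                value = int(val.value)
            elif val.kind == "IDENT" and val.value in ("true", "false"):
                value = val.value == "true"
            else:
                raise PatternParseError(
                    f"line {val.line}, col {val.col}: expected a value, got {val.value!r}"
                )
            tests.append((name.value, op.value, value))
        self.expect("}")
        return Constraint(ann_type, tuple(tests))


def _unquote(s: str) -> str:
    return re.sub(r"\\(.)", r"\1", s[1:-1])


def parse_pattern(src: str):
    """Parse a pattern expression such as ``{Person}({Token})?:v`` into an AST."""
    parser = _Parser(_lex(src))
    node = parser.parse_alt()
    if parser.peek() is not None:
        parser.error(f"trailing input starting at {parser.peek().value!r}")
    return node


# ---------------------------------------------------------------------------
# Grammar file parser


_HEADER_RE = re.compile(r"^(Phase|Input|Options|Rule|Priority)\s*:\s*(.*)$")


def parse_grammar(src: str) -> Grammar:
    """Parse a grammar file (Phase/Input/Options headers plus rules)."""
    name = "unnamed"
    input_types: set = set()
    control = "appelt"
    rules: list[Rule] = []

    lines = src.splitlines()
    i = 0
    # headers
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("//") or line.startswith("#"):
            i += 1
            continue
        m = _HEADER_RE.match(line)
        if m is None:
            raise PatternParseError(f"line {i + 1}: expected a header or Rule:, got {line!r}")
        key, rest = m.group(1), m.group(2).strip()
        if key == "Phase":
            name = rest
        elif key == "Input":
            input_types.update(rest.split())
        elif key == "Options":
            for opt in re.split(r"[,\s]+", rest):
                if not opt:
                    continue
                k, _, v = opt.partition("=")
                if k == "control":
                    if v not in ("appelt", "all"):
                        raise PatternParseError(f"line {i + 1}: unknown control {v!r}")
                    control = v
        elif key == "Rule":
            rule, i = _parse_rule(lines, i)
            rules.append(rule)
            continue
        i += 1
    if not input_types:
        raise PatternParseError("grammar declares no Input annotation types")
    return Grammar(name, input_types, rules, control)


def _parse_rule(lines: list[str], i: int) -> tuple[Rule, int]:
    m = _HEADER_RE.match(lines[i].strip())
    rule_name = m.group(2).strip()
    i += 1
    priority = 0
    if i < len(lines):
        pm = _HEADER_RE.match(lines[i].strip())
        if pm and pm.group(1) == "Priority":
            priority = int(pm.group(2).strip())
            i += 1
    # collect the body until the next "Rule:" header or EOF
    body_lines = []
    while i < len(lines):
        stripped = lines[i].strip()
        if _HEADER_RE.match(stripped) and _HEADER_RE.match(stripped).group(1) == "Rule":
            break
        body_lines.append(lines[i])
        i += 1
    body = "\n".join(body_lines)
    if "-->" not in body:
        raise PatternParseError(f"rule {rule_name!r}: missing '-->'")
    lhs_src, rhs_src = body.split("-->", 1)
    lhs = parse_pattern(lhs_src)
    rhs = _parse_rhs(rhs_src, rule_name)
    labels = _collect_labels(lhs)
    for label, _, _ in rhs:
        if label not in labels:
            raise RuleError(f"rule {rule_name!r}: RHS label :{label} is not bound on the LHS")
    return Rule(rule_name, priority, lhs, rhs), i


def _collect_labels(node, acc=None) -> set:
    if acc is None:
        acc = set()
    if isinstance(node, Group):
        if node.label in acc:
            raise PatternParseError(f"duplicate group label :{node.label}")
        acc.add(node.label)
        _collect_labels(node.expr, acc)
    elif isinstance(node, (Seq, Alt)):
        for c in node.children:
            _collect_labels(c, acc)
    elif isinstance(node, Quant):
        _collect_labels(node.expr, acc)
    return acc


_RHS_ACTION_RE = re.compile(
    r":(?P<label>[A-Za-z_]\w*)\s*\.\s*(?P<type>[A-Za-z_]\w*)\s*=\s*\{(?P<body>[^{}]*)\}"
)
_RHS_VALUE_RE = re.compile(
    r"""^(?:
        "(?P<str>(?:[^"\\]|\\.)*)" |
        (?P<num>-?\d+) |
        :(?P<vlabel>[A-Za-z_]\w*)@(?P<what>[A-Za-z_]\w*)
    )$""",
    re.VERBOSE,
)


def _parse_rhs(src: str, rule_name: str) -> list:
    actions = []
    rest = src.strip()
    if not rest:
        raise PatternParseError(f"rule {rule_name!r}: empty RHS")
    pos = 0
    for m in _RHS_ACTION_RE.finditer(rest):
        template = []
        body = m.group("body").strip()
        if body:
            for item in body.split(","):
                fname, eq, fval = item.partition("=")
                if not eq:
                    raise PatternParseError(
                        f"rule {rule_name!r}: bad feature assignment {item.strip()!r}"
                    )
                fname = fname.strip()
                vm = _RHS_VALUE_RE.match(fval.strip())
                if vm is None:
                    raise PatternParseError(
                        f"rule {rule_name!r}: bad feature value {fval.strip()!r}"
                    )
                if vm.group("str") is not None:
                    template.append((fname, ("lit", re.sub(r"\\(.)", r"\1", vm.group("str")))))
                elif vm.group("num") is not None:
                    template.append((fname, ("lit", int(vm.group("num")))))
                elif vm.group("what") == "string":
                    template.append((fname, ("text", vm.group("vlabel"))))
                else:
                    template.append((fname, ("feat", vm.group("vlabel"), vm.group("what"))))
        actions.append((m.group("label"), m.group("type"), template))
        pos = m.end()
    if not actions:
        raise PatternParseError(f"rule {rule_name!r}: no RHS actions found")
    return actions


# ---------------------------------------------------------------------------
# Matching engine


def _input_annotations(doc: Document, input_types, set_name: str = "") -> list[Annotation]:
    anns = [
        a
        for aset in ([doc.annotation_set(set_name, create=False)] if set_name in doc.sets else [])
        for a in aset
        if a.ann_type in input_types
    ]
    anns.sort(key=Annotation.sort_key)
    return anns


def _successors(anns: Sequence[Annotation], from_offset: int) -> list[Annotation]:
    """Annotations whose start is the minimal start >= from_offset."""
    starts = [a.start for a in anns if a.start >= from_offset]
    if not starts:
        return []
    s = min(starts)
    return [a for a in anns if a.start == s]


class _MState:
    """Backtracking match state: consumed annotations + group bindings."""

    __slots__ = ("consumed", "bindings")

    def __init__(self, consumed=(), bindings=()):
        self.consumed = consumed
        self.bindings = bindings

    def after(self, ann: Annotation) -> "_MState":
        s = _MState(self.consumed + (ann,), self.bindings)
        return s


def _match_node(node, state: _MState, anns, first: Annotation | None) -> Iterator[_MState]:
    """Yield all states after *node* consumes annotations.

    *first*: when no annotation has been consumed yet, the match is
    anchored so that the first consumed annotation must be exactly this
    one; afterwards successor semantics apply.
    """
    if isinstance(node, Constraint):
        if not state.consumed:
            candidates = [first] if first is not None else []
        else:
            candidates = _successors(anns, state.consumed[-1].end)
        for cand in candidates:
            if node.accepts(cand):
                yield state.after(cand)
    elif isinstance(node, Seq):
        def rec(idx: int, st: _MState) -> Iterator[_MState]:
            if idx == len(node.children):
                yield st
                return
            for nxt in _match_node(node.children[idx], st, anns, first):
                yield from rec(idx + 1, nxt)

        yield from rec(0, state)
    elif isinstance(node, Alt):
        for child in node.children:
            yield from _match_node(child, state, anns, first)
    elif isinstance(node, Quant):
        def rec(count: int, st: _MState) -> Iterator[_MState]:
            if count >= node.min:
                yield st
            if count < node.max:
                for nxt in _match_node(node.expr, st, anns, first):
                    if len(nxt.consumed) == len(st.consumed):
                        continue  # zero-width repetition: stop
                    yield from rec(count + 1, nxt)

        yield from rec(0, state)
    elif isinstance(node, Group):
        before = len(state.consumed)
        for nxt in _match_node(node.expr, state, anns, first):
            inner = nxt.consumed[before:]
            if inner:
                binding = (node.label, inner[0].start, inner[-1].end)
            else:
                # empty group: zero-width at the current position
                at = state.consumed[-1].end if state.consumed else (
                    first.start if first is not None else 0
                )
                binding = (node.label, at, at)
            yield _MState(nxt.consumed, nxt.bindings + (binding,))
    else:  # pragma: no cover - guarded by the parser
        raise TypeError(f"unknown pattern node {node!r}")


def match(
    doc: Document,
    expr,
    input_types,
    set_name: str = "",
) -> list[Match]:
    """Return all matches of *expr* over the annotation sequence.

    A match records its character span (first annotation start to last
    annotation end), the consumed annotations and the labelled group
    bindings.  Empty-width matches are suppressed.  Results are ordered
    by (start, end) and deduplicated on (span, consumed ids, bindings).
    """
    if isinstance(expr, str):
        expr = parse_pattern(expr)
    anns = _input_annotations(doc, set(input_types), set_name)
    results = {}
    for a in anns:
        for st in _match_node(expr, _MState(), anns, a):
            if not st.consumed:
                continue  # empty-width match
            m = Match(
                st.consumed[0].start,
                st.consumed[-1].end,
                st.consumed,
                st.bindings,
            )
            key = (m.start, m.end, tuple(x.id for x in m.annotations), m.bindings)
            results.setdefault(key, m)
    return sorted(results.values(), key=lambda m: (m.start, m.end))


# ---------------------------------------------------------------------------
# Transduction


def _fire(doc: Document, rule: Rule, m: Match, set_name: str) -> int:
    created = 0
    for label, new_type, template in rule.rhs:
        span = m.binding_span(label)
        if span is None:
            continue  # group inside an unexercised alternation branch
        feats = {}
        for fname, spec in template:
            if spec[0] == "lit":
                feats[fname] = spec[1]
            elif spec[0] == "text":
                s = m.binding_span(spec[1])
                feats[fname] = doc.text[s[0] : s[1]] if s else ""
            else:  # feat copy from the first annotation of the bound group
                _, src_label, feat_name = spec
                bound = m.binding_annotations(src_label)
                if bound and feat_name in bound[0].features:
                    feats[fname] = bound[0].features[feat_name]
        doc.add_annotation(set_name, span[0], span[1], new_type, feats)
        created += 1
    return created


def apply_grammar(doc: Document, grammar: Grammar, set_name: str = "") -> int:
    """Run every rule of *grammar* over *doc*; returns annotations created.

    ``control=all``: every match of every rule fires.  ``control=appelt``:
    matches of all rules compete; at each position the longest match wins
    (ties: higher priority, then earlier rule order), fires, and matching
    resumes after its end.
    """
    all_matches: list[tuple[Match, int, Rule]] = []
    for order, rule in enumerate(grammar.rules):
        for m in match(doc, rule.lhs, grammar.input_types, set_name):
            all_matches.append((m, order, rule))

    created = 0
    if grammar.control == "all":
        for m, _, rule in sorted(all_matches, key=lambda t: (t[0].start, t[0].end, t[1])):
            created += _fire(doc, rule, m, set_name)
        return created

    # appelt: scan left to right, longest match first
    pending = sorted(
        all_matches,
        key=lambda t: (t[0].start, -(t[0].end - t[0].start), -t[2].priority, t[1]),
    )
    pos = -1
    idx = 0
    while idx < len(pending):
        m, order, rule = pending[idx]
        if m.start < pos:
            idx += 1
            continue
        # competitors at the same start position
        group = [t for t in pending[idx:] if t[0].start == m.start]
        winner = group[0]  # sort order already encodes length/priority/order
        created += _fire(doc, winner[2], winner[0], set_name)
        pos = winner[0].end
        # skip every match that starts before the winner's end
        idx += 1
        while idx < len(pending) and pending[idx][0].start < pos:
            idx += 1
    return created
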