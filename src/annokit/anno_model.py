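"""Stand-off annotation document model.

Text is stored once, immutably; all mark-up lives in named annotation sets
whose members point back into the text by character offsets (the
"annotation graph" representation).  Offsets are 0-based, half-open
``[start, end)`` and counted in Unicode code points.  Inline XML/HTML can
be converted into this representation by stripping the tags and recording
each element as an annotation in the ``"Original markups"`` set, and whole
documents round-trip through a JSON stand-off serialization.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from lxml import etree, html as _lxml_html

__all__ = [
    "Annotation",
    "AnnotationSet",
    "Document",
    "Corpus",
    "MarkupError",
    "SchemaError",
    "ORIGINAL_MARKUPS",
    "create_document",
    "from_inline_markup",
    "add_annotation",
    "select",
    "to_standoff",
    "from_standoff",
]

#: Name of the annotation set that receives stripped inline markup.
ORIGINAL_MARKUPS = "Original markups"

#: HTML elements accepted by the best-effort tag-soup reader.
HTML_WHITELIST = frozenset({"p", "div", "b", "i", "a", "span", "br"})

_SCALAR_TYPES = (str, int, float, bool, _dt.date)


class MarkupError(ValueError):
    """Raised for inline markup outside the supported XML/HTML subset."""


class SchemaError(ValueError):
    """Raised for malformed stand-off input; names the offending field."""


def _check_features(features: Mapping[str, object]) -> dict:
    out = {}
    for name, value in dict(features or {}).items():
        if not isinstance(name, str) or not name:
            raise ValueError(f"feature names must be non-empty text, got {name!r}")
        if not isinstance(value, _SCALAR_TYPES):
            raise ValueError(
                f"feature {name!r} has non-scalar value of type {type(value).__name__}"
            )
        out[name] = value
    return out


@dataclass
class Annotation:
    """A typed, feature-bearing span keyed by character offsets."""

    id: int
    ann_type: str
    start: int
    end: int
    features: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.start, self.end, self.id)

    def covered_text(self, doc: "Document") -> str:
        return doc.text[self.start : self.end]

    def matches_features(self, constraints: Mapping[str, object] | None) -> bool:
        if not constraints:
            return True
        return all(self.features.get(k) == v for k, v in constraints.items())


class AnnotationSet:
    """A named collection of annotations; iteration is (start, end, id) ordered."""

    def __init__(self, name: str = ""):
        self.name = name
        self._by_id: dict[int, Annotation] = {}

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(sorted(self._by_id.values(), key=Annotation.sort_key))

    def __contains__(self, ann_id: int) -> bool:
        return ann_id in self._by_id

    def get(self, ann_id: int) -> Annotation | None:
        return self._by_id.get(ann_id)

    def by_type(self, ann_type: str) -> list[Annotation]:
        return [a for a in self if a.ann_type == ann_type]

    def _add(self, ann: Annotation) -> None:
        if ann.id in self._by_id:
            raise ValueError(f"duplicate annotation id {ann.id} in set {self.name!r}")
        self._by_id[ann.id] = ann

    def remove(self, ann_id: int) -> None:
        # ids are never reused: the document-level counter only moves forward
        self._by_id.pop(ann_id)


class Document:
    """Immutable text plus named annotation sets (the annotation graph).

    The default annotation set is named ``""``.  Annotation ids are
    per-document monotone integers starting at 0; deleting an annotation
    never frees its id.
    """

    def __init__(self, text: str, features: Mapping[str, object] | None = None):
        if not isinstance(text, str):
            raise TypeError("document text must be a unicode string")
        self._text = text
        self.features = _check_features(features or {})
        self._sets: dict[str, AnnotationSet] = {"": AnnotationSet("")}
        self._next_id = 0

    @property
    def text(self) -> str:
        return self._text

    @property
    def sets(self) -> Mapping[str, AnnotationSet]:
        return self._sets

    def annotation_set(self, name: str = "", create: bool = True) -> AnnotationSet:
        if name not in self._sets:
            if not create:
                raise KeyError(f"unknown annotation set {name!r}")
            self._sets[name] = AnnotationSet(name)
        return self._sets[name]

    def add_annotation(
        self,
        set_name: str,
        start: int,
        end: int,
        ann_type: str,
        features: Mapping[str, object] | None = None,
    ) -> int:
        if not (0 <= start <= end <= len(self._text)):
            raise ValueError(
                f"span [{start}, {end}) out of range for text of length {len(self._text)}"
            )
        ann = Annotation(self._next_id, ann_type, start, end, _check_features(features or {}))
        self.annotation_set(set_name)._add(ann)
        self._next_id += 1
        return ann.id

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n = sum(len(s) for s in self._sets.values())
        return f"<Document {len(self._text)} chars, {n} annotations in {len(self._sets)} sets>"


@dataclass
class Corpus:
    """An ordered collection of documents keyed by unique text ids."""

    doc_ids: list[str] = field(default_factory=list)
    documents: dict[str, Document] = field(default_factory=dict)

    def add(self, doc_id: str, doc: Document) -> None:
        if doc_id in self.documents:
            raise ValueError(f"duplicate document id {doc_id!r}")
        self.doc_ids.append(doc_id)
        self.documents[doc_id] = doc

    def __len__(self) -> int:
        return len(self.doc_ids)

    def __iter__(self) -> Iterator[tuple[str, Document]]:
        for doc_id in self.doc_ids:
            yield doc_id, self.documents[doc_id]


# ---------------------------------------------------------------------------
# Construction


def create_document(text: str, features: Mapping[str, object] | None = None) -> Document:
    """Create a document holding *text* verbatim, with an empty default set."""
    return Document(text, features)


def _walk_element(elem, doc: Document, cursor: int, whitelist=None) -> int:
    """Append *elem*'s character data to nothing (text is fixed already) --
    rather, record the annotation spans while replaying the same traversal
    that produced the text.  Returns the cursor after the element."""
    start = cursor
    if elem.text:
        cursor += len(elem.text)
    for child in elem:
        cursor = _walk_element(child, doc, cursor, whitelist)
        if child.tail:
            cursor += len(child.tail)
    tag = str(elem.tag) if isinstance(elem.tag, str) else None
    if tag is not None and (whitelist is None or tag.lower() in whitelist):
        doc.add_annotation(
            ORIGINAL_MARKUPS, start, cursor, tag, {k: v for k, v in elem.attrib.items()}
        )
    return cursor


def _element_text(elem) -> str:
    parts = []
    if elem.text:
        parts.append(elem.text)
    for child in elem:
        parts.append(_element_text(child))
        if child.tail:
            parts.append(child.tail)
    return "".join(parts)


def from_inline_markup(markup: str, html: bool = False) -> Document:
    """Strip inline markup, keeping each element as a stand-off annotation.

    The document text is the concatenated character data; every element
    becomes an annotation in the ``"Original markups"`` set spanning its
    text content, with ``ann_type`` the element name and the attributes as
    features.  XML must be well formed; with ``html=True`` a tag-soup
    subset is accepted and only whitelisted elements (p, div, b, i, a,
    span, br) are recorded.
    """
    if html:
        try:
            root = _lxml_html.fromstring(markup)
        except Exception as exc:  # lxml raises several parser error types
            raise MarkupError(f"unparseable HTML: {exc}") from exc
        whitelist = HTML_WHITELIST
    else:
        try:
            root = etree.fromstring(markup.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            line, col = exc.position
            raise MarkupError(
                f"malformed XML at line {line}, column {col}: {exc.msg}"
            ) from exc
        whitelist = None
    text = _element_text(root)
    doc = Document(text)
    _walk_element(root, doc, 0, whitelist)
    return doc


def add_annotation(
    doc: Document,
    set_name: str,
    start: int,
    end: int,
    ann_type: str,
    features: Mapping[str, object] | None = None,
) -> int:
    """Add an annotation; returns its fresh (monotone) id."""
    return doc.add_annotation(set_name, start, end, ann_type, features)


# ---------------------------------------------------------------------------
# Selection


def _relation_ok(ann: Annotation, rng: tuple[int, int], relation: str) -> bool:
    lo, hi = rng
    if relation == "within":
        return lo <= ann.start and ann.end <= hi
    if relation == "covering":
        return ann.start <= lo and hi <= ann.end
    if relation == "overlapping":
        if ann.start == ann.end:  # zero-length: interior point of the range
            return lo < ann.start < hi
        return ann.start < hi and lo < ann.end
    raise ValueError(f"unknown relation {relation!r}")


def select(
    doc: Document,
    set_name: str = "",
    ann_type: str | None = None,
    feature_constraints: Mapping[str, object] | None = None,
    range: tuple[int, int] | None = None,
    relation: str = "within",
) -> list[Annotation]:
    """Return annotations matching every given criterion, (start, end, id) ordered."""
    aset = doc.annotation_set(set_name, create=False)
    out = []
    for ann in aset:
        if ann_type is not None and ann.ann_type != ann_type:
            continue
        if not ann.matches_features(feature_constraints):
            continue
        if range is not None and not _relation_ok(ann, range, relation):
            continue
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# Stand-off serialization
#
# JSON schema: {"text": str, "features": {...}, "sets": {name: [
#   {"id": int, "type": str, "start": int, "end": int, "features": {...}}]}}
# Date-valued features are encoded as {"$date": "YYYY-MM-DD"} so that values
# round-trip with their types intact.


def _enc_value(v):
    if isinstance(v, _dt.date) and not isinstance(v, _dt.datetime):
        return {"$date": v.isoformat()}
    return v


def _dec_value(v, where: str):
    if isinstance(v, dict):
        if set(v) == {"$date"}:
            try:
                return _dt.date.fromisoformat(v["$date"])
            except ValueError as exc:
                raise SchemaError(f"{where}: bad $date value {v['$date']!r}") from exc
        raise SchemaError(f"{where}: feature values must be scalars")
    return v


def _enc_features(fm: Mapping[str, object]) -> dict:
    return {k: _enc_value(v) for k, v in fm.items()}


def _dec_features(obj, where: str) -> dict:
    if not isinstance(obj, dict):
        raise SchemaError(f"{where}: 'features' must be an object")
    return {k: _dec_value(v, f"{where}.{k}") for k, v in obj.items()}


def to_standoff(doc: Document) -> str:
    """Serialize a document (text, features, all sets and ids) to JSON."""
    payload = {
        "text": doc.text,
        "features": _enc_features(doc.features),
        "sets": {
            name: [
                {
                    "id": a.id,
                    "type": a.ann_type,
                    "start": a.start,
                    "end": a.end,
                    "features": _enc_features(a.features),
                }
                for a in aset
            ]
            for name, aset in doc.sets.items()
        },
    }
    return json.dumps(payload, ensure_ascii=False, indent=None, sort_keys=True)


def from_standoff(payload: str) -> Document:
    """Inverse of :func:`to_standoff`; raises :class:`SchemaError` on bad input."""
    try:
        obj = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaError("top level: expected an object")
    for key in ("text", "features", "sets"):
        if key not in obj:
            raise SchemaError(f"top level: missing field {key!r}")
    if not isinstance(obj["text"], str):
        raise SchemaError("'text' must be a string")
    doc = Document(obj["text"], _dec_features(obj["features"], "features"))
    if not isinstance(obj["sets"], dict):
        raise SchemaError("'sets' must be an object")
    max_id = -1
    for name, anns in obj["sets"].items():
        aset = doc.annotation_set(name)
        if not isinstance(anns, list):
            raise SchemaError(f"sets.{name}: expected a list")
        for i, a in enumerate(anns):
            where = f"sets.{name}[{i}]"
            if not isinstance(a, dict):
                raise SchemaError(f"{where}: expected an object")
            for key in ("id", "type", "start", "end", "features"):
                if key not in a:
                    raise SchemaError(f"{where}: missing field {key!r}")
            if not isinstance(a["id"], int):
                raise SchemaError(f"{where}.id: must be an integer")
            if not (isinstance(a["start"], int) and isinstance(a["end"], int)):
                raise SchemaError(f"{where}.start/end: must be integers")
            if not (0 <= a["start"] <= a["end"] <= len(doc.text)):
                raise SchemaError(
                    f"{where}: span [{a['start']}, {a['end']}) out of range"
                )
            ann = Annotation(
                a["id"], str(a["type"]), a["start"], a["end"],
                _dec_features(a["features"], f"{where}.features"),
            )
            aset._add(ann)
            max_id = max(max_id, a["id"])
    doc._next_id = max_id + 1
    return doc


def documents_equal(a: Document, b: Document) -> bool:
    """Structural equality: text, features, sets, annotations and ids."""
    if a.text != b.text or a.features != b.features:
        return False
    if set(a.sets) != set(b.sets):
        return False
    for name in a.sets:
        xs, ys = list(a.sets[name]), list(b.sets[name])
        if len(xs) != len(ys):
            return False
        for x, y in zip(xs, ys):
            if (x.id, x.ann_type, x.start, x.end, x.features) != (
                y.id, y.ann_type, y.start, y.end, y.features,
            ):
                return False
    return True
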