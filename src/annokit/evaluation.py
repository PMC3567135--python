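"""Gold-standard comparison and inter-annotator agreement.

Annotation responses are aligned to a reference with a deterministic
greedy 1–1 matcher in (start, end) order.  ``strict`` counts a match only
when spans (and any compared features) are identical; ``lenient`` accepts
any overlap; ``average`` counts overlapping-but-not-identical pairs as
partial matches worth half a point in both precision and recall.
Inter-annotator agreement is reported as pairwise F1 between annotators,
which is symmetric under this alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .anno_model import Annotation

__all__ = ["EvalResult", "align", "evaluate", "iaa"]

MODES = ("strict", "lenient", "average")


@dataclass(frozen=True)
class EvalResult:
    correct: int
    partial: int
    spurious: int
    missing: int
    precision: float
    recall: float
    f1: float


def _spans_equal(a: Annotation, b: Annotation, features: Sequence[str]) -> bool:
    if (a.start, a.end) != (b.start, b.end):
        return False
    return all(a.features.get(f) == b.features.get(f) for f in features)


def _overlap(a: Annotation, b: Annotation) -> bool:
    return a.start < b.end and b.start < a.end


def align(
    reference: Sequence[Annotation],
    response: Sequence[Annotation],
    mode: str = "strict",
    features: Sequence[str] = (),
) -> tuple[int, int, int, int]:
    """Greedy 1–1 alignment; returns (correct, partial, spurious, missing).

    Exact (span + compared features) matches are paired first; in lenient
    and average modes the leftovers are then paired by overlap.  Pairing
    walks both sides in (start, end, id) order, so the result is
    deterministic; this greedy order is the contract even on the rare
    configurations where an optimal assignment would pair more.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ref = sorted(reference, key=Annotation.sort_key)
    resp = sorted(response, key=Annotation.sort_key)
    used = [False] * len(resp)
    correct = 0
    partial = 0
    remaining_ref = []
    for r in ref:
        for j, s in enumerate(resp):
            if not used[j] and _spans_equal(r, s, features):
                used[j] = True
                correct += 1
                break
        else:
            remaining_ref.append(r)
    if mode in ("lenient", "average"):
        for r in remaining_ref:
            for j, s in enumerate(resp):
                if not used[j] and _overlap(r, s):
                    used[j] = True
                    partial += 1
                    break
    if mode == "lenient":
        correct += partial
        partial = 0
    spurious = used.count(False)
    missing = len(ref) - correct - partial
    return (correct, partial, spurious, missing)


def _prf(correct: int, partial: int, spurious: int, missing: int) -> tuple[float, float, float]:
    eff = correct + 0.5 * partial
    p_den = correct + partial + spurious
    r_den = correct + partial + missing
    precision = eff / p_den if p_den else 0.0
    recall = eff / r_den if r_den else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate(
    reference: Sequence[Annotation],
    response: Sequence[Annotation],
    mode: str = "strict",
    features: Sequence[str] = (),
) -> EvalResult:
    """Align and score: precision, recall and F1 (0 when undefined)."""
    correct, partial, spurious, missing = align(reference, response, mode, features)
    precision, recall, f1 = _prf(correct, partial, spurious, missing)
    return EvalResult(correct, partial, spurious, missing, precision, recall, f1)


def iaa(
    annotator_sets: Sequence[Sequence[Annotation]],
    mode: str = "strict",
    features: Sequence[str] = (),
) -> tuple[dict[tuple[int, int], float], float]:
    """Pairwise F1 between annotators and the mean over pairs.

    Requires at least two annotation sets; returns ({(i, j): f1}, mean).
    """
    if len(annotator_sets) < 2:
        raise ValueError("inter-annotator agreement needs at least two annotators")
    scores = {}
    for i, j in combinations(range(len(annotator_sets)), 2):
        res = evaluate(annotator_sets[i], annotator_sets[j], mode, features)
        scores[(i, j)] = res.f1
    mean = sum(scores.values()) / len(scores)
    return scores, mean
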