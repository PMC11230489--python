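"""Entity-level strict and lenient micro precision/recall/F1.

Follows the i2b2/n2c2 convention: a *strict* match requires identical
(start, end, label); a *lenient* (also called *relaxed*) match requires
the same label and at least one character of overlap.  Matching is
greedy one-to-one, taking candidate pairs in order of decreasing
overlap (ties broken by gold start, then predicted start), so no entity
is double-counted.  Counts are pooled over all notes and types before
computing micro precision, recall and F1, with the 0/0 → 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_io import Entity

__all__ = ["STRICT", "LENIENT", "MatchResult", "TypeCounts", "EvalReport",
           "match_entities", "micro_f1"]

STRICT = "strict"
LENIENT = "lenient"


def _overlap(a: Entity, b: Entity) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class MatchResult:
    tp_pairs: list[tuple[Entity, Entity]]
    fp: list[Entity]  # unmatched predictions
    fn: list[Entity]  # unmatched gold


def match_entities(
    gold: Sequence[Entity], pred: Sequence[Entity], mode: str = STRICT
) -> MatchResult:
    """Greedy maximal-overlap one-to-one matching within one note."""
    if mode not in (STRICT, LENIENT):
        raise ValueError(f"unknown mode {mode!r}")
    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if g.label != p.label:
                continue
            if mode == STRICT and (g.start, g.end) != (p.start, p.end):
                continue
            ov = _overlap(g, p)
            if ov < 1:
                continue
            candidates.append((-ov, g.start, p.start, gi, pi))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, _, _, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((gold[gi], pred[pi]))
    fn = [g for i, g in enumerate(gold) if i not in used_g]
    fp = [p for i, p in enumerate(pred) if i not in used_p]
    return MatchResult(tp_pairs=pairs, fp=fp, fn=fn)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class TypeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[2]


@dataclass
class EvalReport:
    mode: str
    per_type: dict[str, TypeCounts] = field(default_factory=dict)

    @property
    def tp(self) -> int:
        return sum(c.tp for c in self.per_type.values())

    @property
    def fp(self) -> int:
        return sum(c.fp for c in self.per_type.values())

    @property
    def fn(self) -> int:
        return sum(c.fn for c in self.per_type.values())

    @property
    def micro_precision(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[0]

    @property
    def micro_recall(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[1]

    @property
    def micro_f1(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[2]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "micro": {
                "tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "per_type": {
                t: {
                    "tp": c.tp, "fp": c.fp, "fn": c.fn,
                    "precision": c.precision, "recall": c.recall, "f1": c.f1,
                }
                for t, c in sorted(self.per_type.items())
            },
        }


def micro_f1(
    gold_by_note: Mapping[str, Sequence[Entity]],
    pred_by_note: Mapping[str, Sequence[Entity]],
    mode: str = STRICT,
) -> EvalReport:
    """Pool TP/FP/FN over all notes and entity types, then compute micro
    precision/recall/F1.  Notes present in only one mapping contribute
    their entities as pure FN (gold-only) or FP (prediction-only)."""
    report = EvalReport(mode=mode)

    def counts(label: str) -> TypeCounts:
        return report.per_type.setdefault(label, TypeCounts())

    for note_id in sorted(set(gold_by_note) | set(pred_by_note)):
        res = match_entities(
            list(gold_by_note.get(note_id, ())),
            list(pred_by_note.get(note_id, ())),
            mode,
        )
        for g, _ in res.tp_pairs:
            counts(g.label).tp += 1
        for p in res.fp:
            counts(p.label).fp += 1
        for g in res.fn:
            counts(g.label).fn += 1
    return report
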