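"""Four-step post-processing of raw LLM generations into weak labels.

1. **Generated-text extraction** — keep the text after the last closing
   dialect token; if the model starts a new instruction block, truncate
   there.
2. **JSON formatting** — pull non-greedy ``{.*?}`` substrings out of the
   generation and parse each one independently, so a single malformed
   object never sinks the sentence.
3. **Entity recovery** — exact, case-sensitive string matching of each
   parsed entity text back into the input sentence, assigning the
   leftmost occurrence not already covered.
4. **Entity type filtering** — discard entities whose type is not in the
   task schema.

Every discarded record is logged with a reason so the weak-label report
can account for all model noise; a sentence counts as *failed* only when
no object parses at all and no empty-list token is present.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Entity, Sentence, TaskSchema
from .prompt_builder import Dialect

__all__ = [
    "DropReason",
    "RawEntityRecord",
    "PostprocessResult",
    "WeakLabelReport",
    "extract_generation",
    "extract_json_objects",
    "recover_spans",
    "filter_types",
    "postprocess_sentence",
    "run_postprocess",
]

# drop-log reasons
NO_JSON = "no_json"
BAD_OBJECT = "bad_object"
TEXT_NOT_FOUND = "text_not_found"
OFF_SCHEMA_TYPE = "off_schema_type"
DUPLICATE = "duplicate"
DropReason = str

_OBJECT_RE = re.compile(r"\{.*?\}", re.DOTALL)
_EMPTY_LIST_RE = re.compile(r"\[\s*\]")


@dataclass(frozen=True)
class RawEntityRecord:
    """One ``{"text": ..., "type": ...}`` object parsed from a generation."""

    text: str
    type: str


@dataclass
class PostprocessResult:
    sentence_id: str
    entities: list[Entity] = field(default_factory=list)
    failed: bool = False
    drop_log: list[tuple[str, DropReason]] = field(default_factory=list)

    def drops(self, reason: DropReason) -> int:
        return sum(1 for _, r in self.drop_log if r == reason)


@dataclass
class WeakLabelReport:
    """Corpus-level weak-label statistics (total entities, failure rate,
    per-sentence and per-note entity-count median and quartiles)."""

    n_notes: int
    n_sentences: int
    failed_sentences: int
    total_entities: int
    per_sentence_quartiles: tuple[float, float, float]  # (Q1, median, Q3)
    per_note_quartiles: tuple[float, float, float]
    drop_counts: dict[DropReason, int]

    @property
    def failed_fraction(self) -> float:
        return self.failed_sentences / self.n_sentences if self.n_sentences else 0.0

    def to_dict(self) -> dict:
        q1s, meds, q3s = self.per_sentence_quartiles
        q1n, medn, q3n = self.per_note_quartiles
        return {
            "n_notes": self.n_notes,
            "n_sentences": self.n_sentences,
            "failed_sentences": self.failed_sentences,
            "failed_sentences_pct": round(100 * self.failed_fraction, 2),
            "total_entities": self.total_entities,
            "entities_per_sentence": {"median": meds, "q1": q1s, "q3": q3s},
            "entities_per_note": {"median": medn, "q1": q1n, "q3": q3n},
            "drop_counts": dict(self.drop_counts),
        }


def extract_generation(
    raw_output: str, dialect: Dialect | None = None, prompt: str | None = None
) -> tuple[str, bool]:
    """Step 1: return ``(generated_text, flagged)``.

    The generation is the substring after the last closing dialect token
    of the prompt region (when *prompt* is given and echoed, everything
    after the echo), truncated at the first newly generated opening
    token.  If no closing token is present at all the whole string is
    treated as the generation and flagged.
    """
    dialect = dialect or Dialect()
    flagged = False
    if prompt is not None and raw_output.startswith(prompt):
        tail = raw_output[len(prompt):]
    else:
        idx = raw_output.rfind(dialect.instruction_close)
        if idx == -1:
            tail, flagged = raw_output, True
        else:
            tail = raw_output[idx + len(dialect.instruction_close):]
    cut = tail.find(dialect.instruction_open)
    if cut != -1:
        tail = tail[:cut]
    return tail, flagged


def extract_json_objects(
    generated_text: str,
) -> tuple[list[RawEntityRecord], list[tuple[str, DropReason]], bool]:
    """Step 2: parse brace-delimited objects; returns (records, drops, failed).

    *failed* is True only when zero objects parse and no ``[]`` token is
    present — an explicit empty list is a successful empty labeling.
    """
    records: list[RawEntityRecord] = []
    drops: list[tuple[str, DropReason]] = []
    for m in _OBJECT_RE.finditer(generated_text):
        chunk = m.group()
        try:
            obj = json.loads(chunk)
        except json.JSONDecodeError:
            drops.append((chunk, BAD_OBJECT))
            continue
        text, etype = obj.get("text"), obj.get("type")
        if not isinstance(text, str) or not text or not isinstance(etype, str):
            drops.append((chunk, BAD_OBJECT))
            continue
        records.append(RawEntityRecord(text=text, type=etype))
    failed = not records and not _EMPTY_LIST_RE.search(generated_text)
    return records, drops, failed


def _occurrences(haystack: str, needle: str) -> Iterable[tuple[int, int]]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1:
            return
        yield idx, idx + len(needle)
        start = idx + 1


def recover_spans(
    records: Sequence[RawEntityRecord], sentence_text: str
) -> tuple[list[Entity], list[tuple[str, DropReason]]]:
    """Step 3: map each record to a character span by exact, case-sensitive
    matching.

    Records are processed in generation order; each takes the leftmost
    occurrence of its text whose span does not overlap an already
    recovered entity, so repeated mentions are consumed left to right.
    A record with no free occurrence is dropped: as ``duplicate`` when a
    prior recovery already holds the same (text, type), otherwise
    ``text_not_found``.
    """
    recovered: list[Entity] = []
    drops: list[tuple[str, DropReason]] = []
    for rec in records:
        span = next(
            (
                (s, e)
                for s, e in _occurrences(sentence_text, rec.text)
                if not any(s < k.end and k.start < e for k in recovered)
            ),
            None,
        )
        if span is None:
            if any(k.text == rec.text and k.label == rec.type for k in recovered):
                drops.append((repr(rec), DUPLICATE))
            else:
                drops.append((repr(rec), TEXT_NOT_FOUND))
            continue
        recovered.append(
            Entity(start=span[0], end=span[1], text=rec.text, label=rec.type)
        )
    return recovered, drops


def filter_types(
    entities: Sequence[Entity], schema: TaskSchema
) -> tuple[list[Entity], list[tuple[str, DropReason]]]:
    """Step 4: keep entities whose label is in the schema (exact string
    equality); off-schema entities are logged and dropped."""
    kept, drops = [], []
    for ent in entities:
        if ent.label in schema:
            kept.append(ent)
        else:
            drops.append((repr(ent), OFF_SCHEMA_TYPE))
    return kept, drops


def postprocess_sentence(
    raw_output: str,
    sentence: Sentence,
    schema: TaskSchema,
    dialect: Dialect | None = None,
    prompt: str | None = None,
) -> PostprocessResult:
    """Apply the four steps to one generation/sentence pair."""
    generated, _flagged = extract_generation(raw_output, dialect, prompt=prompt)
    records, drops, failed = extract_json_objects(generated)
    result = PostprocessResult(sentence_id=sentence.sentence_id)
    result.drop_log.extend(drops)
    if failed:
        result.failed = True
        result.drop_log.append((generated, NO_JSON))
        return result
    entities, span_drops = recover_spans(records, sentence.text)
    result.drop_log.extend(span_drops)
    kept, type_drops = filter_types(entities, schema)
    result.drop_log.extend(type_drops)
    result.entities = sorted(kept)
    return result


def _quartiles(counts: Sequence[int]) -> tuple[float, float, float]:
    if not counts:
        return (0.0, 0.0, 0.0)
    q1, med, q3 = np.percentile(np.asarray(counts, dtype=float), [25, 50, 75])
    return (float(q1), float(med), float(q3))


def run_postprocess(
    generations: Sequence,
    sentences: Sequence[Sentence],
    schema: TaskSchema,
    dialect: Dialect | None = None,
) -> tuple[list[PostprocessResult], WeakLabelReport]:
    """Post-process a full run: one generation per sentence, in order.

    *generations* are :class:`~weakseal.labeler_backend.GenerationRecord`
    objects (or anything with ``raw_output``/``prompt``/``echoes_prompt``).
    Returns per-sentence results plus a corpus-level report.
    """
    if len(generations) != len(sentences):
        raise ValueError(
            f"{len(generations)} generations for {len(sentences)} sentences"
        )
    results = []
    for gen, sent in zip(generations, sentences):
        prompt = gen.prompt if getattr(gen, "echoes_prompt", False) else None
        if getattr(gen, "error", None):
            res = PostprocessResult(sentence_id=sent.sentence_id, failed=True)
            res.drop_log.append((str(gen.error), NO_JSON))
        else:
            res = postprocess_sentence(
                gen.raw_output, sent, schema, dialect, prompt=prompt
            )
        results.append(res)

    per_sentence = [len(r.entities) for r in results]
    by_note: dict[str, int] = {}
    for sent, r in zip(sentences, results):
        by_note[sent.note_id] = by_note.get(sent.note_id, 0) + len(r.entities)
    drop_counts: dict[DropReason, int] = {}
    for r in results:
        for _, reason in r.drop_log:
            drop_counts[reason] = drop_counts.get(reason, 0) + 1
    q1s, meds, q3s = _quartiles(per_sentence)
    q1n, medn, q3n = _quartiles(list(by_note.values()))
    report = WeakLabelReport(
        n_notes=len(by_note),
        n_sentences=len(sentences),
        failed_sentences=sum(r.failed for r in results),
        total_entities=sum(per_sentence),
        per_sentence_quartiles=(q1s, meds, q3s),
        per_note_quartiles=(q1n, medn, q3n),
        drop_counts=drop_counts,
    )
    return results, report


def weak_notes_entities(
    results: Sequence[PostprocessResult], sentences: Sequence[Sentence]
) -> dict[str, list[Entity]]:
    """Lift sentence-relative weak entities back to note-level offsets."""
    out: dict[str, list[Entity]] = {}
    for res, sent in zip(results, sentences):
        out.setdefault(sent.note_id, []).extend(
            ent.shifted(sent.start) for ent in res.entities
        )
    return out
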