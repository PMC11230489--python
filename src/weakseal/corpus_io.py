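"""Corpus I/O: notes, standoff annotations, sentence segmentation, BIO tagging.

Clinical NER corpora are distributed as plain-text notes plus standoff
entity annotations (BRAT ``.ann`` T-lines, or i2b2-style XML handled by
thin adapters).  This module normalizes everything to :class:`Note`
objects with 0-based, half-open character offsets in Unicode code
points, segments notes into sentences for sentence-level prompting, and
converts between character-span entities and token-level BIO tags for
sequence taggers.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Entity",
    "Note",
    "Sentence",
    "TaskSchema",
    "Token",
    "TaggedSequence",
    "StandoffParseError",
    "StandoffValidationError",
    "read_standoff",
    "write_standoff",
    "read_i2b2_xml",
    "load_corpus_jsonl",
    "dump_corpus_jsonl",
    "regex_tokenize",
    "rule_based_boundaries",
    "segment",
    "entities_to_bio",
    "bio_to_entities",
]


class StandoffParseError(ValueError):
    """A standoff annotation line could not be parsed."""


class StandoffValidationError(ValueError):
    """An annotation contradicts the note text (offset/surface mismatch)."""


@dataclass(frozen=True, order=True)
class Entity:
    """A typed text span: ``owning_text[start:end] == text``.

    Offsets are 0-based, half-open, counted in Unicode code points.
    """

    start: int
    end: int
    text: str
    label: str

    def validate(self, owning_text: str, *, ann_id: str = "?") -> None:
        if not (0 <= self.start < self.end <= len(owning_text)):
            raise StandoffValidationError(
                f"{ann_id}: span ({self.start},{self.end}) outside text of "
                f"length {len(owning_text)}"
            )
        surface = owning_text[self.start : self.end]
        if surface != self.text:
            raise StandoffValidationError(
                f"{ann_id}: annotated text {self.text!r} does not match "
                f"note text {surface!r} at ({self.start},{self.end})"
            )
        if not self.label or any(c.isspace() for c in self.label):
            raise StandoffValidationError(
                f"{ann_id}: label {self.label!r} must be a non-empty token "
                "without whitespace"
            )

    def shifted(self, delta: int) -> "Entity":
        return replace(self, start=self.start + delta, end=self.end + delta)


@dataclass
class Note:
    """A full note text with note-level gold entities."""

    note_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)

    def validate(self) -> None:
        for ent in self.entities:
            ent.validate(self.text, ann_id=self.note_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Note):
            return NotImplemented
        return (
            self.note_id == other.note_id
            and self.text == other.text
            and sorted(self.entities) == sorted(other.entities)
        )


@dataclass
class Sentence:
    """One sentence of a note; entity offsets are sentence-relative."""

    note_id: str
    index: int
    start: int
    end: int
    text: str
    entities: list[Entity] = field(default_factory=list)

    @property
    def sentence_id(self) -> str:
        return f"{self.note_id}#{self.index}"


@dataclass(frozen=True)
class TaskSchema:
    """The allowed entity types of a benchmark task."""

    task_name: str
    entity_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.entity_types:
            raise ValueError("schema must declare at least one entity type")
        if len(set(self.entity_types)) != len(self.entity_types):
            raise ValueError("entity types must be unique")

    def __contains__(self, label: str) -> bool:
        return label in self.entity_types


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


@dataclass
class TaggedSequence:
    """Tokens with aligned BIO tags; ``text`` is the owning sentence text."""

    tokens: list[Token]
    tags: list[str]
    text: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tags must align 1:1 with tokens")


# ---------------------------------------------------------------------------
# standoff (BRAT) and JSONL corpus formats
# ---------------------------------------------------------------------------

def _parse_t_line(line: str, lineno: int) -> tuple[str, Entity]:
    # canonical BRAT: "T1\tLabel start end\ttext"; tolerate all-space variants
    parts = line.split("\t")
    if len(parts) == 3:
        ann_id, middle, text = parts
        fields = middle.split()
    else:
        fields = line.split()
        if len(fields) < 5:
            raise StandoffParseError(f"line {lineno}: cannot parse {line!r}")
        ann_id, fields, text = fields[0], fields[1:4], " ".join(fields[4:])
    if len(fields) != 3:
        raise StandoffParseError(f"line {lineno}: expected 'label start end'")
    label, s, e = fields
    try:
        start, end = int(s), int(e)
    except ValueError as exc:
        raise StandoffParseError(f"line {lineno}: non-integer offsets") from exc
    return ann_id, Entity(start=start, end=end, text=text, label=label)


def read_standoff(
    text_path: str | Path,
    ann_path: str | Path,
    schema: TaskSchema | None = None,
) -> Note:
    """Read a note (``.txt``) and its BRAT standoff T-lines (``.ann``).

    Entities whose label is outside *schema* are retained but logged,
    so downstream type filtering stays observable.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    text = text_path.read_text(encoding="utf-8")
    entities: list[Entity] = []
    for lineno, line in enumerate(
        ann_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or not line.startswith("T"):
            continue
        ann_id, ent = _parse_t_line(line, lineno)
        ent.validate(text, ann_id=ann_id)
        if schema is not None and ent.label not in schema:
            logger.warning(
                "%s: entity %s label %r outside schema %s (retained)",
                text_path.stem, ann_id, ent.label, schema.task_name,
            )
        entities.append(ent)
    return Note(note_id=text_path.stem, text=text, entities=entities)


def write_standoff(note: Note, text_path: str | Path, ann_path: str | Path) -> None:
    """Write a note back to BRAT standoff; inverse of :func:`read_standoff`."""
    note.validate()
    Path(text_path).write_text(note.text, encoding="utf-8")
    lines = [
        f"T{i}\t{e.label} {e.start} {e.end}\t{e.text}"
        for i, e in enumerate(note.entities, start=1)
    ]
    Path(ann_path).write_text(
        "".join(line + "\n" for line in lines), encoding="utf-8"
    )


def read_i2b2_xml(xml_path: str | Path, schema: TaskSchema | None = None) -> Note:
    """Adapter for the i2b2 XML dialect: ``<TEXT>`` plus ``<TAGS>`` children
    carrying ``start``/``end``/``text`` attributes and a ``TYPE`` (falling
    back to the element tag name) as the entity label."""
    from lxml import etree

    xml_path = Path(xml_path)
    root = etree.parse(str(xml_path)).getroot()
    text_el = root.find("TEXT")
    if text_el is None or text_el.text is None:
        raise StandoffParseError(f"{xml_path}: missing TEXT element")
    text = text_el.text
    entities: list[Entity] = []
    tags_el = root.find("TAGS")
    if tags_el is not None:
        for el in tags_el:
            attrs = el.attrib
            if "start" not in attrs or "end" not in attrs:
                continue
            ent = Entity(
                start=int(attrs["start"]),
                end=int(attrs["end"]),
                text=attrs.get("text", ""),
                label=attrs.get("TYPE", el.tag),
            )
            ent.validate(text, ann_id=attrs.get("id", el.tag))
            if schema is not None and ent.label not in schema:
                logger.warning(
                    "%s: label %r outside schema (retained)", xml_path.stem, ent.label
                )
            entities.append(ent)
    return Note(note_id=xml_path.stem, text=text, entities=entities)


def dump_corpus_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": note.note_id,
                        "text": note.text,
                        "entities": [
                            {"start": e.start, "end": e.end, "text": e.text,
                             "label": e.label}
                            for e in note.entities
                        ],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def load_corpus_jsonl(path: str | Path) -> list[Note]:
    notes = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            note = Note(
                note_id=obj["note_id"],
                text=obj["text"],
                entities=[Entity(**e) for e in obj["entities"]],
            )
            note.validate()
            notes.append(note)
    return notes


# ---------------------------------------------------------------------------
# tokenization and sentence segmentation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def regex_tokenize(text: str) -> list[Token]:
    """Whitespace + punctuation tokenizer with character offsets."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)|\n+")


def rule_based_boundaries(text: str) -> list[tuple[int, int]]:
    """Default segmenter: split after sentence-final punctuation or newlines,
    then strip flanking whitespace from each span."""
    raw: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        raw.append((start, m.end()))
        start = m.end()
    if start < len(text):
        raw.append((start, len(text)))
    spans = []
    for s, e in raw:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            spans.append((s, e))
    return spans


Segmenter = Callable[[str], Sequence[tuple[int, int]]]


def segment(note: Note, segmenter: Segmenter | None = None) -> list[Sentence]:
    """Segment a note into sentences, assigning entities to the sentence
    containing their start.

    An entity crossing a candidate boundary forces a boundary repair: the
    two sentences are merged so no gold entity is ever split.  A note with
    no boundaries yields a single sentence.
    """
    segmenter = segmenter or rule_based_boundaries
    spans = [tuple(s) for s in segmenter(note.text)]
    if not spans:
        spans = [(0, len(note.text))] if note.text else []
    # repair: merge consecutive spans until every entity is contained in one
    for ent in sorted(note.entities):
        while True:
            idx = next(
                (i for i, (s, e) in enumerate(spans) if s <= ent.start < e), None
            )
            if idx is None:
                # start fell in an inter-sentence gap: widen the next span
                idx = next(
                    (i for i, (s, _) in enumerate(spans) if s > ent.start), None
                )
                if idx is None:
                    raise StandoffValidationError(
                        f"{note.note_id}: entity {ent} outside all sentences"
                    )
                spans[idx] = (ent.start, spans[idx][1])
            s, e = spans[idx]
            if ent.end <= e:
                break
            if idx + 1 < len(spans):
                spans[idx] = (s, spans[idx + 1][1])
                del spans[idx + 1]
            else:
                spans[idx] = (s, ent.end)
    sentences = []
    for i, (s, e) in enumerate(spans):
        ents = [
            ent.shifted(-s) for ent in sorted(note.entities) if s <= ent.start < e
        ]
        sentences.append(
            Sentence(
                note_id=note.note_id, index=i, start=s, end=e,
                text=note.text[s:e], entities=ents,
            )
        )
    return sentences


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------

Tokenizer = Callable[[str], Sequence[Token]]


def _resolve_overlaps(entities: Sequence[Entity]) -> list[Entity]:
    # single-layer BIO cannot express overlap: keep the longer span
    kept: list[Entity] = []
    for ent in sorted(entities, key=lambda e: (-(e.end - e.start), e.start)):
        if any(ent.start < k.end and k.start < ent.end for k in kept):
            logger.info("dropping overlapping entity %s for BIO encoding", ent)
            continue
        kept.append(ent)
    return sorted(kept)


def entities_to_bio(
    sentence: Sentence, tokenizer: Tokenizer | None = None
) -> TaggedSequence:
    """Encode a sentence's entities as token-level BIO tags.

    An entity boundary strictly inside a token is snapped outward to the
    token boundaries (and logged); overlapping entities keep the longer span.
    """
    tokenizer = tokenizer or regex_tokenize
    tokens = list(tokenizer(sentence.text))
    tags = ["O"] * len(tokens)
    for ent in _resolve_overlaps(sentence.entities):
        covered = [
            i for i, t in enumerate(tokens)
            if t.start < ent.end and ent.start < t.end
        ]
        if not covered:
            continue
        first, last = tokens[covered[0]], tokens[covered[-1]]
        if first.start != ent.start or last.end != ent.end:
            logger.info(
                "entity %s snapped to token boundaries (%d,%d)",
                ent, first.start, last.end,
            )
        tags[covered[0]] = f"B-{ent.label}"
        for i in covered[1:]:
            tags[i] = f"I-{ent.label}"
    return TaggedSequence(tokens=tokens, tags=tags, text=sentence.text)


def bio_to_entities(seq: TaggedSequence) -> list[Entity]:
    """Decode BIO tags back to character-span entities.

    An ``I-X`` without a preceding ``B-X``/``I-X`` is repaired to ``B-X``,
    so every non-O token belongs to exactly one decoded entity.
    """
    entities: list[Entity] = []
    run: list[int] = []
    run_label = ""

    def flush() -> None:
        if run:
            first, last = seq.tokens[run[0]], seq.tokens[run[-1]]
            entities.append(
                Entity(
                    start=first.start, end=last.end,
                    text=seq.text[first.start : last.end]
                    if seq.text
                    else " ".join(seq.tokens[i].surface for i in run),
                    label=run_label,
                )
            )

    for i, tag in enumerate(seq.tags):
        if tag == "O":
            flush(); run, run_label = [], ""
        elif tag.startswith("B-") or (
            tag.startswith("I-") and tag[2:] != run_label
        ):
            flush(); run, run_label = [i], tag[2:]
        else:  # valid I- continuation
            run.append(i)
    flush()
    return entities
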