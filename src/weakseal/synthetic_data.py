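"""Synthetic clinical-style corpora and simulated noisy LLM generations.

Real clinical benchmarks are access-restricted, so every pipeline stage
is exercised on generated data: short notes whose sentences are built
from a filler vocabulary with typed entity phrases planted at token
boundaries, plus a noise model that corrupts gold label JSON the way a
generative labeler does — free-text refusals instead of JSON,
hallucinated entity texts, off-schema type names, dropped records and
jittered boundaries.

Entity vocabularies, filler words and hallucination texts are mutually
disjoint (no word of one list is a substring of a phrase in another), so
exact-match span recovery is unambiguous and every injected mutation is
attributable 1:1 to a post-processing drop reason or a surviving wrong
label.  All randomness flows from explicit seeds; per-sentence noise is
seeded by ``(seed, sentence_id)`` so a store is reproducible regardless
of generation order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import Entity, Note, Sentence, TaskSchema, segment
from .labeler_backend import GenerationRecord, GenerationSettings, generate
from .prompt_builder import PromptTemplate, canonical_label_json, render

__all__ = [
    "DEFAULT_SCHEMA",
    "SyntheticCorpusConfig",
    "NoiseConfig",
    "NoiseEvent",
    "CorruptorBackend",
    "generate_corpus",
    "simulate_generations",
]

# word-disjoint vocabularies: no token appears in two lists and no phrase
# is a substring of any sentence built without planting it
DRUG_VOCAB = [
    "aspirin", "heparin", "warfarin", "metformin", "lisinopril",
    "atorvastatin", "insulin", "prednisone", "amoxicillin", "ibuprofen",
    "furosemide", "gabapentin",
]
DOSE_VOCAB = [
    "10mg", "25mg", "50mg", "100mg", "500mg", "81mg", "5ml", "2tabs",
]
SYMPTOM_VOCAB = [
    "chest pain", "shortness breath", "severe nausea", "mild dizziness",
    "acute headache", "dry cough", "leg swelling", "night fevers",
]
FILLER_VOCAB = [
    "patient", "was", "given", "the", "daily", "and", "continued", "on",
    "with", "denies", "reports", "admitted", "for", "history", "of",
    "stable", "today", "morning", "tolerated", "well", "noted", "exam",
    "followup", "plan", "discussed",
]
HALLUCINATION_VOCAB = [
    "zyxovir", "quorline", "blortamab", "fexxidone", "kryptozine",
    "vumeradol",
]
OFF_SCHEMA_TYPES = ["Medication", "Finding", "Anatomy", "Procedure", "Test"]

DEFAULT_SCHEMA = TaskSchema(
    task_name="synthetic-meds",
    entity_types=("Drug", "Dose", "Symptom"),
)

_DEFAULT_VOCABS = {
    "Drug": DRUG_VOCAB,
    "Dose": DOSE_VOCAB,
    "Symptom": SYMPTOM_VOCAB,
}


@dataclass
class SyntheticCorpusConfig:
    """Corpus shape parameters.

    Entities per sentence follow a zero-inflated Poisson: with
    probability ``p_zero`` a sentence carries no entity, otherwise a
    Poisson(``poisson_mean``) count (capped at ``max_entities_per_sentence``),
    which reproduces the low per-sentence medians of clinical concept
    benchmarks.
    """

    n_notes: int = 50
    sentences_per_note: tuple[int, int] = (3, 8)
    entity_types: tuple[str, ...] = DEFAULT_SCHEMA.entity_types
    p_zero: float = 0.25
    poisson_mean: float = 2.5
    max_entities_per_sentence: int = 6
    vocabularies: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_VOCABS.items()}
    )
    filler: list[str] = field(default_factory=lambda: list(FILLER_VOCAB))
    seed: int = 0

    @property
    def schema(self) -> TaskSchema:
        return TaskSchema(task_name="synthetic-meds", entity_types=self.entity_types)


def _poisson(rng: random.Random, mean: float) -> int:
    # inverse-CDF sampling; deterministic for a seeded rng
    import math

    u = rng.random()
    p = math.exp(-mean)
    cum, k = p, 0
    while u > cum and k < 1000:
        k += 1
        p *= mean / k
        cum += p
    return k


def _build_sentence(
    rng: random.Random, config: SyntheticCorpusConfig
) -> tuple[str, list[Entity]]:
    if rng.random() < config.p_zero:
        n_entities = 0
    else:
        n_entities = min(
            max(1, _poisson(rng, config.poisson_mean)),
            config.max_entities_per_sentence,
        )
    words: list[str] = rng.sample(config.filler, rng.randint(1, 3))
    entities: list[Entity] = []
    entity_slots: list[tuple[int, str, str]] = []  # (word index, phrase, label)
    for _ in range(n_entities):
        label = rng.choice(config.entity_types)
        vocab = config.vocabularies.get(label)
        if not vocab:
            raise ValueError(f"empty vocabulary for entity type {label!r}")
        phrase = rng.choice(vocab)
        entity_slots.append((len(words), phrase, label))
        words.append(phrase)
        words.extend(rng.sample(config.filler, rng.randint(1, 2)))
    offset = 0
    starts: dict[int, int] = {}
    for i, w in enumerate(words):
        starts[i] = offset
        offset += len(w) + 1
    text = " ".join(words) + "."
    for idx, phrase, label in entity_slots:
        s = starts[idx]
        entities.append(Entity(start=s, end=s + len(phrase), text=phrase, label=label))
    return text, sorted(entities)


def generate_corpus(config: SyntheticCorpusConfig) -> list[Note]:
    """Generate a seeded, byte-reproducible corpus of synthetic notes with
    planted whole-token entities that never cross sentence boundaries."""
    rng = random.Random(config.seed)
    notes = []
    for i in range(config.n_notes):
        n_sent = rng.randint(*config.sentences_per_note)
        parts: list[str] = []
        entities: list[Entity] = []
        offset = 0
        for _ in range(n_sent):
            text, sent_entities = _build_sentence(rng, config)
            parts.append(text)
            entities.extend(e.shifted(offset) for e in sent_entities)
            offset += len(text) + 1
        note = Note(
            note_id=f"note{i:04d}", text=" ".join(parts), entities=entities
        )
        note.validate()
        notes.append(note)
    return notes


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel corruption probabilities for simulated generations."""

    p_format_corrupt: float = 0.0
    p_hallucinate: float = 0.0
    p_type_swap: float = 0.0
    p_drop: float = 0.0
    p_boundary_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_format_corrupt", "p_hallucinate", "p_type_swap", "p_drop",
            "p_boundary_jitter",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class NoiseEvent:
    """One injected mutation, for 1:1 auditing against drop logs."""

    sentence_id: str
    kind: str  # format_corrupt | drop | hallucinate | type_swap | boundary_jitter
    detail: str


_GARBAGE_TEMPLATES = [
    "I am sorry but I cannot find relevant entities in this sentence",
    "Sure! Here is my analysis of the sentence in plain words",
    "The sentence appears to describe routine care without findings",
]


class CorruptorBackend:
    """Backend that emits gold label JSON corrupted by the noise model.

    Output echoes the full prompt (so generated-text extraction over the
    dialect tokens is exercised) and sometimes appends a spurious new
    instruction block that post-processing must truncate.
    """

    echoes_prompt = True

    def __init__(
        self,
        sentences: Sequence[Sentence],
        template: PromptTemplate,
        noise: NoiseConfig,
    ):
        self.noise = noise
        self.template = template
        self.ledger: list[NoiseEvent] = []
        # consumed in generation order (generate() is 1:1 order-preserving);
        # prompt-keyed lookup would misattribute duplicate sentence texts
        self._queue: list[Sentence] = list(sentences)
        self._pos = 0

    def __call__(self, prompt: str, settings: GenerationSettings) -> str:
        if self._pos >= len(self._queue):
            raise KeyError("more prompts than known sentences")
        sent = self._queue[self._pos]
        if render(self.template, sent.text) != prompt:
            raise KeyError("prompt does not match the next sentence in order")
        self._pos += 1
        rng = random.Random(f"{self.noise.seed}:{sent.sentence_id}")
        d = self.template.dialect
        noise = self.noise
        if rng.random() < noise.p_format_corrupt:
            garbage = rng.choice(_GARBAGE_TEMPLATES)
            self.ledger.append(NoiseEvent(sent.sentence_id, "format_corrupt", garbage))
            return f"{prompt} {garbage}"
        records: list[dict] = []
        for ent in sorted(sent.entities):
            if rng.random() < noise.p_drop:
                self.ledger.append(
                    NoiseEvent(sent.sentence_id, "drop", ent.text)
                )
                continue
            text, etype = ent.text, ent.label
            if rng.random() < noise.p_type_swap:
                etype = rng.choice(OFF_SCHEMA_TYPES)
                self.ledger.append(
                    NoiseEvent(sent.sentence_id, "type_swap", f"{ent.text}->{etype}")
                )
            if rng.random() < noise.p_boundary_jitter:
                text = self._jitter(rng, text)
                self.ledger.append(
                    NoiseEvent(
                        sent.sentence_id, "boundary_jitter", f"{ent.text}->{text}"
                    )
                )
            records.append({"text": text, "type": etype})
        if rng.random() < noise.p_hallucinate:
            fake = {
                "text": rng.choice(HALLUCINATION_VOCAB),
                "type": rng.choice(self._schema_types(sent)),
            }
            records.append(fake)
            self.ledger.append(
                NoiseEvent(sent.sentence_id, "hallucinate", fake["text"])
            )
        import json as _json

        body = _json.dumps(records, separators=(", ", ": "), ensure_ascii=False)
        out = f"{prompt} {body}"
        if rng.random() < 0.5:  # spurious continuation the extractor must cut
            out += f" {d.instruction_open} label the next sentence"
        return out

    def _schema_types(self, sent: Sentence) -> list[str]:
        labels = sorted({e.label for e in sent.entities})
        return labels or ["Drug"]

    @staticmethod
    def _jitter(rng: random.Random, text: str) -> str:
        words = text.split(" ")
        if len(words) > 1 and rng.random() < 0.5:
            return " ".join(words[:-1])  # truncate: prefix may still match
        return text + " " + rng.choice(HALLUCINATION_VOCAB)  # extend: never matches


def simulate_generations(
    notes: Sequence[Note],
    template: PromptTemplate,
    noise: NoiseConfig,
    settings: GenerationSettings | None = None,
) -> tuple[list[GenerationRecord], list[Sentence], list[NoiseEvent]]:
    """Render prompts for every sentence of *notes* and run the corruptor.

    Returns the generation records (aligned 1:1 with the returned
    sentences) and the noise ledger of injected mutations.
    """
    sentences = [s for note in notes for s in segment(note)]
    backend = CorruptorBackend(sentences, template, noise)
    prompts = [render(template, s.text) for s in sentences]
    records = generate(
        backend, prompts, settings, sentence_ids=[s.sentence_id for s in sentences]
    )
    return records, sentences, backend.ledger
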