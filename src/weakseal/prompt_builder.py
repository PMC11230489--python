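"""Prompt and SFT-record construction.

The labeling prompt has four ordered sections: a system prompt that
assigns the model a role, a task instruction, a block of few-shot
examples (sentence plus its gold label JSON), and the input placeholder
the target sentence is substituted into.  The instruction region is
delimited by configurable dialect tokens (default the Llama-2 chat
convention ``[INST]`` / ``[/INST]``); the model's continuation is
collected after the closing token.  Supervised fine-tuning (SFT)
records are the same rendered prompt with the gold label JSON appended
after the closing token, so parsing and training share one canon.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import Entity, Note, Sentence, TaskSchema, segment

__all__ = [
    "Dialect",
    "FewShotExample",
    "PromptTemplate",
    "SFTRecord",
    "canonical_label_json",
    "sample_fewshot",
    "render",
    "build_sft_records",
    "default_template",
]

INPUT_PLACEHOLDER = "{{input}}"


@dataclass(frozen=True)
class Dialect:
    """Special-token strings delimiting the instruction region."""

    instruction_open: str = "[INST]"
    instruction_close: str = "[/INST]"


def canonical_label_json(entities: Sequence[Entity]) -> str:
    """Serialize entities as the canonical label JSON: an array of
    ``{"text": ..., "type": ...}`` objects, keys in that order, compact."""
    return json.dumps(
        [{"text": e.text, "type": e.label} for e in sorted(entities)],
        separators=(", ", ": "),
        ensure_ascii=False,
    )


@dataclass(frozen=True)
class FewShotExample:
    sentence_text: str
    label_json: str

    def validate(self, schema: TaskSchema | None = None) -> None:
        records = json.loads(self.label_json)
        for rec in records:
            if rec["text"] not in self.sentence_text:
                raise ValueError(
                    f"few-shot label text {rec['text']!r} not in sentence"
                )
            if schema is not None and rec["type"] not in schema:
                raise ValueError(f"few-shot type {rec['type']!r} off schema")


_DEFAULT_SYSTEM = (
    "You are a careful clinical annotation assistant that extracts "
    "entities from medical note sentences."
)
_DEFAULT_INSTRUCTION = (
    "Given one sentence from a medical note, list every entity of the "
    "types {types} as a JSON array of objects with keys \"text\" and "
    "\"type\". Output [] if the sentence contains no entity."
)


@dataclass
class PromptTemplate:
    """The 4-section prompt: system, instruction, few-shot, input."""

    system_prompt: str = _DEFAULT_SYSTEM
    instruction: str = _DEFAULT_INSTRUCTION
    fewshot: list[FewShotExample] = field(default_factory=list)
    dialect: Dialect = field(default_factory=Dialect)

    @classmethod
    def for_schema(
        cls, schema: TaskSchema, fewshot: Iterable[FewShotExample] = ()
    ) -> "PromptTemplate":
        return cls(
            instruction=_DEFAULT_INSTRUCTION.format(
                types=", ".join(schema.entity_types)
            ),
            fewshot=list(fewshot),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "system_prompt": self.system_prompt,
                "instruction": self.instruction,
                "fewshot": [
                    {"sentence_text": ex.sentence_text, "label_json": ex.label_json}
                    for ex in self.fewshot
                ],
                "dialect": {
                    "instruction_open": self.dialect.instruction_open,
                    "instruction_close": self.dialect.instruction_close,
                },
            },
            indent=2,
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "PromptTemplate":
        obj = json.loads(text)
        return cls(
            system_prompt=obj["system_prompt"],
            instruction=obj["instruction"],
            fewshot=[FewShotExample(**ex) for ex in obj.get("fewshot", [])],
            dialect=Dialect(**obj.get("dialect", {})),
        )


def default_template(schema: TaskSchema) -> PromptTemplate:
    return PromptTemplate.for_schema(schema)


def sample_fewshot(
    sentences: Sequence[Sentence], k: int, seed: int
) -> list[FewShotExample]:
    """Uniformly sample *k* sentences (without replacement, seeded) as
    few-shot examples; the pool includes entity-free sentences."""
    if k > len(sentences):
        raise ValueError(f"k={k} exceeds {len(sentences)} candidate sentences")
    rng = random.Random(seed)
    chosen = rng.sample(list(sentences), k)
    return [
        FewShotExample(
            sentence_text=s.text, label_json=canonical_label_json(s.entities)
        )
        for s in chosen
    ]


def _render_fewshot_block(template: PromptTemplate) -> str:
    d = template.dialect
    parts = []
    for ex in template.fewshot:
        parts.append(
            f"{d.instruction_open} {ex.sentence_text} "
            f"{d.instruction_close} {ex.label_json}\n"
        )
    return "".join(parts)


def render(template: PromptTemplate, input_sentence: str) -> str:
    """Render the full prompt for one input sentence.

    The result ends at the closing dialect token so generation continues
    immediately after it; the input sentence appears exactly once outside
    the few-shot blocks.
    """
    d = template.dialect
    prompt = (
        f"{template.system_prompt}\n\n"
        f"{template.instruction}\n\n"
        f"{_render_fewshot_block(template)}"
        f"{d.instruction_open} {input_sentence} {d.instruction_close}"
    )
    if INPUT_PLACEHOLDER in prompt:
        raise ValueError("unfilled input placeholder remains in rendered prompt")
    return prompt


@dataclass(frozen=True)
class SFTRecord:
    """A training record: rendered prompt + gold completion.

    ``full_text`` equals ``prompt + completion``; splitting at the last
    closing dialect token recovers the completion exactly.  The
    structured parts are kept so over-length records can shed whole
    few-shot examples without touching the completion.
    """

    sentence_id: str
    prompt: str
    completion: str
    template: PromptTemplate
    sentence_text: str

    @property
    def full_text(self) -> str:
        return self.prompt + self.completion

    def with_fewshot(self, fewshot: list[FewShotExample]) -> "SFTRecord":
        trimmed = PromptTemplate(
            system_prompt=self.template.system_prompt,
            instruction=self.template.instruction,
            fewshot=fewshot,
            dialect=self.template.dialect,
        )
        return SFTRecord(
            sentence_id=self.sentence_id,
            prompt=render(trimmed, self.sentence_text),
            completion=self.completion,
            template=trimmed,
            sentence_text=self.sentence_text,
        )


def build_sft_records(
    gold_notes: Iterable[Note],
    template: PromptTemplate,
    segmenter=None,
) -> list[SFTRecord]:
    """One SFT record per sentence of the gold notes; the completion is the
    canonical label JSON (``[]`` for entity-free sentences), appended after
    the closing dialect token."""
    records = []
    for note in gold_notes:
        for sent in segment(note, segmenter):
            records.append(
                SFTRecord(
                    sentence_id=sent.sentence_id,
                    prompt=render(template, sent.text),
                    completion=" " + canonical_label_json(sent.entities),
                    template=template,
                    sentence_text=sent.text,
                )
            )
    return records
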