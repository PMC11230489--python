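"""Pluggable text-generation backends and SFT dataset export.

A backend is any callable ``(prompt, settings) -> raw_output`` with an
``echoes_prompt`` attribute saying whether its output repeats the prompt
before the continuation.  Shipped backends never need model weights:

* :class:`ReplayBackend` — replays a JSONL store of previous
  generations, keyed by the SHA-256 of the prompt (robust to
  re-ordering); used for byte-exact regression tests.
* :class:`OracleBackend` — returns the gold label JSON for each
  sentence, the noise-free upper bound of the pipeline.
* :class:`EchoBackend` — always answers ``[]``.
* a corruptor backend lives in :mod:`weakseal.synthetic_data`, driven by
  its noise model.

With ``top_k=1`` decoding is greedy, so every backend here is
deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

from .corpus_io import Sentence, regex_tokenize
from .prompt_builder import (
    PromptTemplate,
    SFTRecord,
    canonical_label_json,
    render,
)

__all__ = [
    "GenerationSettings",
    "GenerationRecord",
    "SFTConfig",
    "Backend",
    "ReplayBackend",
    "OracleBackend",
    "EchoBackend",
    "generate",
    "save_generation_store",
    "export_sft_dataset",
]


@dataclass(frozen=True)
class GenerationSettings:
    """Decoding settings: greedy ``top_k=1`` and a 128-token output cap."""

    top_k: int = 1
    max_new_tokens: int = 128


@dataclass
class GenerationRecord:
    sentence_id: str
    prompt: str
    raw_output: str
    settings: GenerationSettings = field(default_factory=GenerationSettings)
    echoes_prompt: bool = False
    error: str | None = None

    @property
    def prompt_sha256(self) -> str:
        return hashlib.sha256(self.prompt.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class SFTConfig:
    """Supervised fine-tuning hyperparameters emitted in the manifest."""

    schedule: str = "cosine"
    initial_lr: float = 2e-5
    weight_decay: float = 0.1
    max_seq_len: int = 4096
    epochs: int = 2
    batch_size: int = 1

    def to_dict(self) -> dict:
        return {
            "schedule": self.schedule,
            "initial_lr": self.initial_lr,
            "weight_decay": self.weight_decay,
            "max_seq_len": self.max_seq_len,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
        }


@runtime_checkable
class Backend(Protocol):
    echoes_prompt: bool

    def __call__(self, prompt: str, settings: GenerationSettings) -> str: ...


class EchoBackend:
    """Always generates an empty label list."""

    echoes_prompt = False

    def __call__(self, prompt: str, settings: GenerationSettings) -> str:
        return " []"


class OracleBackend:
    """Returns the gold label JSON of each sentence: the zero-noise path."""

    echoes_prompt = False

    def __init__(self, answers: dict[str, str]):
        self._answers = answers  # prompt sha256 -> label JSON

    @classmethod
    def from_sentences(
        cls, sentences: Iterable[Sentence], template: PromptTemplate
    ) -> "OracleBackend":
        answers = {}
        for sent in sentences:
            key = hashlib.sha256(
                render(template, sent.text).encode("utf-8")
            ).hexdigest()
            answers[key] = " " + canonical_label_json(sent.entities)
        return cls(answers)

    def __call__(self, prompt: str, settings: GenerationSettings) -> str:
        key = hashlib.sha256(prompt.encode("utf-8")).hexdigest()
        if key not in self._answers:
            raise KeyError(f"no gold answer for prompt {key[:12]}…")
        return self._answers[key]


class ReplayBackend:
    """Replays a stored generation run byte-exactly."""

    echoes_prompt = False

    def __init__(self, store: dict[str, str], echoes_prompt: bool = False):
        self._store = store
        self.echoes_prompt = echoes_prompt

    @classmethod
    def from_jsonl(cls, path: str | Path, echoes_prompt: bool = False) -> "ReplayBackend":
        store = {}
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    obj = json.loads(line)
                    store[obj["prompt_sha256"]] = obj["raw_output"]
        return cls(store, echoes_prompt=echoes_prompt)

    def __call__(self, prompt: str, settings: GenerationSettings) -> str:
        key = hashlib.sha256(prompt.encode("utf-8")).hexdigest()
        if key not in self._store:
            raise KeyError(f"prompt {key[:12]}… not in replay store")
        return self._store[key]


def generate(
    backend: Backend,
    prompts: Sequence[str],
    settings: GenerationSettings | None = None,
    sentence_ids: Sequence[str] | None = None,
) -> list[GenerationRecord]:
    """Run the backend over prompts, order-preserving, one record each.

    A backend failure on one prompt yields a record with the error flag
    set; the run continues and the failure is accounted downstream as a
    failed sentence.
    """
    settings = settings or GenerationSettings()
    if sentence_ids is None:
        sentence_ids = [f"s{i}" for i in range(len(prompts))]
    if len(sentence_ids) != len(prompts):
        raise ValueError("sentence_ids must align with prompts")
    records = []
    for sid, prompt in zip(sentence_ids, prompts):
        try:
            raw = backend(prompt, settings)
            records.append(
                GenerationRecord(
                    sentence_id=sid, prompt=prompt, raw_output=raw,
                    settings=settings,
                    echoes_prompt=getattr(backend, "echoes_prompt", False),
                )
            )
        except Exception as exc:  # failure is data, not an abort
            records.append(
                GenerationRecord(
                    sentence_id=sid, prompt=prompt, raw_output="",
                    settings=settings, error=str(exc),
                )
            )
    return records


def save_generation_store(
    records: Iterable[GenerationRecord], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "sentence_id": rec.sentence_id,
                        "prompt_sha256": rec.prompt_sha256,
                        "raw_output": rec.raw_output,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def _count_tokens(text: str) -> int:
    return len(regex_tokenize(text))


def export_sft_dataset(
    records: Sequence[SFTRecord],
    config: SFTConfig,
    dataset_path: str | Path,
    manifest_path: str | Path,
    token_counter: Callable[[str], int] = _count_tokens,
) -> list[SFTRecord]:
    """Emit a JSONL of SFT ``full_text`` lines plus a trainer manifest.

    Records longer than ``max_seq_len`` tokens shed whole few-shot
    examples from the left of the few-shot block until they fit; the
    completion is never truncated — if a record cannot fit even with an
    empty few-shot block, that is an error.
    """
    fitted = []
    for rec in records:
        while token_counter(rec.full_text) > config.max_seq_len and rec.template.fewshot:
            rec = rec.with_fewshot(rec.template.fewshot[1:])
        if token_counter(rec.full_text) > config.max_seq_len:
            raise ValueError(
                f"record {rec.sentence_id} exceeds max_seq_len even with no "
                "few-shot examples; refusing to truncate the completion"
            )
        fitted.append(rec)
    with Path(dataset_path).open("w", encoding="utf-8") as fh:
        for rec in fitted:
            fh.write(
                json.dumps(
                    {"sentence_id": rec.sentence_id, "text": rec.full_text},
                    ensure_ascii=False,
                )
                + "\n"
            )
    manifest = {"n_records": len(fitted), **config.to_dict()}
    Path(manifest_path).write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return fitted
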