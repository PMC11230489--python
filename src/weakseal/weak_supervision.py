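"""Gold-note selection, weak+gold dataset assembly, two-stage training.

The weak-supervision scheme: of *N* training notes, a small
representative subset of ``n_s`` notes keeps its gold annotations and
the remaining ``N − n_s`` notes contribute machine-generated weak
labels.  A sequence tagger is first fitted on the weak labels, then
fine-tuned — continuing from the stage-1 state — on the gold subset.
The gold subset holds the notes whose entity counts are closest to the
median entity count over all training notes, which makes the few gold
notes representative of typical annotation density:

    S_ns = { note_i : i in top-n_s argmin |#entities_i − median #entities| }

Two reference taggers honor the pluggable interface: a dictionary
memorizer (exact oracle on memorizable corpora) and a greedy perceptron
tagger for noise experiments.  Both train in epochs with validation
checkpointing and an early stop after ``patience`` consecutive
non-improving epochs.
"""

from __future__ import annotations

import copy
import random
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

from .corpus_io import (
    Entity,
    Note,
    Sentence,
    TaggedSequence,
    Token,
    bio_to_entities,
    entities_to_bio,
    regex_tokenize,
    segment,
)
from .evaluation import STRICT, micro_f1

__all__ = [
    "GoldSelection",
    "WSDatasetSpec",
    "TrainConfig",
    "SplitDataset",
    "Tagger",
    "DictionaryTagger",
    "PerceptronTagger",
    "select_gold_notes",
    "assemble_ws_dataset",
    "fit_with_early_stopping",
    "train_two_stage",
    "predict_entities",
]


# ---------------------------------------------------------------------------
# gold-note selection
# ---------------------------------------------------------------------------

@dataclass
class GoldSelection:
    n_s: int
    selected_ids: list[str]
    median_entities: float
    distances: dict[str, float]


def select_gold_notes(
    notes: Sequence[Note],
    n_s: int,
    counts: Mapping[str, int] | None = None,
) -> GoldSelection:
    """Pick the ``n_s`` notes whose entity counts are closest to the median
    count over all notes (even N: mean of the middle two; ties broken by
    ascending note id).

    *counts* overrides the per-note gold entity counts, e.g. with weak
    counts when selecting before annotation exists.
    """
    if n_s < 1:
        raise ValueError("n_s must be at least 1")
    if n_s > len(notes):
        raise ValueError(f"n_s={n_s} exceeds N={len(notes)} notes")
    if counts is None:
        counts = {note.note_id: len(note.entities) for note in notes}
    med = statistics.median([counts[n.note_id] for n in notes])
    distances = {n.note_id: abs(counts[n.note_id] - med) for n in notes}
    ranked = sorted(notes, key=lambda n: (distances[n.note_id], n.note_id))
    return GoldSelection(
        n_s=n_s,
        selected_ids=[n.note_id for n in ranked[:n_s]],
        median_entities=float(med),
        distances=distances,
    )


@dataclass
class WSDatasetSpec:
    """Partition of the N training notes into weak and gold subsets."""

    N: int
    n_s: int
    weak_note_ids: list[str]
    gold_note_ids: list[str]
    split_fraction: float = 0.8

    def __post_init__(self) -> None:
        weak, gold = set(self.weak_note_ids), set(self.gold_note_ids)
        if weak & gold:
            raise ValueError("weak and gold note sets must be disjoint")
        if len(weak) + len(gold) != self.N:
            raise ValueError("weak ∪ gold must cover all N training notes")

    @classmethod
    def from_selection(
        cls, notes: Sequence[Note], selection: GoldSelection,
        split_fraction: float = 0.8,
    ) -> "WSDatasetSpec":
        gold = list(selection.selected_ids)
        weak = [n.note_id for n in notes if n.note_id not in set(gold)]
        return cls(
            N=len(notes), n_s=selection.n_s, weak_note_ids=weak,
            gold_note_ids=gold, split_fraction=split_fraction,
        )


@dataclass
class TrainConfig:
    split_fraction: float = 0.8
    early_stop_patience: int = 8
    checkpoint_metric: str = "micro-F1"
    max_epochs: int = 50
    seed: int = 0


@dataclass
class SplitDataset:
    train: list[TaggedSequence]
    val: list[TaggedSequence]

    def __len__(self) -> int:
        return len(self.train) + len(self.val)


def _split_sentences(
    sequences: list[TaggedSequence], fraction: float, seed: int
) -> SplitDataset:
    idx = list(range(len(sequences)))
    random.Random(seed).shuffle(idx)
    n = len(sequences)
    n_train = int(round(fraction * n))
    if n >= 2:
        n_train = min(max(n_train, 1), n - 1)
    train = [sequences[i] for i in sorted(idx[:n_train])]
    val = [sequences[i] for i in sorted(idx[n_train:])]
    return SplitDataset(train=train, val=val)


def assemble_ws_dataset(
    notes: Sequence[Note],
    spec: WSDatasetSpec,
    weak_labels: Mapping[str, Sequence[Entity]],
    tokenizer=None,
    seed: int = 0,
) -> tuple[SplitDataset, SplitDataset]:
    """Build the two training stages as BIO-encoded sentence datasets.

    Stage 1 uses the weak labels of the ``N − n_s`` weak notes; stage 2
    the gold labels of the ``n_s`` selected notes.  Each stage is split
    80/20 by sentence with a fixed seed.
    """
    by_id = {n.note_id: n for n in notes}
    missing = [nid for nid in spec.weak_note_ids if nid not in weak_labels]
    if missing:
        raise ValueError(f"missing weak labels for notes: {sorted(missing)}")

    def encode(note: Note) -> list[TaggedSequence]:
        return [entities_to_bio(s, tokenizer) for s in segment(note)]

    stage1_seqs: list[TaggedSequence] = []
    for nid in spec.weak_note_ids:
        weak_note = Note(
            note_id=nid, text=by_id[nid].text, entities=list(weak_labels[nid])
        )
        stage1_seqs.extend(encode(weak_note))
    stage2_seqs: list[TaggedSequence] = []
    for nid in spec.gold_note_ids:
        stage2_seqs.extend(encode(by_id[nid]))
    return (
        _split_sentences(stage1_seqs, spec.split_fraction, seed),
        _split_sentences(stage2_seqs, spec.split_fraction, seed + 1),
    )


# ---------------------------------------------------------------------------
# taggers
# ---------------------------------------------------------------------------

@runtime_checkable
class Tagger(Protocol):
    """Epoch-trainable sequence tagger; state persists across stages."""

    def train_epoch(self, sequences: Sequence[TaggedSequence]) -> None: ...

    def predict_tags(self, tokens: Sequence[Token]) -> list[str]: ...

    def get_state(self) -> object: ...

    def set_state(self, state: object) -> None: ...


class DictionaryTagger:
    """Memorizes the majority tag of each token surface; exact on corpora
    where the token→tag mapping is unambiguous."""

    def __init__(self) -> None:
        self.counts: dict[str, dict[str, int]] = {}

    def train_epoch(self, sequences: Sequence[TaggedSequence]) -> None:
        for seq in sequences:
            for tok, tag in zip(seq.tokens, seq.tags):
                self.counts.setdefault(tok.surface, {})
                self.counts[tok.surface][tag] = (
                    self.counts[tok.surface].get(tag, 0) + 1
                )

    def predict_tags(self, tokens: Sequence[Token]) -> list[str]:
        tags = []
        for tok in tokens:
            by_tag = self.counts.get(tok.surface)
            if not by_tag:
                tags.append("O")
            else:
                tags.append(max(sorted(by_tag), key=lambda t: by_tag[t]))
        return tags

    def get_state(self) -> object:
        return copy.deepcopy(self.counts)

    def set_state(self, state: object) -> None:
        self.counts = copy.deepcopy(state)  # type: ignore[arg-type]


def _shape(w: str) -> str:
    if w.isdigit():
        return "d"
    if w.isupper():
        return "U"
    if w[:1].isupper():
        return "T"
    return "x"


class PerceptronTagger:
    """Greedy left-to-right perceptron tagger over sparse lexical features
    (token, suffix, shape, neighbors, previous tag)."""

    def __init__(self, seed: int = 0) -> None:
        self.weights: dict[str, dict[str, float]] = {}
        self.tags: set[str] = {"O"}
        self._rng = random.Random(seed)

    @staticmethod
    def _features(
        tokens: Sequence[Token], i: int, prev_tag: str
    ) -> list[str]:
        w = tokens[i].surface
        prev_w = tokens[i - 1].surface if i > 0 else "<s>"
        next_w = tokens[i + 1].surface if i + 1 < len(tokens) else "</s>"
        return [
            "bias",
            f"w={w.lower()}",
            f"suf3={w.lower()[-3:]}",
            f"shape={_shape(w)}",
            f"prev_w={prev_w.lower()}",
            f"next_w={next_w.lower()}",
            f"prev_tag={prev_tag}",
        ]

    def _score(self, feats: Sequence[str]) -> str:
        scores = {t: 0.0 for t in self.tags}
        for f in feats:
            for t, wgt in self.weights.get(f, {}).items():
                scores[t] = scores.get(t, 0.0) + wgt
        return max(sorted(scores), key=lambda t: scores[t])

    def train_epoch(self, sequences: Sequence[TaggedSequence]) -> None:
        order = list(sequences)
        self._rng.shuffle(order)
        for seq in order:
            self.tags.update(seq.tags)
            prev = "<start>"
            for i in range(len(seq.tokens)):
                feats = self._features(seq.tokens, i, prev)
                pred = self._score(feats)
                gold = seq.tags[i]
                if pred != gold:
                    for f in feats:
                        row = self.weights.setdefault(f, {})
                        row[gold] = row.get(gold, 0.0) + 1.0
                        row[pred] = row.get(pred, 0.0) - 1.0
                prev = pred

    def predict_tags(self, tokens: Sequence[Token]) -> list[str]:
        tags = []
        prev = "<start>"
        for i in range(len(tokens)):
            pred = self._score(self._features(tokens, i, prev))
            tags.append(pred)
            prev = pred
        return tags

    def get_state(self) -> object:
        return (copy.deepcopy(self.weights), set(self.tags))

    def set_state(self, state: object) -> None:
        weights, tags = state  # type: ignore[misc]
        self.weights = copy.deepcopy(weights)
        self.tags = set(tags)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _validation_f1(tagger: Tagger, val: Sequence[TaggedSequence]) -> float:
    if not val:
        return 0.0
    gold = {}
    pred = {}
    for i, seq in enumerate(val):
        gold[str(i)] = bio_to_entities(seq)
        pred[str(i)] = bio_to_entities(
            TaggedSequence(
                tokens=list(seq.tokens),
                tags=tagger.predict_tags(seq.tokens),
                text=seq.text,
            )
        )
    return micro_f1(gold, pred, STRICT).micro_f1


def fit_with_early_stopping(
    tagger: Tagger,
    data: SplitDataset,
    config: TrainConfig,
) -> list[float]:
    """Train in epochs, checkpoint on validation micro-F1, stop after
    ``early_stop_patience`` consecutive non-improving epochs, and restore
    the best checkpoint.  Returns the per-epoch validation scores."""
    best_score = float("-inf")
    best_state = None
    bad = 0
    history: list[float] = []
    for _epoch in range(config.max_epochs):
        tagger.train_epoch(data.train)
        score = _validation_f1(tagger, data.val)
        history.append(score)
        if score > best_score:
            best_score = score
            best_state = tagger.get_state()
            bad = 0
        else:
            bad += 1
        if bad >= config.early_stop_patience:
            break
    if best_state is not None:
        tagger.set_state(best_state)
    return history


def train_two_stage(
    tagger: Tagger,
    stage1: SplitDataset,
    stage2: SplitDataset,
    config: TrainConfig,
) -> tuple[Tagger, dict]:
    """Weak-label fit, then gold fine-tuning continuing from the stage-1
    state; the best validation checkpoint of the final stage is kept."""
    history: dict = {"stage1": [], "stage2": [], "flags": []}
    if len(stage1) > 0:
        history["stage1"] = fit_with_early_stopping(tagger, stage1, config)
    else:
        history["flags"].append("empty_stage1")
    if len(stage2) > 0:
        history["stage2"] = fit_with_early_stopping(tagger, stage2, config)
    else:
        history["flags"].append("empty_stage2")
    return tagger, history


def predict_entities(
    tagger: Tagger, sentences: Sequence[Sentence], tokenizer=None
) -> dict[str, list[Entity]]:
    """Tag sentences and decode to note-level entities by note id."""
    tokenizer = tokenizer or regex_tokenize
    out: dict[str, list[Entity]] = {}
    for sent in sentences:
        tokens = list(tokenizer(sent.text))
        seq = TaggedSequence(
            tokens=tokens, tags=tagger.predict_tags(tokens), text=sent.text
        )
        out.setdefault(sent.note_id, []).extend(
            ent.shifted(sent.start) for ent in bio_to_entities(seq)
        )
    return out
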