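"""Gold-note selection, dataset assembly and two-stage training."""

import itertools
import random
import statistics

import pytest

from weakseal import (
    DictionaryTagger,
    Note,
    PerceptronTagger,
    SyntheticCorpusConfig,
    TrainConfig,
    WSDatasetSpec,
    assemble_ws_dataset,
    default_template,
    generate_corpus,
    micro_f1,
    predict_entities,
    segment,
    select_gold_notes,
    train_two_stage,
)
from weakseal.weak_supervision import (
    SplitDataset,
    fit_with_early_stopping,
)


def _notes_with_counts(counts: dict[str, int]) -> list[Note]:
    notes = []
    for nid, k in counts.items():
        words = []
        entities = []
        offset = 0
        for i in range(k):
            w = "aspirin"
            from weakseal.corpus_io import Entity

            entities.append(Entity(offset, offset + len(w), w, "Drug"))
            words.append(w)
            offset += len(w) + 1
        text = " ".join(words) + "." if words else "empty."
        notes.append(Note(note_id=nid, text=text, entities=entities))
    return notes


class TestSelectGoldNotes:
    def test_single_pick_is_the_median_note(self):
        notes = _notes_with_counts({"a": 2, "b": 5, "c": 7, "d": 9, "e": 100})
        sel = select_gold_notes(notes, 1)
        assert sel.selected_ids == ["c"] and sel.median_entities == 7

    def test_three_picks_bracket_the_median(self):
        notes = _notes_with_counts({"a": 2, "b": 5, "c": 7, "d": 9, "e": 100})
        sel = select_gold_notes(notes, 3)
        assert set(sel.selected_ids) == {"b", "c", "d"}

    def test_ties_broken_by_ascending_note_id(self):
        notes = _notes_with_counts({"b": 4, "a": 4, "d": 4, "c": 4})
        sel = select_gold_notes(notes, 2)
        assert sel.selected_ids == ["a", "b"]

    def test_even_count_median_is_mean_of_middle_two(self):
        notes = _notes_with_counts({"a": 1, "b": 3, "c": 5, "d": 11})
        sel = select_gold_notes(notes, 1)
        assert sel.median_entities == 4.0
        assert sel.selected_ids == ["b"]  # |3-4| = 1 beats |5-4|? tie -> id order

    def test_oversized_ns_raises(self):
        notes = _notes_with_counts({"a": 1})
        with pytest.raises(ValueError):
            select_gold_notes(notes, 2)

    def test_matches_bruteforce_subset_minimization(self):
        """Greedy top-n_s selection attains the exhaustive minimum of
        Σ|count − median| over all size-n_s subsets."""
        rng = random.Random(17)
        for _ in range(50):
            n = rng.randint(2, 10)
            counts = {f"n{i:02d}": rng.randint(0, 30) for i in range(n)}
            notes = _notes_with_counts(counts)
            n_s = rng.randint(1, n)
            med = statistics.median(counts.values())
            best = min(
                sum(abs(counts[i] - med) for i in sub)
                for sub in itertools.combinations(counts, n_s)
            )
            sel = select_gold_notes(notes, n_s)
            achieved = sum(abs(counts[i] - med) for i in sel.selected_ids)
            assert achieved == best


class TestAssemble:
    @pytest.fixture()
    def corpus(self):
        return generate_corpus(SyntheticCorpusConfig(n_notes=5, seed=3))

    def test_stage_note_counts(self, corpus):
        sel = select_gold_notes(corpus, 2)
        spec = WSDatasetSpec.from_selection(corpus, sel)
        assert len(spec.weak_note_ids) == 3 and len(spec.gold_note_ids) == 2
        assert not set(spec.weak_note_ids) & set(spec.gold_note_ids)

    def test_missing_weak_labels_error_lists_ids(self, corpus):
        sel = select_gold_notes(corpus, 2)
        spec = WSDatasetSpec.from_selection(corpus, sel)
        with pytest.raises(ValueError, match=spec.weak_note_ids[0]):
            assemble_ws_dataset(corpus, spec, {})

    def test_split_fractions_within_one_sentence(self, corpus):
        sel = select_gold_notes(corpus, 2)
        spec = WSDatasetSpec.from_selection(corpus, sel)
        weak = {n.note_id: n.entities for n in corpus}
        stage1, stage2 = assemble_ws_dataset(corpus, spec, weak, seed=0)
        for stage, ids in ((stage1, spec.weak_note_ids), (stage2, spec.gold_note_ids)):
            total = sum(len(segment(n)) for n in corpus if n.note_id in set(ids))
            assert len(stage.train) + len(stage.val) == total
            assert abs(len(stage.train) - round(0.8 * total)) <= 1

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError):
            WSDatasetSpec(N=2, n_s=1, weak_note_ids=["a"], gold_note_ids=["a"])


class TestTraining:
    def _two_stage_setup(self, n_notes=30, seed=0, n_s=2):
        corpus = generate_corpus(SyntheticCorpusConfig(n_notes=n_notes, seed=seed))
        sel = select_gold_notes(corpus, n_s)
        spec = WSDatasetSpec.from_selection(corpus, sel)
        weak = {n.note_id: n.entities for n in corpus}  # zero-noise weak labels
        return corpus, assemble_ws_dataset(corpus, spec, weak, seed=seed)

    def test_memorizer_with_oracle_weak_labels_is_perfect(self):
        corpus, (stage1, stage2) = self._two_stage_setup()
        tagger, _ = train_two_stage(
            DictionaryTagger(), stage1, stage2, TrainConfig()
        )
        test = generate_corpus(SyntheticCorpusConfig(n_notes=10, seed=99))
        sents = [s for n in test for s in segment(n)]
        gold = {n.note_id: n.entities for n in test}
        pred = predict_entities(tagger, sents)
        assert micro_f1(gold, pred, "strict").micro_f1 == 1.0

    def test_constant_validation_score_stops_after_patience_plus_one(self):
        corpus, (stage1, _) = self._two_stage_setup()
        history = fit_with_early_stopping(
            DictionaryTagger(), stage1, TrainConfig(early_stop_patience=8)
        )
        assert len(history) == 9
        assert len(set(history)) == 1  # score really was constant

    def test_empty_stage2_runs_stage1_only_with_flag(self):
        corpus, (stage1, _) = self._two_stage_setup()
        _, history = train_two_stage(
            DictionaryTagger(), stage1, SplitDataset([], []), TrainConfig()
        )
        assert "empty_stage2" in history["flags"]
        assert history["stage1"] and not history["stage2"]

    def test_two_stage_equals_all_gold_with_zero_noise_weak(self):
        corpus, (stage1, stage2) = self._two_stage_setup(seed=4)
        two, _ = train_two_stage(DictionaryTagger(), stage1, stage2, TrainConfig())
        all_gold = DictionaryTagger()
        seqs = []
        from weakseal.corpus_io import entities_to_bio

        for note in corpus:
            seqs.extend(entities_to_bio(s) for s in segment(note))
        fit_with_early_stopping(
            all_gold, SplitDataset(seqs, []), TrainConfig(max_epochs=1)
        )
        test = generate_corpus(SyntheticCorpusConfig(n_notes=10, seed=123))
        sents = [s for n in test for s in segment(n)]
        gold = {n.note_id: n.entities for n in test}
        f_two = micro_f1(gold, predict_entities(two, sents), "strict").micro_f1
        f_all = micro_f1(gold, predict_entities(all_gold, sents), "strict").micro_f1
        assert f_two == f_all

    def test_gold_only_memorizer_f1_monotone_in_ns(self):
        """More gold notes never hurt the memorizing tagger (ties allowed)."""
        corpus = generate_corpus(SyntheticCorpusConfig(n_notes=60, seed=21))
        test = generate_corpus(SyntheticCorpusConfig(n_notes=15, seed=22))
        sents = [s for n in test for s in segment(n)]
        gold = {n.note_id: n.entities for n in test}
        scores = []
        for n_s in (3, 5, 10, 50):
            sel = select_gold_notes(corpus, n_s)
            spec = WSDatasetSpec.from_selection(corpus, sel)
            weak = {n.note_id: [] for n in corpus}
            _, stage2 = assemble_ws_dataset(corpus, spec, weak, seed=1)
            tagger = DictionaryTagger()
            fit_with_early_stopping(tagger, stage2, TrainConfig(max_epochs=1))
            scores.append(
                micro_f1(gold, predict_entities(tagger, sents), "strict").micro_f1
            )
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_perceptron_learns_memorizable_corpus(self):
        corpus, (stage1, stage2) = self._two_stage_setup(n_notes=40, seed=8)
        tagger, history = train_two_stage(
            PerceptronTagger(seed=0), stage1, stage2, TrainConfig(seed=0)
        )
        assert max(history["stage1"]) > 0.9
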