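"""Standoff I/O, sentence segmentation and BIO conversion."""

import random

import pytest

from weakseal.corpus_io import (
    Entity,
    Note,
    Sentence,
    StandoffValidationError,
    TaggedSequence,
    Token,
    bio_to_entities,
    entities_to_bio,
    read_standoff,
    regex_tokenize,
    rule_based_boundaries,
    segment,
    write_standoff,
)


def _write_pair(tmp_path, text, ann_lines, stem="note"):
    txt = tmp_path / f"{stem}.txt"
    ann = tmp_path / f"{stem}.ann"
    txt.write_text(text, encoding="utf-8")
    ann.write_text("".join(l + "\n" for l in ann_lines), encoding="utf-8")
    return txt, ann


class TestStandoff:
    def test_reads_validated_entity(self, tmp_path, schema):
        txt, ann = _write_pair(tmp_path, "Took aspirin.", ["T1\tDrug 5 12\taspirin"])
        note = read_standoff(txt, ann, schema)
        assert note.entities == [Entity(5, 12, "aspirin", "Drug")]

    def test_case_mismatch_is_validation_error_naming_annotation(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "Took aspirin.", ["T1\tDrug 5 12\tAspirin"])
        with pytest.raises(StandoffValidationError, match="T1"):
            read_standoff(txt, ann)

    def test_space_separated_dialect_accepted(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "Took aspirin.", ["T1 Drug 5 12 aspirin"])
        note = read_standoff(txt, ann)
        assert note.entities[0].text == "aspirin"

    def test_round_trip_three_entity_fixture(self, tmp_path):
        text = "gave aspirin 81mg for chest pain."
        note = Note(
            note_id="rt",
            text=text,
            entities=[
                Entity(5, 12, "aspirin", "Drug"),
                Entity(13, 17, "81mg", "Dose"),
                Entity(22, 32, "chest pain", "Symptom"),
            ],
        )
        txt, ann = tmp_path / "rt.txt", tmp_path / "rt.ann"
        write_standoff(note, txt, ann)
        assert read_standoff(txt, ann) == note
        # read∘write∘read is stable on the emitted files too
        txt2, ann2 = tmp_path / "rt2.txt", tmp_path / "rt2.ann"
        write_standoff(read_standoff(txt, ann), txt2, ann2)
        assert txt2.read_text() == txt.read_text()
        assert ann2.read_text().replace("rt2", "rt") == ann.read_text()

    def test_round_trip_on_synthetic_corpus(self, tmp_path, small_corpus):
        for note in small_corpus:
            txt = tmp_path / f"{note.note_id}.txt"
            ann = tmp_path / f"{note.note_id}.ann"
            write_standoff(note, txt, ann)
            assert read_standoff(txt, ann) == note

    def test_empty_note_writes_zero_t_lines(self, tmp_path):
        note = Note(note_id="e", text="nothing here.", entities=[])
        txt, ann = tmp_path / "e.txt", tmp_path / "e.ann"
        write_standoff(note, txt, ann)
        assert ann.read_text() == ""


def test_i2b2_xml_adapter_normalizes_to_note(tmp_path):
    from weakseal.corpus_io import read_i2b2_xml

    xml = tmp_path / "doc1.xml"
    xml.write_text(
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        "<deIdi2b2><TEXT>Took aspirin today.</TEXT><TAGS>"
        '<MEDICATION id="P0" start="5" end="12" text="aspirin" TYPE="Drug"/>'
        "</TAGS></deIdi2b2>",
        encoding="utf-8",
    )
    note = read_i2b2_xml(xml)
    assert note.note_id == "doc1"
    assert note.entities == [Entity(5, 12, "aspirin", "Drug")]


class TestSegmentation:
    def test_splits_on_sentence_final_punctuation(self):
        note = Note(note_id="n", text="A. B.")
        assert [s.text for s in segment(note)] == ["A.", "B."]

    def test_offsets_are_sentence_relative(self):
        note = Note(
            note_id="n",
            text="Took aspirin. Gave heparin.",
            entities=[Entity(19, 26, "heparin", "Drug")],
        )
        sents = segment(note)
        assert len(sents) == 2
        assert sents[1].entities == [Entity(5, 12, "heparin", "Drug")]
        # sentence-relative offsets + start reproduce note-level offsets
        ent = sents[1].entities[0]
        assert note.text[ent.start + sents[1].start: ent.end + sents[1].start] == "heparin"

    def test_entity_crossing_boundary_merges_sentences(self):
        text = "Pain since Jan. 3 visit. Stable now."
        note = Note(
            note_id="n", text=text,
            entities=[Entity(11, 17, "Jan. 3", "Dose")],
        )
        sents = segment(note)
        assert any(
            s.start <= 11 and 17 <= s.end and len(s.entities) == 1 for s in sents
        )

    def test_degenerate_note_is_single_sentence(self):
        note = Note(note_id="n", text="no final punctuation at all")
        sents = segment(note)
        assert len(sents) == 1 and sents[0].text == note.text

    def test_conservation_of_text_and_entities(self, small_corpus):
        for note in small_corpus:
            sents = segment(note)
            rebuilt = [note.text[s.start:s.end] for s in sents]
            assert rebuilt == [s.text for s in sents]
            note_spans = sorted(
                (s.start + e.start, s.start + e.end, e.label)
                for s in sents for e in s.entities
            )
            assert note_spans == sorted(
                (e.start, e.end, e.label) for e in note.entities
            )

    def test_pluggable_segmenter(self):
        note = Note(note_id="n", text="one two three")
        sents = segment(note, segmenter=lambda t: [(0, 3), (4, 13)])
        assert [s.text for s in sents] == ["one", "two three"]


class TestBio:
    def test_simple_tagging(self):
        sent = Sentence(
            note_id="n", index=0, start=0, end=12, text="Took aspirin",
            entities=[Entity(5, 12, "aspirin", "Drug")],
        )
        assert entities_to_bio(sent).tags == ["O", "B-Drug"]

    def test_no_entities_all_outside(self):
        sent = Sentence(note_id="n", index=0, start=0, end=8, text="all good")
        assert entities_to_bio(sent).tags == ["O", "O"]

    def test_multi_token_run_decodes_to_one_entity(self):
        seq = TaggedSequence(
            tokens=[Token("aspirin", 0, 7), Token("tablet", 8, 14)],
            tags=["B-Drug", "I-Drug"],
            text="aspirin tablet",
        )
        assert bio_to_entities(seq) == [Entity(0, 14, "aspirin tablet", "Drug")]

    def test_orphan_inside_tag_repaired_to_begin(self):
        seq = TaggedSequence(
            tokens=[Token("aspirin", 0, 7)], tags=["I-Drug"], text="aspirin"
        )
        assert bio_to_entities(seq) == [Entity(0, 7, "aspirin", "Drug")]

    def test_overlapping_gold_keeps_longer_span(self):
        sent = Sentence(
            note_id="n", index=0, start=0, end=14, text="aspirin tablet",
            entities=[
                Entity(0, 7, "aspirin", "Drug"),
                Entity(0, 14, "aspirin tablet", "Drug"),
            ],
        )
        assert entities_to_bio(sent).tags == ["B-Drug", "I-Drug"]

    def test_boundary_inside_token_snaps_outward(self):
        sent = Sentence(
            note_id="n", index=0, start=0, end=12, text="Took aspirin",
            entities=[Entity(5, 10, "aspir", "Drug")],
        )
        seq = entities_to_bio(sent)
        assert seq.tags == ["O", "B-Drug"]
        assert bio_to_entities(seq)[0] == Entity(5, 12, "aspirin", "Drug")

    def test_round_trip_on_random_token_aligned_sentences(self):
        """Token-aligned, non-overlapping entities survive BIO round-trip."""
        rng = random.Random(11)
        words = [f"w{i}" for i in range(30)]
        labels = ["Drug", "Dose", "Symptom"]
        for _ in range(1000):
            n = rng.randint(1, 12)
            text = " ".join(rng.choice(words) for _ in range(n))
            tokens = regex_tokenize(text)
            entities = []
            i = 0
            while i < len(tokens):
                if rng.random() < 0.4:
                    j = min(len(tokens) - 1, i + rng.randint(0, 2))
                    entities.append(
                        Entity(
                            tokens[i].start, tokens[j].end,
                            text[tokens[i].start: tokens[j].end],
                            rng.choice(labels),
                        )
                    )
                    i = j + 1
                else:
                    i += 1
            sent = Sentence(
                note_id="n", index=0, start=0, end=len(text), text=text,
                entities=entities,
            )
            assert bio_to_entities(entities_to_bio(sent)) == sorted(entities)
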