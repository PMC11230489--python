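import pytest

from weakseal import (
    DEFAULT_SCHEMA,
    SyntheticCorpusConfig,
    default_template,
    generate_corpus,
    sample_fewshot,
    segment,
)


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def small_corpus():
    """20 synthetic notes with planted entities, fixed seed."""
    return generate_corpus(SyntheticCorpusConfig(n_notes=20, seed=7))


@pytest.fixture(scope="session")
def corpus_sentences(small_corpus):
    return [s for note in small_corpus for s in segment(note)]


@pytest.fixture(scope="session")
def template(schema, corpus_sentences):
    tmpl = default_template(schema)
    tmpl.fewshot = sample_fewshot(corpus_sentences, 8, seed=42)
    return tmpl
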