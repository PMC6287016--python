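import pytest

from hpbu.config import ModelConfig
from hpbu.repertoire import train
from hpbu.synth import CorpusSpec, NoiseLevels, generate_corpus


@pytest.fixture(scope="session")
def model_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def corpus_no4():
    """Default training corpus: digits 0-9 minus 4, ten exemplars each."""
    return generate_corpus(CorpusSpec(n_per_digit=10, master_seed=0, exclude=(4,)))


@pytest.fixture(scope="session")
def repertoire_no4(corpus_no4, model_config):
    return train(corpus_no4, model_config)


@pytest.fixture(scope="session")
def corpus_all(model_config):
    """Full ten-digit corpus for the production round-trip checks."""
    return generate_corpus(CorpusSpec(n_per_digit=10, master_seed=0))


@pytest.fixture(scope="session")
def repertoire_all(corpus_all, model_config):
    return train(corpus_all, model_config)


@pytest.fixture(scope="session")
def small_repertoire(model_config):
    """Three digits, three exemplars: fast fixture for unit tests."""
    corpus = generate_corpus(
        CorpusSpec(digits=(1, 5, 9), n_per_digit=3, master_seed=7,
                   noise=NoiseLevels(0.02, 0.02, 0.03))
    )
    return train(corpus, model_config)


def digit_of_schema(repertoire, schema_id):
    """Majority source digit of one schema (evaluation helper)."""
    by_id = {s.id: s for s in repertoire.sequences}
    schema = next(c for c in repertoire.schemas if c.id == schema_id)
    digits = [by_id[m].source_digit for m in schema.member_sequence_ids]
    return max(set(digits), key=digits.count)
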