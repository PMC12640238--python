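import pytest

from temporel.backend import OracleBackend
from temporel.context import enumerate_pairs
from temporel.prompts import ExampleBank
from temporel.synth import GenerationConfig, generate_corpus_with_timelines


@pytest.fixture(scope="session")
def corpus200():
    """The 200-document seeded corpus used by corpus-level checks."""
    config = GenerationConfig(n_docs=200, seed=7)
    docs, timelines = generate_corpus_with_timelines(config)
    return docs, timelines


@pytest.fixture(scope="session")
def small_corpus():
    config = GenerationConfig(n_docs=20, seed=11)
    docs, timelines = generate_corpus_with_timelines(config)
    return docs, timelines


@pytest.fixture(scope="session")
def bank_corpus():
    """A separate label-balanced 20-doc corpus curated for prompting examples."""
    mix = {label: 1.0 / 7.0 for label in
           ("BEGINS-AT", "ENDS-AT", "CONTAINS", "OVERLAP",
            "BEFORE-OVERLAP", "BEFORE", "SIMULTANEOUS")}
    config = GenerationConfig(n_docs=20, seed=23, relation_mix=mix)
    docs, timelines = generate_corpus_with_timelines(config)
    return docs, timelines


@pytest.fixture(scope="session")
def bank(bank_corpus) -> ExampleBank:
    docs, _ = bank_corpus
    instances = [inst for doc in docs for inst in enumerate_pairs(doc)]
    return ExampleBank.from_instances(
        instances, per_label=3, none_count=3, provenance="synthetic 20-doc prompting corpus"
    )


@pytest.fixture(scope="session")
def oracle(small_corpus) -> OracleBackend:
    docs, _ = small_corpus
    return OracleBackend.from_documents(docs)
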