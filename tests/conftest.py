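import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emovocab as ev

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_DICT = "\n".join([
    "pattern\tvalence\tfamily\tlemma_group",
    "sad\tnegative\tsadness\tsad",
    "sadly\tnegative\tsadness\tsad",
    "sadness\tnegative\tsadness\tsad",
    "angry\tnegative\tanger\tangry",
    "afraid\tnegative\tfear\tafraid",
    "awful\tnegative\tundifferentiated_negative\tawful",
    "furi*\tnegative\tanger\tfurious",
    "happy\tpositive\tpositive\thappy",
    "happily\tpositive\tpositive\thappy",
    "joy\tpositive\tpositive\tjoy",
]) + "\n"


@pytest.fixture(scope="session")
def lexicon():
    return ev.packaged_lexicon()


@pytest.fixture(scope="session")
def tiny_lexicon():
    return ev.load_lexicon(TINY_DICT, name="tiny")


@pytest.fixture(scope="session")
def function_words():
    return ev.packaged_function_words()


@pytest.fixture(scope="session")
def coverage_vocab():
    return ev.packaged_coverage_vocabulary()


@pytest.fixture(scope="session")
def resources():
    return ev.default_resources()


@pytest.fixture(scope="session")
def sim_documents(lexicon, coverage_vocab):
    """100 random simulated documents with varied latent parameters."""
    pop = ev.PopulationConfig(
        k_neg=(1, 20), k_pos=(1, 20),
        p_emit_neg=0.06, p_emit_pos=0.06,
        verbosity_mean=160.0, verbosity_sd=40.0, verbosity_min=100,
    )
    corpus, _ = ev.generate_corpus(
        pop, lexicon, coverage_vocab, n_authors=100, seed=42)
    return [ev.tokenize(t, d)
            for d, t in zip(corpus.doc_id, corpus.text)]
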