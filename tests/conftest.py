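import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from sudspan import (  # noqa: E402
    CorpusSpec,
    HashingNgramEmbedder,
    PipelineConfig,
    generate_corpus,
    lexicon_map,
    run_pipeline,
)

#: Fixed corpus seed for the reproducible end-to-end checks.
CORPUS_SEED = 11


@pytest.fixture(scope="session")
def lexicons():
    return lexicon_map()


@pytest.fixture(scope="session")
def embedder():
    return HashingNgramEmbedder()


@pytest.fixture(scope="session")
def corpus577():
    """Full-size corpus matching the study's 577-note shape."""
    spec = CorpusSpec(seed=CORPUS_SEED)
    return spec, *generate_corpus(spec)


@pytest.fixture(scope="session")
def small_corpus():
    spec = CorpusSpec(n_notes=60, seed=5)
    return spec, *generate_corpus(spec)


@pytest.fixture(scope="session")
def oracle_run(corpus577):
    _, notes, gold = corpus577
    return run_pipeline(PipelineConfig(backend="oracle"), notes, gold=gold)


@pytest.fixture(scope="session")
def noisy_run(corpus577):
    _, notes, gold = corpus577
    return run_pipeline(PipelineConfig(backend="noisy"), notes, gold=gold)
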