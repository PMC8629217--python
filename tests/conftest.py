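import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radeval import GeneratorConfig, Report, default_lexicon, generate_references

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def random_report(rng: np.random.Generator, vocab, lo=1, hi=10) -> Report:
    n = int(rng.integers(lo, hi + 1))
    return Report(tuple(vocab[int(i)] for i in rng.integers(0, len(vocab), n)))


def random_reports(seed: int, n: int, vocab=("a", "b", "c", "d", "e"), lo=1, hi=10):
    rng = np.random.default_rng(seed)
    return [random_report(rng, vocab, lo, hi) for _ in range(n)]


@pytest.fixture(scope="session")
def synthetic_records():
    return generate_references(GeneratorConfig(n_reports=120, seed=42))
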