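import pytest

from lysotyper import synthetic


@pytest.fixture(scope="session")
def golden():
    """The bundled deterministic 10-genome pipeline case."""
    return synthetic.golden_pipeline_case()


@pytest.fixture(scope="session")
def small_bundle():
    """A small separable fixture shared by search/classifier tests."""
    return synthetic.generate(
        synthetic.FixtureSpec(
            n_temperate=10, n_virulent=10, genome_length=1200,
            n_domains=4, markers_per_temperate=2, leak_rate=0.0, seed=7,
        )
    )
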