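import logging

import pytest

from codonforge import GeneratorConfig, generate_corpus, load_code

logging.getLogger("codonforge").setLevel(logging.ERROR)
logging.getLogger("codonforge.ordination").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def code():
    return load_code(1)


@pytest.fixture(scope="session")
def small_corpus():
    """A small mixed-effects corpus shared across tests (60 genes)."""
    cfg = GeneratorConfig(n_genes=60, seed=42)
    return generate_corpus(cfg)
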