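import pytest

import excessvocab as ev
from excessvocab.synthetic import generate_corpus, injection_config


@pytest.fixture(scope="session")
def small_injection():
    """A modest LLM-injection corpus (2,000 docs/year) with its matrix.

    Shared read-only across tests; 12,000 documents, lambda = 0.15 in the
    final year.
    """
    cfg = injection_config(docs_per_year=2000, seed=5)
    store, truth = generate_corpus(cfg)
    vocab, matrix, counts = ev.build_matrix(store, min_doc_frac=0.0)
    return {
        "config": cfg,
        "store": store,
        "truth": truth,
        "vocab": vocab,
        "matrix": matrix,
        "counts": counts,
        "annotations": ev.synthetic_annotations(cfg),
    }


@pytest.fixture(scope="session")
def country_injection():
    """Two synthetic countries with different adoption rates (0.05 / 0.20)."""
    cfg = injection_config(
        docs_per_year=4000,
        seed=9,
        country_lambdas={"aaland": 0.05, "bbland": 0.20},
    )
    store, truth = generate_corpus(cfg)
    _vocab, matrix, _counts = ev.build_matrix(store, min_doc_frac=0.0)
    return {"config": cfg, "matrix": matrix, "truth": truth}
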