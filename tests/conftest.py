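from __future__ import annotations

import pytest

from agrigraph.config import RunConfig
from agrigraph.corpus import Document, clean_text
from agrigraph.pipeline import build_bundle
from agrigraph.synthetic import GeneratorParams, generate_kg, make_stubs, render_corpus


def make_synthetic_index(seed=3, docs=6, chunk_size=40, overlap=10, **param_kw):
    """Generate a corpus, build its bundle, and hand back all the pieces."""
    params = GeneratorParams(seed=seed, docs=docs, **param_kw)
    kg = generate_kg(params)
    rows = render_corpus(kg, params)
    documents = [Document(i, clean_text(t)) for i, t in rows]
    provider, encoder = make_stubs(kg)
    cfg = RunConfig(chunk_size=chunk_size, overlap=overlap)
    bundle, stats = build_bundle(documents, cfg, provider)
    return kg, bundle, stats, provider, encoder


@pytest.fixture(scope="session")
def synthetic_index():
    """One shared small synthetic corpus with its built index.

    Session-scoped for speed; tests must not mutate the bundle.
    """
    return make_synthetic_index()
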