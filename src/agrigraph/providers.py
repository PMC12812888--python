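"""Provider contracts for the two external model dependencies, plus stubs.

The pipeline needs exactly two model capabilities: text completion
(extraction, summarization, scoring, answering) and text embedding.  Both
are defined here as minimal protocols so that real adapters can be plugged
in, and both ship with deterministic offline implementations:

* :class:`StubCompletionProvider` — a rule table keyed on the prompt
  template id.  Summaries echo their packed context, relevance scores are
  quantized keyword overlap, answers embed their evidence verbatim.  The
  extraction rule is pluggable (the synthetic-corpus module supplies the
  inverse of its sentence templates).  Every call is logged for test
  inspection.
* :class:`HashingEncoder` — hashed bag-of-words embeddings, L2-normalized.

Stub outputs are pure functions of their inputs, which makes every
provider-backed stage exactly reproducible and checkable.
"""

from __future__ import annotations

import math
import re
from hashlib import sha1
from typing import Callable, Protocol

import numpy as np

from agrigraph import prompts
from agrigraph.errors import DataError
from agrigraph.prompts import CompletionRequest

STOPWORDS = frozenset(
    """a an and are as at be by does do for from has have in is it of on or
    s t that the this to was were what which who with""".split()
)

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def keywords(text: str) -> set[str]:
    """Lowercased word tokens minus stopwords."""
    return {w for w in (m.lower() for m in _WORD_RE.findall(text)) if w not in STOPWORDS}


def keyword_overlap(query: str, text: str) -> float:
    """Fraction of the query's keywords present in *text* (0 when none)."""
    kw = keywords(query)
    if not kw:
        return 0.0
    present = {w.lower() for w in _WORD_RE.findall(text)}
    return len(kw & present) / len(kw)


class CompletionProvider(Protocol):
    def complete(self, req: CompletionRequest) -> str: ...


class Encoder(Protocol):
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


ExtractionRule = Callable[[str], str]


def _no_extraction(_: str) -> str:
    return prompts.COMPLETION_DELIM


class StubCompletionProvider:
    """Deterministic rule-based completion provider.

    Parameters
    ----------
    extraction_rule:
        Maps a chunk text to a delimiter-grammar payload; defaults to an
        empty extraction.  The synthetic-corpus module supplies the exact
        inverse of its sentence templates here.
    """

    def __init__(self, extraction_rule: ExtractionRule = _no_extraction):
        self._extract = extraction_rule
        self.calls: list[CompletionRequest] = []

    def complete(self, req: CompletionRequest) -> str:
        self.calls.append(req)
        tid = req.prompt_template_id
        context = prompts.extract_context(req.filled_prompt)
        if tid == prompts.EXTRACT:
            return self._extract(context)
        if not context.strip():
            return ""  # explicit empty-result signal
        if tid in (prompts.ELEMENT_SUMMARY, prompts.LEAF_SUMMARY, prompts.PARENT_SUMMARY):
            # Summaries echo the packed context so content is fully checkable.
            return context
        if tid == prompts.SCORE:
            query = prompts.extract_query(req.filled_prompt)
            return str(min(5, math.floor(5 * keyword_overlap(query, context))))
        if tid == prompts.LOCAL_ANSWER:
            query = prompts.extract_query(req.filled_prompt)
            return f"Answer to: {query}\n{context}"
        if tid == prompts.MAP_ANSWER:
            query = prompts.extract_query(req.filled_prompt)
            return f"Partial answer to: {query}\n{context}"
        if tid == prompts.REDUCE_ANSWER:
            query = prompts.extract_query(req.filled_prompt)
            return f"Final answer to: {query}\n{context}"
        raise DataError(f"unknown prompt template id: {tid}")


class HashingEncoder:
    """Hashed bag-of-words embedding: each token is hashed into one of
    ``dim`` buckets, counts are accumulated and L2-normalized.

    Pure function of the input text: identical strings always map to the
    identical unit vector, and disjoint vocabularies with no bucket
    collisions map to orthogonal vectors.
    """

    def __init__(self, dim: int = 256):
        if dim <= 0:
            raise DataError("embedding dimension must be positive")
        self.dim = dim

    @staticmethod
    def token_bucket(token: str, dim: int) -> int:
        return int.from_bytes(sha1(token.lower().encode()).digest()[:8], "big") % dim

    def embed(self, text: str) -> np.ndarray:
        tokens = _WORD_RE.findall(text)
        if not tokens:
            raise DataError("cannot embed empty text")
        v = np.zeros(self.dim)
        for tok in tokens:
            v[self.token_bucket(tok, self.dim)] += 1.0
        return v / np.linalg.norm(v)
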