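"""Corpus loading, cleaning, grouping and sliding-window chunking.

The input corpus is a UTF-8 CSV with exactly two columns, ``id`` and
``text``.  Rows sharing an ``id`` are concatenated in input order into one
document, which is then tokenized and cut into overlapping windows of
``chunk_size`` tokens with ``overlap`` shared tokens between neighbours
(stride = chunk_size - overlap).  Overlap keeps entities and relations that
straddle a window boundary visible in more than one context.

Two chunk-count notions coexist:

* :func:`chunk` emits windows until the whole token range is covered,
  including a possibly shorter final window, so no trailing text is lost.
* :func:`nominal_chunk_count` is the closed-form count
  ``floor((T - O) / (S - O))``, which silently drops a trailing remainder
  whenever ``(T - O)`` is not divisible by the stride.  It is kept as a
  separate faithful operation; the two agree exactly on divisible lengths.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from hashlib import sha1
from pathlib import Path
from typing import Callable, Iterable, Sequence

from agrigraph.errors import DataError, SchemaError

logger = logging.getLogger(__name__)

Tokenizer = Callable[[str], list[str]]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

#: Default ordered cleaning rules: (pattern, replacement), applied in order.
#: Normalizes full-width CJK punctuation to ASCII and collapses whitespace.
DEFAULT_CLEANING_RULES: tuple[tuple[str, str], ...] = (
    ("，", ","),
    ("。", "."),
    ("：", ":"),
    ("；", ";"),
    ("！", "!"),
    ("？", "?"),
    ("（", "("),
    ("）", ")"),
    ("“", '"'),
    ("”", '"'),
    ("‘", "'"),
    ("’", "'"),
    (r"\s+", " "),
)


def tokenize(text: str) -> list[str]:
    """Split *text* into word and punctuation tokens.

    Deterministic, dependency-free default for the tokenizer contract; any
    ``str -> list[str]`` callable (e.g. a model tokenizer) can replace it.
    """
    return _TOKEN_RE.findall(text)


def detokenize(tokens: Sequence[str]) -> str:
    return " ".join(tokens)


@dataclass(frozen=True)
class Document:
    """One cleaned corpus row (grouping by id happens later)."""

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise DataError("Document.doc_id must be non-empty")
        if not self.text:
            raise DataError("Document.text must be non-empty")


@dataclass(frozen=True)
class GroupedText:
    """All pieces sharing a doc_id, concatenated and tokenized."""

    doc_id: str
    tokens: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class ChunkingConfig:
    """Sliding-window parameters: window of `chunk_size` tokens, `overlap`
    tokens shared between consecutive windows."""

    chunk_size: int = 1200
    overlap: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.chunk_size):
            raise DataError(
                f"require 0 <= overlap < chunk_size, got "
                f"overlap={self.overlap}, chunk_size={self.chunk_size}"
            )

    @property
    def stride(self) -> int:
        return self.chunk_size - self.overlap


@dataclass(frozen=True)
class Chunk:
    """A token window [token_start, token_end) of one grouped document."""

    chunk_id: str
    doc_id: str
    token_start: int
    token_end: int
    text: str


def clean_text(
    raw: str, rules: Iterable[tuple[str, str]] = DEFAULT_CLEANING_RULES
) -> str:
    """Apply the ordered (pattern -> replacement) rule list, then strip.

    Deterministic and idempotent: cleaning an already-clean string is a
    no-op.  Whitespace runs collapse to single spaces via the default rules.
    """
    out = raw
    for pattern, repl in rules:
        out = re.sub(pattern, repl, out)
    return out.strip()


def load_corpus(
    path: str | Path,
    rules: Iterable[tuple[str, str]] = DEFAULT_CLEANING_RULES,
) -> list[Document]:
    """Read an ``id,text`` CSV into cleaned Documents.

    Rows whose text is missing or blank after cleaning are dropped with a
    logged count.  Missing columns raise :class:`SchemaError` naming them.
    """
    path = Path(path)
    rules = tuple(rules)
    docs: list[Document] = []
    dropped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ("id", "text") if c not in header]
        if missing:
            raise SchemaError(f"corpus CSV missing required column(s): {missing}")
        for row in reader:
            doc_id = (row.get("id") or "").strip()
            text = clean_text(row.get("text") or "", rules)
            if not doc_id or not text:
                dropped += 1
                continue
            docs.append(Document(doc_id=doc_id, text=text))
    if dropped:
        logger.warning("load_corpus: dropped %d blank/invalid row(s)", dropped)
    return docs


def group_and_tokenize(
    docs: Sequence[Document], tokenizer: Tokenizer = tokenize
) -> list[GroupedText]:
    """Concatenate pieces per doc_id (input order) and tokenize.

    Grouping treats all text sharing an id as one unit so that chunking
    never splits a record's content across unrelated windows.  Output order
    follows first appearance of each id.
    """
    pieces: dict[str, list[str]] = {}
    for doc in docs:
        pieces.setdefault(doc.doc_id, []).append(doc.text)
    out = []
    for doc_id, texts in pieces.items():
        tokens: list[str] = []
        for t in texts:
            tokens.extend(tokenizer(t))
        out.append(GroupedText(doc_id=doc_id, tokens=tuple(tokens)))
    return out


def _chunk_id(doc_id: str, start: int, end: int) -> str:
    return sha1(f"{doc_id}:{start}:{end}".encode()).hexdigest()[:16]


def chunk(grouped: GroupedText, cfg: ChunkingConfig) -> list[Chunk]:
    """Cut a grouped document into overlapping windows with full coverage.

    Windows start at 0, stride, 2*stride, ...; each spans at most
    ``chunk_size`` tokens; consecutive windows share exactly ``overlap``
    tokens except that the final window may be shorter.  ``T <= chunk_size``
    yields a single window; an empty document yields no chunks.
    """
    T = grouped.length
    if T == 0:
        return []
    chunks: list[Chunk] = []
    start = 0
    while True:
        end = min(start + cfg.chunk_size, T)
        chunks.append(
            Chunk(
                chunk_id=_chunk_id(grouped.doc_id, start, end),
                doc_id=grouped.doc_id,
                token_start=start,
                token_end=end,
                text=detokenize(grouped.tokens[start:end]),
            )
        )
        if end == T:
            return chunks
        start += cfg.stride


def nominal_chunk_count(T: int, cfg: ChunkingConfig) -> int:
    """Closed-form chunk count ``floor((T - O) / (S - O))``.

    Exact as printed; drops a trailing partial window.  ``T < overlap`` is a
    domain error.
    """
    if T < cfg.overlap:
        raise DataError(f"T={T} < overlap={cfg.overlap}: count undefined")
    return (T - cfg.overlap) // cfg.stride
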