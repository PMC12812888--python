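"""Element extraction: chunks -> typed entities and relations -> summaries.

A completion provider is prompted per chunk to emit entity and relation
records in the delimiter grammar (see :mod:`agrigraph.prompts`); the parser
here is tolerant — records missing required fields are quarantined and
counted, never fatal.  Records are then merged across chunks under a
deterministic normalization (case-fold, trim, collapse whitespace, exact
match), relation multiplicity accumulating into the edge weight, and each
element's dispersed descriptions are concatenated in chunk order, truncated
to a token cap, and condensed into one element summary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from agrigraph import prompts
from agrigraph.corpus import Chunk, detokenize, tokenize
from agrigraph.errors import DataError, ProviderError, TruncatedOutputError
from agrigraph.prompts import (
    COMPLETION_DELIM,
    DEFAULT_ENTITY_TYPES,
    RECORD_DELIM,
    TUPLE_DELIM,
)
from agrigraph.providers import CompletionProvider

logger = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical entity-name form: case-folded, trimmed, single-spaced."""
    return _WS_RE.sub(" ", name.strip()).casefold()


@dataclass
class EntityRecord:
    name: str
    entity_type: str
    descriptions: list[str] = field(default_factory=list)
    source_chunks: list[str] = field(default_factory=list)
    summary: str = ""


@dataclass
class RelationRecord:
    head: str
    relation_type: str
    tail: str
    descriptions: list[str] = field(default_factory=list)
    weight: float = 1.0
    source_chunks: list[str] = field(default_factory=list)
    summary: str = ""

    def __post_init__(self) -> None:
        if self.head == self.tail:
            raise DataError(f"self-relation not allowed: {self.head!r}")
        if self.weight < 1:
            raise DataError("relation weight must be >= 1")


def relation_id(head: str, relation_type: str, tail: str) -> str:
    return f"{head}|{relation_type}|{tail}"


@dataclass(frozen=True)
class ElementDescriptions:
    """All description fragments of one entity or relation, in chunk order."""

    element_id: str
    descriptions: tuple[str, ...]


@dataclass(frozen=True)
class SummarizerConfig:
    """`token_cap` bounds the concatenated description text handed to the
    summarizer so it fits a model context window."""

    token_cap: int = 512

    def __post_init__(self) -> None:
        if self.token_cap <= 0:
            raise DataError("token_cap must be positive")


@dataclass(frozen=True)
class ElementSummary:
    element_id: str
    summary_text: str
    fallback: bool = False


@dataclass
class ParseResult:
    entities: list[EntityRecord]
    relations: list[RelationRecord]
    quarantined: list[str] = field(default_factory=list)


def parse_extraction_output(
    text: str, entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
) -> ParseResult:
    """Parse a delimiter-grammar payload into entity/relation records.

    Splits on record / tuple / completion delimiters; tolerant of trailing
    whitespace.  A missing completion delimiter raises
    :class:`TruncatedOutputError`; malformed records are quarantined.
    """
    if COMPLETION_DELIM not in text:
        raise TruncatedOutputError("extraction output missing completion delimiter")
    payload = text.split(COMPLETION_DELIM, 1)[0]
    result = ParseResult([], [])
    valid_types = set(entity_types)
    for raw in payload.split(RECORD_DELIM):
        rec = raw.strip()
        if not rec:
            continue
        fields = [f.strip().strip('"') for f in rec.strip("()").split(TUPLE_DELIM)]
        kind = fields[0].lower()
        if kind == "entity" and len(fields) == 4 and fields[1] and fields[2] in valid_types:
            result.entities.append(
                EntityRecord(name=fields[1], entity_type=fields[2], descriptions=[fields[3]])
            )
        elif kind == "relationship" and len(fields) == 5 and fields[1] and fields[2] and fields[3]:
            head, tail = normalize_name(fields[1]), normalize_name(fields[2])
            if head == tail:
                result.quarantined.append(rec)
                continue
            result.relations.append(
                RelationRecord(head=fields[1], relation_type=fields[3], tail=fields[2], descriptions=[fields[4]])
            )
        else:
            result.quarantined.append(rec)
    if result.quarantined:
        logger.warning("parse_extraction_output: quarantined %d record(s)", len(result.quarantined))
    return result


def extract_elements(
    chunk: Chunk,
    provider: CompletionProvider,
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES,
) -> ParseResult:
    """Run extraction on one chunk and attach provenance.

    Guarantees that every returned relation's endpoints appear in the
    returned entity list; relations violating this are quarantined.
    """
    req = prompts.extraction_prompt(chunk.text, entity_types)
    parsed = parse_extraction_output(provider.complete(req), entity_types)
    for ent in parsed.entities:
        ent.source_chunks = [chunk.chunk_id]
    known = {normalize_name(e.name) for e in parsed.entities}
    kept_relations = []
    for rel in parsed.relations:
        if normalize_name(rel.head) in known and normalize_name(rel.tail) in known:
            rel.source_chunks = [chunk.chunk_id]
            kept_relations.append(rel)
        else:
            parsed.quarantined.append(relation_id(rel.head, rel.relation_type, rel.tail))
    parsed.relations = kept_relations
    return parsed


@dataclass
class AggregationResult:
    entities: list[EntityRecord]
    relations: list[RelationRecord]
    elements: dict[str, ElementDescriptions]


def aggregate_descriptions(
    entities: list[EntityRecord], relations: list[RelationRecord]
) -> AggregationResult:
    """Merge records across chunks under name normalization.

    One record per distinct element; descriptions concatenate in input
    (chunk) order; relation multiplicity accumulates into ``weight``.
    Idempotent: aggregating an already-merged result changes nothing.
    """
    ents: dict[str, EntityRecord] = {}
    for e in entities:
        key = normalize_name(e.name)
        if key not in ents:
            ents[key] = EntityRecord(name=key, entity_type=e.entity_type, summary=e.summary)
        merged = ents[key]
        merged.descriptions.extend(d for d in e.descriptions if d not in merged.descriptions)
        merged.source_chunks.extend(c for c in e.source_chunks if c not in merged.source_chunks)
    rels: dict[tuple[str, str, str], RelationRecord] = {}
    for r in relations:
        key = (normalize_name(r.head), r.relation_type.lower(), normalize_name(r.tail))
        if key not in rels:
            rels[key] = RelationRecord(
                head=key[0], relation_type=key[1], tail=key[2], weight=r.weight, summary=r.summary
            )
        else:
            rels[key].weight += r.weight
        merged_r = rels[key]
        merged_r.descriptions.extend(d for d in r.descriptions if d not in merged_r.descriptions)
        merged_r.source_chunks.extend(c for c in r.source_chunks if c not in merged_r.source_chunks)
    elements: dict[str, ElementDescriptions] = {}
    for key, e in ents.items():
        elements[key] = ElementDescriptions(key, tuple(e.descriptions))
    for key, r in rels.items():
        rid = relation_id(*key)
        elements[rid] = ElementDescriptions(rid, tuple(r.descriptions))
    return AggregationResult(list(ents.values()), list(rels.values()), elements)


def truncate_tokens(text: str, cap: int) -> str:
    toks = tokenize(text)
    return detokenize(toks[:cap]) if len(toks) > cap else text


def summarize_element(
    entry: ElementDescriptions,
    cfg: SummarizerConfig,
    provider: CompletionProvider,
) -> ElementSummary:
    """Condense one element's descriptions: concatenate in order, truncate
    at the token cap, summarize via the provider.

    On provider failure the truncated concatenation itself is used, flagged
    as a fallback.
    """
    if not entry.descriptions:
        raise DataError(f"element {entry.element_id!r} has no descriptions")
    joined = truncate_tokens(" ".join(entry.descriptions), cfg.token_cap)
    req = prompts.element_summary_prompt(joined)
    try:
        return ElementSummary(entry.element_id, provider.complete(req))
    except ProviderError:
        logger.warning("summarize_element: provider failed for %s; using fallback", entry.element_id)
        return ElementSummary(entry.element_id, joined, fallback=True)
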