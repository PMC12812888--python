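"""End-to-end indexing: corpus -> extraction -> graph -> hierarchy -> index.

``run_index`` executes the whole construction pipeline in order and
persists the six-artifact bundle.  Everything is deterministic given the
corpus, the configuration and the providers, so two runs with the same
inputs produce byte-identical bundles (the manifest records the config
hash and seed that guarantee it).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from agrigraph.config import RunConfig
from agrigraph.corpus import (
    Chunk,
    ChunkingConfig,
    Document,
    chunk as cut_chunks,
    group_and_tokenize,
    load_corpus,
)
from agrigraph.errors import DataError
from agrigraph.extraction import (
    SummarizerConfig,
    aggregate_descriptions,
    extract_elements,
    relation_id,
    summarize_element,
)
from agrigraph.graph import build_graph, detect_hierarchy
from agrigraph.index_store import CommunityMeta, IndexBundle, config_hash, write_index
from agrigraph.providers import CompletionProvider
from agrigraph.summaries import ROOT_ID, build_reports

logger = logging.getLogger(__name__)


@dataclass
class IndexStats:
    documents: int = 0
    rows: int = 0
    chunks: int = 0
    entities: int = 0
    relations: int = 0
    quarantined: int = 0
    communities_per_level: list[int] = field(default_factory=list)
    modularity_per_level: list[float] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)


def build_bundle(
    documents: list[Document],
    config: RunConfig,
    provider: CompletionProvider,
) -> tuple[IndexBundle, IndexStats]:
    """Run the construction stages on already-loaded documents."""
    stats = IndexStats(rows=len(documents))
    t0 = time.perf_counter()

    grouped = group_and_tokenize(documents)
    cfg = ChunkingConfig(chunk_size=config.chunk_size, overlap=config.overlap)
    chunks: list[Chunk] = []
    for g in grouped:
        chunks.extend(cut_chunks(g, cfg))
    stats.documents = len(grouped)
    stats.chunks = len(chunks)
    stats.stage_seconds["chunking"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw_entities, raw_relations = [], []
    for ch in chunks:
        parsed = extract_elements(ch, provider, config.entity_types)
        raw_entities.extend(parsed.entities)
        raw_relations.extend(parsed.relations)
        stats.quarantined += len(parsed.quarantined)
    agg = aggregate_descriptions(raw_entities, raw_relations)
    if not agg.entities:
        raise DataError("no entities extracted from the corpus")
    stats.entities = len(agg.entities)
    stats.relations = len(agg.relations)
    stats.stage_seconds["extraction"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summarizer = SummarizerConfig(token_cap=config.token_cap)
    element_summaries: dict[str, str] = {}
    for eid, entry in agg.elements.items():
        element_summaries[eid] = summarize_element(entry, summarizer, provider).summary_text
    for e in agg.entities:
        e.summary = element_summaries.get(e.name, "")
    for r in agg.relations:
        r.summary = element_summaries.get(relation_id(r.head, r.relation_type, r.tail), "")
    stats.stage_seconds["element_summaries"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    g = build_graph(agg.entities, agg.relations)
    hierarchy = detect_hierarchy(
        g, seed=config.seed, resolution=config.resolution, max_levels=config.max_levels
    )
    stats.communities_per_level = [len(p.communities) for p in hierarchy.levels]
    if g.number_of_edges():
        stats.modularity_per_level = hierarchy.modularities(g)
    stats.stage_seconds["communities"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    chunk_map = {c.chunk_id: c for c in chunks}
    entity_map = {e.name: e for e in agg.entities}
    reports = build_reports(
        hierarchy, g, chunk_map, entity_map, agg.relations, element_summaries,
        provider, budget=config.leaf_budget,
    )
    communities = [
        CommunityMeta(cid, p.level, hierarchy.parent_of.get(cid, ""), sorted(members))
        for p in hierarchy.levels
        for cid, members in sorted(p.communities.items())
    ]
    communities.append(
        CommunityMeta(ROOT_ID, hierarchy.n_levels, "", sorted(g.nodes))
    )
    stats.stage_seconds["reports"] = time.perf_counter() - t0

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
        "provider": config.provider,
        "counts": {
            "documents": stats.documents,
            "chunks": stats.chunks,
            "entities": stats.entities,
            "relations": stats.relations,
            "communities_per_level": stats.communities_per_level,
            "quarantined": stats.quarantined,
        },
        "modularity_per_level": stats.modularity_per_level,
    }
    bundle = IndexBundle(
        documents=documents,
        chunks=chunks,
        entities=sorted(agg.entities, key=lambda e: e.name),
        relations=sorted(agg.relations, key=lambda r: (r.head, r.relation_type, r.tail)),
        communities=communities,
        reports=reports,
        manifest=manifest,
    )
    return bundle, stats


def run_index(
    config: RunConfig,
    corpus_path: str | Path,
    out_dir: str | Path,
    provider: CompletionProvider,
) -> tuple[IndexBundle, IndexStats]:
    """Load a corpus CSV, build the bundle, persist the six artifacts."""
    documents = load_corpus(corpus_path)
    bundle, stats = build_bundle(documents, config, provider)
    write_index(bundle, out_dir)
    logger.info(
        "indexed %s: %d docs, %d chunks, %d entities, %d relations, communities %s",
        corpus_path, stats.documents, stats.chunks, stats.entities,
        stats.relations, stats.communities_per_level,
    )
    return bundle, stats
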