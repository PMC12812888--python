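"""Community reports: leaf summaries from chunks + graph, parents from children.

A leaf community's report is generated from everything known about its
members: the text chunks its entities appear in, their element summaries,
and the community's internal graph structure (entities with attributes,
weighted relations).  A higher-level community's report is generated from
its children's summary texts ONLY — no chunks, no element summaries, no
graph structure reach the provider (tests assert this by inspecting
provider calls).  A single root rollup aggregates the top level.

When the packed leaf context exceeds the token budget, items are dropped
in reverse evidence priority — chunk excerpts first, then entities by
ascending degree, then relations by ascending weight — so the
highest-evidence facts survive truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from agrigraph import prompts
from agrigraph.corpus import Chunk, tokenize
from agrigraph.errors import DataError
from agrigraph.extraction import EntityRecord, RelationRecord
from agrigraph.graph import CommunityHierarchy
from agrigraph.providers import CompletionProvider

logger = logging.getLogger(__name__)

ROOT_ID = "__root__"


@dataclass
class CommunityReport:
    community_id: str
    level: int
    summary_text: str
    member_entities: list[str] = field(default_factory=list)
    member_relations: list[tuple[str, str, str, float]] = field(default_factory=list)
    source_chunk_ids: list[str] = field(default_factory=list)
    children: list[str] = field(default_factory=list)
    truncated: bool = False


def _relation_line(head: str, rel: str, tail: str, weight: float) -> str:
    return f"- {head} | {rel} | {tail} (w={weight:g})"


def pack_leaf_context(
    entity_lines: list[str],
    relation_lines: list[str],
    chunk_lines: list[str],
    budget: int,
) -> tuple[str, bool]:
    """Assemble the leaf context, dropping lowest-priority items to fit."""

    def total_tokens() -> int:
        return sum(
            len(tokenize(line))
            for line in entity_lines + relation_lines + chunk_lines
        )

    truncated = False
    for bucket in (chunk_lines, entity_lines, relation_lines):
        while total_tokens() > budget and bucket:
            bucket.pop()
            truncated = True
    text = "\n".join(
        ["ENTITIES:", *entity_lines, "RELATIONS:", *relation_lines, "SOURCES:", *chunk_lines]
    )
    return text, truncated


def summarize_leaf(
    community_id: str,
    members: frozenset[str],
    g: nx.Graph,
    chunks: dict[str, Chunk],
    entities: dict[str, EntityRecord],
    relations: list[RelationRecord],
    element_summaries: dict[str, str],
    provider: CompletionProvider,
    budget: int = 4000,
) -> CommunityReport:
    """Report for one level-0 community from its texts and graph view."""
    degree = dict(g.degree(weight="weight"))
    member_list = sorted(members, key=lambda n: (-degree.get(n, 0.0), n))
    entity_lines = [
        f"- {name} ({entities[name].entity_type}): {element_summaries.get(name, '')}"
        for name in member_list
        if name in entities
    ]
    member_rels = sorted(
        (r for r in relations if r.head in members and r.tail in members),
        key=lambda r: (-r.weight, r.head, r.relation_type, r.tail),
    )
    relation_lines = [_relation_line(r.head, r.relation_type, r.tail, r.weight) for r in member_rels]
    chunk_ids: list[str] = []
    for name in member_list:
        if name in entities:
            for cid in entities[name].source_chunks:
                if cid not in chunk_ids:
                    chunk_ids.append(cid)
    missing = [cid for cid in chunk_ids if cid not in chunks]
    if missing:
        raise DataError(f"community {community_id} cites unknown chunk(s): {missing[:3]}")
    chunk_lines = [f"- [{cid}] {chunks[cid].text}" for cid in chunk_ids]
    context, truncated = pack_leaf_context(entity_lines, relation_lines, chunk_lines, budget)
    if truncated:
        logger.warning("summarize_leaf: context for %s truncated to budget", community_id)
    summary = provider.complete(prompts.leaf_summary_prompt(context))
    return CommunityReport(
        community_id=community_id,
        level=0,
        summary_text=summary,
        member_entities=member_list,
        member_relations=[(r.head, r.relation_type, r.tail, r.weight) for r in member_rels],
        source_chunk_ids=chunk_ids,
        truncated=truncated,
    )


def summarize_parent(
    community_id: str,
    children_reports: list[CommunityReport],
    provider: CompletionProvider,
) -> CommunityReport:
    """Report for a higher-level community from its children's summaries only.

    The provider input contains nothing but the child summary texts; member
    listings are carried forward as provenance metadata, never packed into
    the prompt.
    """
    if not children_reports:
        raise DataError(f"parent community {community_id} has no children")
    levels = {r.level for r in children_reports}
    if len(levels) > 1:
        raise DataError(f"children of {community_id} span levels {sorted(levels)}")
    ordered = sorted(children_reports, key=lambda r: r.community_id)
    context = "\n".join(f"CHILD {r.community_id}:\n{r.summary_text}" for r in ordered)
    summary = provider.complete(prompts.parent_summary_prompt(context))
    member_entities = sorted({e for r in ordered for e in r.member_entities})
    member_relations = sorted({t for r in ordered for t in r.member_relations})
    return CommunityReport(
        community_id=community_id,
        level=levels.pop() + 1,
        summary_text=summary,
        member_entities=member_entities,
        member_relations=member_relations,
        children=[r.community_id for r in ordered],
    )


def build_reports(
    hierarchy: CommunityHierarchy,
    g: nx.Graph,
    chunks: dict[str, Chunk],
    entities: dict[str, EntityRecord],
    relations: list[RelationRecord],
    element_summaries: dict[str, str],
    provider: CompletionProvider,
    budget: int = 4000,
) -> dict[str, CommunityReport]:
    """All community reports for a hierarchy, plus the single root rollup."""
    reports: dict[str, CommunityReport] = {}
    for cid, members in sorted(hierarchy.levels[0].communities.items()):
        reports[cid] = summarize_leaf(
            cid, members, g, chunks, entities, relations, element_summaries, provider, budget
        )
    for partition in hierarchy.levels[1:]:
        for cid in sorted(partition.communities):
            kids = [reports[c] for c in hierarchy.children_of(cid)]
            reports[cid] = summarize_parent(cid, kids, provider)
    top = sorted(hierarchy.levels[-1].communities)
    reports[ROOT_ID] = summarize_parent(ROOT_ID, [reports[c] for c in top], provider)
    reports[ROOT_ID].level = hierarchy.n_levels
    return reports
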