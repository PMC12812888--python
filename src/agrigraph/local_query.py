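"""Entity-centric local querying.

The question is embedded, matched against every entity's vector (built
from the entity name plus its element summary) by exact cosine argmax,
and the best entity's one-hop neighbourhood is expanded.  Everything known
about that entity — its incident relations, neighbour entities, the chunks
that mention it and the summaries of the communities containing it — is
consolidated into a structured table which is the ONLY context the
answering provider sees.  Suited to factual, narrowly scoped questions
("Which pests does X harm?"); a low best-similarity triggers a warning
rather than a refusal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from agrigraph import prompts
from agrigraph.answers import Answer
from agrigraph.errors import DataError
from agrigraph.graph import build_graph
from agrigraph.index_store import IndexBundle
from agrigraph.providers import Encoder
from agrigraph.summaries import ROOT_ID

#: Below this best-match cosine the answer carries a low-confidence warning.
DEFAULT_LOW_SIMILARITY = 0.2


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; scale-invariant, in [-1, 1]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if u.shape != v.shape:
        raise DataError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if nu == 0 or nv == 0:
        raise DataError("cosine undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def embedding_text(name: str, summary: str) -> str:
    """The text an entity is indexed under: its name plus element summary."""
    return f"{name} {summary}".strip()


@dataclass(frozen=True)
class EntityMatch:
    entity_id: str
    similarity: float
    runner_ups: tuple[tuple[str, float], ...] = ()


@dataclass
class LocalContext:
    center: str
    triples: list[tuple[str, str, str, float]]
    chunk_excerpts: list[tuple[str, str]] = field(default_factory=list)
    summary_blocks: list[tuple[str, str]] = field(default_factory=list)
    table: str = ""


def match_entity(
    query: str, bundle: IndexBundle, encoder: Encoder, k: int = 5
) -> EntityMatch:
    """Exact cosine argmax over all entities; ties break to the
    lexicographically smallest entity id."""
    if not bundle.entities:
        raise DataError("cannot match against an empty entity table")
    vq = encoder.embed(query)
    scored = sorted(
        (
            (-cosine(vq, encoder.embed(embedding_text(e.name, e.summary))), e.name)
            for e in bundle.entities
        ),
    )
    best_sim, best = -scored[0][0], scored[0][1]
    runner_ups = tuple((name, -neg) for neg, name in scored[1 : k + 1])
    return EntityMatch(entity_id=best, similarity=best_sim, runner_ups=runner_ups)


def one_hop(g: nx.Graph, center: str) -> list[tuple[str, str, str, float]]:
    """Triples (center, relation, neighbour, weight) for every incident
    edge, ordered by descending weight then neighbour id."""
    if center not in g:
        raise DataError(f"unknown entity: {center}")
    triples = []
    for nbr in g.neighbors(center):
        data = g[center][nbr]
        for rel in sorted(data.get("relation_types", ["related to"])):
            triples.append((center, rel, nbr, float(data.get("weight", 1.0))))
    return sorted(triples, key=lambda t: (-t[3], t[2], t[1]))


def build_context_table(
    center: str,
    triples: list[tuple[str, str, str, float]],
    bundle: IndexBundle,
) -> LocalContext:
    """Consolidate the matched entity's evidence into a structured table.

    Sources are the chunks mentioning the entity plus the summaries of the
    communities whose member list contains it (the root rollup, which
    contains every entity, is excluded).  Sections appear in a fixed order:
    center entity, relations, neighbour entities, sources.
    """
    entities = {e.name: e for e in bundle.entities}
    if center not in entities:
        raise DataError(f"unknown entity: {center}")
    ent = entities[center]
    chunks = {c.chunk_id: c for c in bundle.chunks}
    excerpts = [(cid, chunks[cid].text) for cid in ent.source_chunks]
    blocks = [
        (rep.community_id, rep.summary_text)
        for cid, rep in sorted(bundle.reports.items())
        if cid != ROOT_ID and center in rep.member_entities
    ]
    lines = [f"CENTER ENTITY: {center} ({ent.entity_type})", ent.summary, "RELATIONS:"]
    if triples:
        lines += [f"- ({h}, {r}, {t}) [w={w:g}]" for h, r, t, w in triples]
    else:
        lines += ["- none recorded"]
    lines += ["NEIGHBOR ENTITIES:"]
    for _, _, nbr, _ in triples:
        if nbr in entities:
            lines.append(f"- {nbr} ({entities[nbr].entity_type}): {entities[nbr].summary}")
    lines += ["SOURCES:"]
    lines += [f"- [chunk {cid}] {text}" for cid, text in excerpts]
    lines += [f"- [community {cid}] {text}" for cid, text in blocks]
    return LocalContext(
        center=center,
        triples=triples,
        chunk_excerpts=excerpts,
        summary_blocks=blocks,
        table="\n".join(lines),
    )


def answer_local(
    query: str,
    bundle: IndexBundle,
    encoder: Encoder,
    provider,
    k: int = 5,
    low_similarity: float = DEFAULT_LOW_SIMILARITY,
) -> Answer:
    """Full local pipeline: match -> one-hop expand -> table -> generate."""
    match = match_entity(query, bundle, encoder, k=k)
    g = build_graph(bundle.entities, bundle.relations)
    triples = one_hop(g, match.entity_id)
    context = build_context_table(match.entity_id, triples, bundle)
    text = provider.complete(prompts.local_answer_prompt(context.table, query))
    citations = [cid for cid, _ in context.chunk_excerpts] + [
        cid for cid, _ in context.summary_blocks
    ]
    metadata = {
        "match": match,
        "context": context,
        "low_similarity_warning": match.similarity < low_similarity,
        "no_relations": not triples,
    }
    return Answer(text=text, citations=citations, metadata=metadata)
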