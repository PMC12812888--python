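"""Local (entity-centric) querying: cosine, argmax retrieval, one-hop tables."""

import numpy as np
import pytest

from agrigraph.corpus import Chunk, Document
from agrigraph.errors import DataError
from agrigraph.extraction import EntityRecord, RelationRecord
from agrigraph.graph import build_graph
from agrigraph.index_store import CommunityMeta, IndexBundle
from agrigraph.local_query import (
    answer_local,
    build_context_table,
    cosine,
    embedding_text,
    match_entity,
    one_hop,
)
from agrigraph.providers import HashingEncoder, StubCompletionProvider
from agrigraph.summaries import CommunityReport


class TestCosine:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cosine(x, x) == pytest.approx(1.0)

    def test_orthogonal_basis_vectors(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_scale_invariance(self):
        x = np.array([0.3, -1.2, 4.0])
        assert cosine(x, 3 * x) == pytest.approx(1.0)

    def test_zero_vector_is_domain_error(self):
        with pytest.raises(DataError):
            cosine(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DataError):
            cosine(np.ones(2), np.ones(3))


def tiny_bundle() -> IndexBundle:
    ents = [
        EntityRecord("alpha blast", "Diseases", [], ["c1"], "alpha blast infects rice"),
        EntityRecord("rice", "Crops", [], ["c1"], "rice is a staple"),
        EntityRecord("solo", "Crops", [], ["c2"], "solo crop note"),
    ]
    rels = [RelationRecord("alpha blast", "infects", "rice", weight=2.0)]
    chunks = [
        Chunk("c1", "d1", 0, 5, "alpha blast infects rice ."),
        Chunk("c2", "d1", 5, 9, "solo crop note ."),
    ]
    reports = {
        "c0_0": CommunityReport("c0_0", 0, "blast community digest",
                                ["alpha blast", "rice"], [], ["c1"]),
        "c0_1": CommunityReport("c0_1", 0, "solo digest", ["solo"], [], ["c2"]),
    }
    return IndexBundle(
        documents=[Document("d1", "alpha blast infects rice . solo crop note .")],
        chunks=chunks,
        entities=ents,
        relations=rels,
        communities=[
            CommunityMeta("c0_0", 0, "", ["alpha blast", "rice"]),
            CommunityMeta("c0_1", 0, "", ["solo"]),
        ],
        reports=reports,
    )


class TestMatchEntity:
    def test_exact_indexed_text_matches_with_similarity_one(self):
        bundle = tiny_bundle()
        enc = HashingEncoder(dim=128)
        e = bundle.entities[0]
        m = match_entity(embedding_text(e.name, e.summary), bundle, enc)
        assert m.entity_id == "alpha blast"
        assert m.similarity == pytest.approx(1.0)

    def test_argmax_equals_brute_force_on_synthetic_queries(self, synthetic_index):
        kg, bundle, _, _, enc = synthetic_index
        for query in list(kg.entities)[:8]:
            vq = enc.embed(query)
            brute_best = max(
                cosine(vq, enc.embed(embedding_text(e.name, e.summary)))
                for e in bundle.entities
            )
            m = match_entity(query, bundle, enc)
            assert m.similarity == pytest.approx(brute_best)
            assert m.entity_id == min(
                e.name for e in bundle.entities
                if cosine(vq, enc.embed(embedding_text(e.name, e.summary)))
                == pytest.approx(brute_best)
            )

    def test_tie_breaks_to_lexicographically_smaller_id(self):
        # bag-of-words hashing ignores token order, so "pest one" and
        # "one pest" with equal summaries embed identically
        bundle = tiny_bundle()
        bundle.entities.append(EntityRecord("pest one", "Crops", [], ["c1"], "twin text"))
        bundle.entities.append(EntityRecord("one pest", "Crops", [], ["c1"], "twin text"))
        m = match_entity("one pest twin text", bundle, HashingEncoder(dim=128))
        assert m.entity_id == "one pest"

    def test_runner_ups_sorted_descending(self, synthetic_index):
        _, bundle, _, _, enc = synthetic_index
        m = match_entity("rice wheat maize", bundle, enc, k=4)
        sims = [s for _, s in m.runner_ups]
        assert sims == sorted(sims, reverse=True)
        assert all(m.similarity >= s for s in sims)

    def test_empty_entity_table_is_error(self):
        bundle = tiny_bundle()
        bundle.entities = []
        with pytest.raises(DataError):
            match_entity("q", bundle, HashingEncoder())


class TestOneHop:
    def test_star_center_emits_all_incident_edges(self):
        ents = [EntityRecord(n, "Crops") for n in ("hub", "x", "y", "z")]
        rels = [
            RelationRecord("hub", "r", "x", weight=1.0),
            RelationRecord("hub", "r", "y", weight=3.0),
            RelationRecord("hub", "r", "z", weight=2.0),
        ]
        g = build_graph(ents, rels)
        triples = one_hop(g, "hub")
        assert [t[2] for t in triples] == ["y", "z", "x"]  # descending weight
        assert all(t[0] == "hub" for t in triples)

    def test_isolated_node_has_no_triples(self):
        g = build_graph([EntityRecord("iso", "Crops")], [])
        assert one_hop(g, "iso") == []

    def test_unknown_entity_rejected(self):
        g = build_graph([EntityRecord("a", "Crops")], [])
        with pytest.raises(DataError):
            one_hop(g, "ghost")


class TestContextTable:
    def test_sections_and_sources(self):
        bundle = tiny_bundle()
        g = build_graph(bundle.entities, bundle.relations)
        ctx = build_context_table("alpha blast", one_hop(g, "alpha blast"), bundle)
        assert ctx.chunk_excerpts == [("c1", "alpha blast infects rice .")]
        assert ctx.summary_blocks == [("c0_0", "blast community digest")]
        for section in ("CENTER ENTITY:", "RELATIONS:", "NEIGHBOR ENTITIES:", "SOURCES:"):
            assert section in ctx.table

    def test_degree_zero_entity_has_empty_relations_but_sources(self):
        bundle = tiny_bundle()
        g = build_graph(bundle.entities, bundle.relations)
        ctx = build_context_table("solo", one_hop(g, "solo"), bundle)
        assert ctx.triples == [] and "- none recorded" in ctx.table
        assert ctx.chunk_excerpts and ctx.summary_blocks


class TestAnswerLocal:
    def test_hub_answer_covers_all_planted_neighbors(self, synthetic_index):
        kg, bundle, _, provider, enc = synthetic_index
        degree = {}
        for h, _, t in kg.triples:
            degree[h] = degree.get(h, 0) + 1
            degree[t] = degree.get(t, 0) + 1
        hub = max(sorted(degree), key=degree.get)
        ans = answer_local(f"what affects {hub} ?", bundle, enc, provider)
        assert ans.metadata["match"].entity_id == hub
        neighbors = {t if h == hub else h for h, _, t in kg.triples if hub in (h, t)}
        for n in neighbors:
            assert n in ans.text

    def test_citations_stay_local_to_the_matched_entity(self, synthetic_index):
        kg, bundle, _, provider, enc = synthetic_index
        entity = bundle.entities[0]
        ans = answer_local(entity.name, bundle, enc, provider)
        center = ans.metadata["match"].entity_id
        ent = next(e for e in bundle.entities if e.name == center)
        allowed = set(ent.source_chunks) | {
            cid for cid, rep in bundle.reports.items() if center in rep.member_entities
        }
        assert set(ans.citations) <= allowed

    def test_isolated_entity_answer_flags_missing_relations(self):
        bundle = tiny_bundle()
        ans = answer_local("solo crop note", bundle, HashingEncoder(dim=128), StubCompletionProvider())
        assert ans.metadata["match"].entity_id == "solo"
        assert ans.metadata["no_relations"] and "- none recorded" in ans.text

    def test_repeated_query_is_deterministic(self, synthetic_index):
        _, bundle, _, provider, enc = synthetic_index
        q = "which pests harm rice ?"
        a1 = answer_local(q, bundle, enc, provider)
        a2 = answer_local(q, bundle, enc, provider)
        assert a1.text == a2.text and a1.citations == a2.citations
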