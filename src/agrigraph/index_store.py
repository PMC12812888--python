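"""Persist and reload the six-artifact index bundle.

On-disk layout (all plain text, diff-able, byte-stable across rewrites):

========================  =====================================================
file                      contents
========================  =====================================================
documents.csv             raw units: ``doc_id,text``
chunks.csv                text-chunk units with token offsets
entities.csv              entity table (type, descriptions, sources, summary)
relations.csv             relation table (head, type, tail, weight, ...)
communities.csv           community metadata (id, level, parent, members)
community_reports.jsonl   one report object per line, sorted by id
manifest.json             format version, config, seeds, counts, modularity
========================  =====================================================

List-valued cells are JSON-encoded inside the CSV.  Every cross-reference
(chunk -> document, entity -> chunk, relation -> entity, community ->
entity, report -> chunk/child) is checked before writing and a dangling id
is reported by name.  ``read_index(write_index(b)) == b`` exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

from agrigraph.corpus import Chunk, Document
from agrigraph.errors import DataError, IntegrityError
from agrigraph.extraction import EntityRecord, RelationRecord
from agrigraph.summaries import ROOT_ID, CommunityReport

FORMAT_VERSION = "1"

ARTIFACTS = (
    "documents.csv",
    "chunks.csv",
    "entities.csv",
    "relations.csv",
    "communities.csv",
    "community_reports.jsonl",
)


@dataclass
class CommunityMeta:
    community_id: str
    level: int
    parent: str  # "" at the top
    members: list[str]


@dataclass
class IndexBundle:
    documents: list[Document]
    chunks: list[Chunk]
    entities: list[EntityRecord]
    relations: list[RelationRecord]
    communities: list[CommunityMeta]
    reports: dict[str, CommunityReport]
    manifest: dict = field(default_factory=dict)


def config_hash(config: dict) -> str:
    return sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def check_integrity(bundle: IndexBundle) -> None:
    """Raise :class:`IntegrityError` naming the first dangling reference."""
    doc_ids = {d.doc_id for d in bundle.documents}
    chunk_ids = {c.chunk_id for c in bundle.chunks}
    entity_ids = {e.name for e in bundle.entities}
    community_ids = {c.community_id for c in bundle.communities}
    for c in bundle.chunks:
        if c.doc_id not in doc_ids:
            raise IntegrityError(f"chunk {c.chunk_id} references unknown document {c.doc_id}", c.doc_id)
    for e in bundle.entities:
        for cid in e.source_chunks:
            if cid not in chunk_ids:
                raise IntegrityError(f"entity {e.name} references unknown chunk {cid}", cid)
    for r in bundle.relations:
        for endpoint in (r.head, r.tail):
            if endpoint not in entity_ids:
                raise IntegrityError(f"relation references unknown entity {endpoint}", endpoint)
        for cid in r.source_chunks:
            if cid not in chunk_ids:
                raise IntegrityError(f"relation {r.head}|{r.tail} references unknown chunk {cid}", cid)
    for cm in bundle.communities:
        for m in cm.members:
            if m not in entity_ids:
                raise IntegrityError(f"community {cm.community_id} references unknown entity {m}", m)
        if cm.parent and cm.parent not in community_ids:
            raise IntegrityError(f"community {cm.community_id} references unknown parent {cm.parent}", cm.parent)
    for rep in bundle.reports.values():
        for cid in rep.source_chunk_ids:
            if cid not in chunk_ids:
                raise IntegrityError(f"report {rep.community_id} references unknown chunk {cid}", cid)
        for child in rep.children:
            if child not in bundle.reports:
                raise IntegrityError(f"report {rep.community_id} references unknown child {child}", child)


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _read_csv(path: Path) -> list[dict[str, str]]:
    if not path.exists():
        raise DataError(f"missing index artifact: {path.name}")
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def write_index(bundle: IndexBundle, out_dir: str | Path) -> list[Path]:
    """Write the six artifacts plus manifest; returns the file list.

    Deterministic: rewriting an identical bundle is byte-identical.
    """
    check_integrity(bundle)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(out / "documents.csv", ["doc_id", "text"], [[d.doc_id, d.text] for d in bundle.documents])
    _write_csv(
        out / "chunks.csv",
        ["chunk_id", "doc_id", "token_start", "token_end", "text"],
        [[c.chunk_id, c.doc_id, c.token_start, c.token_end, c.text] for c in bundle.chunks],
    )
    _write_csv(
        out / "entities.csv",
        ["name", "entity_type", "descriptions", "source_chunks", "summary"],
        [
            [e.name, e.entity_type, json.dumps(e.descriptions), json.dumps(e.source_chunks), e.summary]
            for e in bundle.entities
        ],
    )
    _write_csv(
        out / "relations.csv",
        ["head", "relation_type", "tail", "weight", "descriptions", "source_chunks", "summary"],
        [
            [r.head, r.relation_type, r.tail, repr(r.weight), json.dumps(r.descriptions),
             json.dumps(r.source_chunks), r.summary]
            for r in bundle.relations
        ],
    )
    _write_csv(
        out / "communities.csv",
        ["community_id", "level", "parent", "members"],
        [[c.community_id, c.level, c.parent, json.dumps(c.members)] for c in bundle.communities],
    )
    with open(out / "community_reports.jsonl", "w", encoding="utf-8") as fh:
        for cid in sorted(bundle.reports):
            rep = bundle.reports[cid]
            fh.write(
                json.dumps(
                    {
                        "community_id": rep.community_id,
                        "level": rep.level,
                        "summary_text": rep.summary_text,
                        "member_entities": rep.member_entities,
                        "member_relations": [list(t) for t in rep.member_relations],
                        "source_chunk_ids": rep.source_chunk_ids,
                        "children": rep.children,
                        "truncated": rep.truncated,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    manifest = dict(bundle.manifest)
    manifest["format_version"] = FORMAT_VERSION
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return [out / name for name in (*ARTIFACTS, "manifest.json")]


def read_index(in_dir: str | Path) -> IndexBundle:
    """Reload a bundle; full round-trip equality with what was written."""
    d = Path(in_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise DataError("missing index artifact: manifest.json")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    version = manifest.pop("format_version", None)
    if version != FORMAT_VERSION:
        raise DataError(
            f"index format version {version!r} is not supported (expected {FORMAT_VERSION}); re-index required"
        )
    documents = [Document(r["doc_id"], r["text"]) for r in _read_csv(d / "documents.csv")]
    chunks = [
        Chunk(r["chunk_id"], r["doc_id"], int(r["token_start"]), int(r["token_end"]), r["text"])
        for r in _read_csv(d / "chunks.csv")
    ]
    entities = [
        EntityRecord(
            name=r["name"],
            entity_type=r["entity_type"],
            descriptions=json.loads(r["descriptions"]),
            source_chunks=json.loads(r["source_chunks"]),
            summary=r["summary"],
        )
        for r in _read_csv(d / "entities.csv")
    ]
    relations = [
        RelationRecord(
            head=r["head"],
            relation_type=r["relation_type"],
            tail=r["tail"],
            weight=float(r["weight"]),
            descriptions=json.loads(r["descriptions"]),
            source_chunks=json.loads(r["source_chunks"]),
            summary=r["summary"],
        )
        for r in _read_csv(d / "relations.csv")
    ]
    communities = [
        CommunityMeta(r["community_id"], int(r["level"]), r["parent"], json.loads(r["members"]))
        for r in _read_csv(d / "communities.csv")
    ]
    reports_path = d / "community_reports.jsonl"
    if not reports_path.exists():
        raise DataError("missing index artifact: community_reports.jsonl")
    reports: dict[str, CommunityReport] = {}
    with open(reports_path, encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            reports[obj["community_id"]] = CommunityReport(
                community_id=obj["community_id"],
                level=obj["level"],
                summary_text=obj["summary_text"],
                member_entities=obj["member_entities"],
                member_relations=[tuple(t) for t in obj["member_relations"]],
                source_chunk_ids=obj["source_chunk_ids"],
                children=obj["children"],
                truncated=obj["truncated"],
            )
    bundle = IndexBundle(documents, chunks, entities, relations, communities, reports, manifest)
    check_integrity(bundle)
    return bundle


__all__ = [
    "ARTIFACTS",
    "CommunityMeta",
    "IndexBundle",
    "ROOT_ID",
    "check_integrity",
    "config_hash",
    "read_index",
    "write_index",
]
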