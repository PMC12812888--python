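"""Synthetic crop/pest/disease corpora with known ground truth.

The generator builds a toy knowledge graph over the six entity types
(crops, diseases, insect pests, symptoms, control measures, pathogens),
realizes every triple as one or more templated declarative sentences
("crimson blast infects rice ."), packs the sentences into documents (a
document may be split across several CSV rows sharing one id, exercising
the group-by-id path), and optionally injects distractor sentences that
plant no facts.  Because the sentence grammar is invertible, the matching
extraction stub recovers exactly the planted triples, so every pipeline
stage downstream can be verified against the generator's bookkeeping.

Entity names are built so that no entity name is a token-suffix of
another; combined with vocabulary validation in the extraction rule, a
sentence fragment cut off at a chunk boundary can never yield a spurious
triple (the intact copy in the overlapping neighbour chunk supplies the
true one).
"""

from __future__ import annotations

import csv
import io
import json
import random
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from agrigraph.prompts import COMPLETION_DELIM, RECORD_DELIM, TUPLE_DELIM
from agrigraph.errors import DataError
from agrigraph.providers import HashingEncoder, StubCompletionProvider

CROPS = "Crops"
DISEASES = "Diseases"
PESTS = "Insect pests"
SYMPTOMS = "Symptoms"
MEASURES = "Control measures"
PATHOGENS = "Pathogen"

#: (verb phrase, head type, tail type); the relation type IS the verb phrase.
RELATION_GRAMMAR: tuple[tuple[str, str, str], ...] = (
    ("infects", DISEASES, CROPS),
    ("harms", PESTS, CROPS),
    ("manifests as", DISEASES, SYMPTOMS),
    ("causes", PATHOGENS, DISEASES),
    ("controls", MEASURES, DISEASES),
    ("targets", MEASURES, PESTS),
)

_CROP_WORDS = ["rice", "wheat", "maize", "cotton", "barley", "millet", "soybean",
               "sorghum", "potato", "tomato", "rapeseed", "peanut"]
_ADJECTIVES = ["amber", "crimson", "dusky", "golden", "ivory", "jade", "mauve",
               "ochre", "pearl", "russet", "sable", "teal", "umber", "violet",
               "azure", "coral", "ebony", "fawn", "hazel", "sienna"]
_NOUNS = {
    DISEASES: ["blast", "blight", "smut", "rust", "mildew", "mold"],
    PESTS: ["borer", "weevil", "aphid", "moth", "beetle", "planthopper"],
    SYMPTOMS: ["lesions", "wilting", "mottling", "streaks", "galls", "chlorosis"],
    MEASURES: ["spray", "trap", "rotation", "biocontrol", "mulching", "netting"],
    PATHOGENS: ["fungus", "virus", "bacterium", "nematode", "oomycete", "phytoplasma"],
}

DISTRACTORS = [
    "farmers inspect the fields at dawn every week",
    "the extension bulletin was printed in early spring",
    "rainfall records were archived by the county station",
    "the survey team photographed the northern plots",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic study corpus; the seed fixes every draw.

    Default type counts follow the roughly 35/25/20/10/10 split of crops,
    diseases, pests, control measures and auxiliary entities (symptoms +
    pathogens) observed in real pest-and-disease knowledge graphs.
    """

    n_crops: int = 7
    n_diseases: int = 5
    n_pests: int = 4
    n_symptoms: int = 1
    n_measures: int = 2
    n_pathogens: int = 1
    triples_per_entity: float = 2.0
    docs: int = 30
    distractor_rate: float = 0.1
    duplicate_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_crops, self.n_diseases, self.n_pests, self.n_symptoms,
               self.n_measures, self.n_pathogens) < 0 or self.docs < 1:
            raise DataError("entity counts must be >= 0 and docs >= 1")

    @classmethod
    def proportional(cls, total: int, seed: int = 0, **overrides) -> "GeneratorParams":
        """Counts for *total* entities at the default type proportions."""
        shares = {"n_crops": 0.35, "n_diseases": 0.25, "n_pests": 0.20,
                  "n_measures": 0.10, "n_symptoms": 0.05, "n_pathogens": 0.05}
        counts = {k: max(1, round(v * total)) for k, v in shares.items()}
        counts.update(overrides)
        return cls(seed=seed, **counts)


@dataclass
class ToyKG:
    entities: dict[str, str]  # name -> entity type
    triples: Counter  # (head, relation, tail) -> multiplicity
    descriptions: dict[str, str] = field(default_factory=dict)

    def to_truth(self) -> dict:
        return {
            "entities": dict(sorted(self.entities.items())),
            "triples": sorted([h, r, t, n] for (h, r, t), n in self.triples.items()),
        }


def _names(params: GeneratorParams) -> dict[str, str]:
    def pool(base: list[str], n: int, compose: str | None = None) -> list[str]:
        out = []
        i = 0
        while len(out) < n:
            word = base[i % len(base)] + ("" if i < len(base) else str(i // len(base) + 1))
            out.append(word if compose is None else word)
            i += 1
        return out

    entities: dict[str, str] = {}
    for name in pool(_CROP_WORDS, params.n_crops):
        entities[name] = CROPS
    counts = {DISEASES: params.n_diseases, PESTS: params.n_pests,
              SYMPTOMS: params.n_symptoms, MEASURES: params.n_measures,
              PATHOGENS: params.n_pathogens}
    adj_i = 0
    for etype, n in counts.items():
        nouns = _NOUNS[etype]
        for j in range(n):
            adj = _ADJECTIVES[adj_i % len(_ADJECTIVES)]
            if adj_i >= len(_ADJECTIVES):
                adj += str(adj_i // len(_ADJECTIVES) + 1)
            noun = nouns[j % len(nouns)]
            entities[f"{adj} {noun}"] = etype
            adj_i += 1
    return entities


def generate_kg(params: GeneratorParams) -> ToyKG:
    """Deterministic toy knowledge graph; every entity joins >= 1 triple."""
    rng = random.Random(params.seed)
    entities = _names(params)
    by_type: dict[str, list[str]] = {}
    for name, etype in entities.items():
        by_type.setdefault(etype, []).append(name)
    usable = [
        (verb, h, t) for verb, h, t in RELATION_GRAMMAR
        if by_type.get(h) and by_type.get(t)
    ]
    if not usable:
        raise DataError("no relation kind has both endpoint types populated")
    triples: Counter = Counter()
    target = max(1, round(params.triples_per_entity * len(entities) / 2))
    attempts = 0
    while sum(1 for _ in triples) < target and attempts < 50 * target:
        attempts += 1
        verb, ht, tt = rng.choice(usable)
        head, tail = rng.choice(by_type[ht]), rng.choice(by_type[tt])
        if head == tail or (head, verb, tail) in triples:
            continue
        triples[(head, verb, tail)] = 1 + (rng.random() < params.duplicate_rate)
    covered = {e for h, _, t in triples for e in (h, t)}
    for name in sorted(set(entities) - covered):
        etype = entities[name]
        options = [(v, h, t) for v, h, t in usable if etype in (h, t)]
        verb, ht, tt = rng.choice(options)
        partner_type = tt if etype == ht else ht
        partners = [p for p in by_type[partner_type] if p != name]
        if not partners:
            continue
        partner = rng.choice(partners)
        trip = (name, verb, partner) if etype == ht else (partner, verb, name)
        triples[trip] = max(triples[trip], 1)
    singular = {CROPS: "crop", DISEASES: "disease", PESTS: "insect pest",
                SYMPTOMS: "symptom", MEASURES: "control measure", PATHOGENS: "pathogen"}
    descriptions = {n: f"{n} is a documented {singular[t]}" for n, t in entities.items()}
    return ToyKG(entities=entities, triples=triples, descriptions=descriptions)


def realize(head: str, verb: str, tail: str) -> str:
    return f"{head} {verb} {tail} ."


def render_corpus(kg: ToyKG, params: GeneratorParams) -> list[tuple[str, str]]:
    """Realize every triple (with multiplicity) into (id, text) CSV rows.

    Sentences are shuffled across ``params.docs`` documents; distractor
    sentences are injected at ``distractor_rate``; a document may be
    emitted as several rows sharing its id.  Deterministic under the seed.
    """
    if not kg.triples:
        raise DataError("cannot render an empty knowledge graph")
    rng = random.Random(params.seed + 1)
    sentences = [
        realize(h, v, t)
        for (h, v, t), mult in sorted(kg.triples.items())
        for _ in range(mult)
    ]
    rng.shuffle(sentences)
    n_docs = min(params.docs, len(sentences))
    buckets: list[list[str]] = [[] for _ in range(n_docs)]
    for i, s in enumerate(sentences):
        buckets[i % n_docs].append(s)
    rows: list[tuple[str, str]] = []
    for d, bucket in enumerate(buckets):
        with_noise = []
        for s in bucket:
            if rng.random() < params.distractor_rate:
                with_noise.append(rng.choice(DISTRACTORS) + " .")
            with_noise.append(s)
        doc_id = f"doc{d:03d}"
        if len(with_noise) > 1 and rng.random() < 0.5:
            cut = rng.randrange(1, len(with_noise))
            rows.append((doc_id, " ".join(with_noise[:cut])))
            rows.append((doc_id, " ".join(with_noise[cut:])))
        else:
            rows.append((doc_id, " ".join(with_noise)))
    return rows


def write_corpus_csv(rows: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "text"])
        writer.writerows(rows)


def corpus_csv_bytes(rows: list[tuple[str, str]]) -> bytes:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["id", "text"])
    writer.writerows(rows)
    return buf.getvalue().encode()


def write_truth(kg: ToyKG, path: str | Path) -> None:
    Path(path).write_text(json.dumps(kg.to_truth(), indent=1) + "\n", encoding="utf-8")


def make_extraction_rule(kg: ToyKG):
    """Inverse of :func:`realize`, validated against the KG vocabulary.

    Splits the chunk into period-terminated sentences (an unterminated
    trailing fragment is ignored), matches each against the relation
    grammar, and emits delimiter-grammar records only when both slots hold
    known entity names of the template's types.
    """
    def rule(text: str) -> str:
        parts = re.split(r"\s*\.\s*", text)
        records: list[str] = []
        for sentence in parts[:-1]:
            sentence = sentence.strip()
            for verb, ht, tt in RELATION_GRAMMAR:
                sep = f" {verb} "
                if sep not in sentence:
                    continue
                head, tail = sentence.split(sep, 1)
                if kg.entities.get(head) == ht and kg.entities.get(tail) == tt:
                    desc = realize(head, verb, tail)
                    records.append(f'("entity"{TUPLE_DELIM}{head}{TUPLE_DELIM}{ht}{TUPLE_DELIM}{desc})')
                    records.append(f'("entity"{TUPLE_DELIM}{tail}{TUPLE_DELIM}{tt}{TUPLE_DELIM}{desc})')
                    records.append(
                        f'("relationship"{TUPLE_DELIM}{head}{TUPLE_DELIM}{tail}'
                        f'{TUPLE_DELIM}{verb}{TUPLE_DELIM}{desc})'
                    )
                break
        payload = (RECORD_DELIM + "\n").join(records)
        return payload + ("\n" if payload else "") + COMPLETION_DELIM

    return rule


def make_stubs(kg: ToyKG, dim: int = 256) -> tuple[StubCompletionProvider, HashingEncoder]:
    """Deterministic providers wired to this KG's sentence templates."""
    return StubCompletionProvider(extraction_rule=make_extraction_rule(kg)), HashingEncoder(dim=dim)
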