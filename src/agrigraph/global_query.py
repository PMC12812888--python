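"""Global querying: score-and-prune community traversal with map-reduce.

For abstract or synthesis questions, the hierarchy of community reports is
traversed top-down.  Each visited community's summary is scored 0-5 for
relevance to the query; a community is kept iff its score reaches the
decision threshold θ (default 3 — the boundary score is kept, so every
core-relevant community with score 3-5 survives).  A discarded community's
descendants are pruned outright and never scored.  Each kept community
with no kept child contributes an independent partial answer (map); the
partials are checked for contradictory single-valued statements (conflict
flagging, preferring the higher-evidence community) and then synthesized
into one final response (reduce).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from agrigraph import prompts
from agrigraph.answers import Answer
from agrigraph.errors import DataError
from agrigraph.index_store import IndexBundle
from agrigraph.providers import CompletionProvider
from agrigraph.summaries import ROOT_ID, CommunityReport

logger = logging.getLogger(__name__)

INSUFFICIENT_EVIDENCE = "Insufficient evidence: no community is relevant to this question."

_STATEMENT_RE = re.compile(r"^- (.+?) \| (.+?) \| (.+?)(?: \(w=[^)]*\))?$")


@dataclass(frozen=True)
class CommunityScore:
    community_id: str
    score: int
    level: int
    kept: bool
    clamped: bool = False


@dataclass(frozen=True)
class GlobalConfig:
    """θ is the keep threshold on the 0-5 relevance score (kept iff
    score >= θ); predicates listed in ``single_valued`` admit one object
    per subject, so differing objects across partials are a conflict."""

    threshold: int = 3
    max_partials: int = 20
    single_valued: tuple[str, ...] = ("causes",)

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 5:
            raise DataError("threshold must be within [0, 5]")


@dataclass
class PartialAnswer:
    community_id: str
    text: str
    evidence_weight: float


@dataclass
class Selection:
    selected: list[str]
    trace: list[CommunityScore]


def score_community(
    report: CommunityReport, query: str, provider: CompletionProvider
) -> tuple[int, bool]:
    """Integer relevance score in [0, 5]; out-of-range or non-integer
    provider output is clamped and flagged."""
    raw = provider.complete(prompts.score_prompt(report.summary_text, query)).strip()
    clamped = False
    try:
        value = int(raw)
    except ValueError:
        logger.warning("score_community: non-integer score %r for %s", raw, report.community_id)
        value, clamped = 0, True
    if not 0 <= value <= 5:
        value, clamped = min(5, max(0, value)), True
    return value, clamped


def _children_map(bundle: IndexBundle) -> dict[str, list[str]]:
    children: dict[str, list[str]] = {}
    has_root = ROOT_ID in bundle.reports
    for cm in bundle.communities:
        if cm.community_id == ROOT_ID:
            continue
        parent = cm.parent or (ROOT_ID if has_root else "")
        if parent:
            children.setdefault(parent, []).append(cm.community_id)
    return {k: sorted(v) for k, v in children.items()}


def _top_level(bundle: IndexBundle) -> list[str]:
    if ROOT_ID in bundle.reports:
        return [ROOT_ID]
    return sorted(cm.community_id for cm in bundle.communities if not cm.parent)


def select_communities(
    bundle: IndexBundle,
    query: str,
    cfg: GlobalConfig,
    provider: CompletionProvider,
) -> Selection:
    """Breadth-first score-and-prune from the top of the hierarchy.

    A community is kept iff score >= θ; only kept communities' children
    enter the queue, so descendants of a discarded community are never
    scored (the trace records exactly the scored communities).
    """
    children = _children_map(bundle)
    queue = list(_top_level(bundle))
    selection = Selection([], [])
    while queue:
        cid = queue.pop(0)
        report = bundle.reports[cid]
        score, clamped = score_community(report, query, provider)
        kept = score >= cfg.threshold
        selection.trace.append(CommunityScore(cid, score, report.level, kept, clamped))
        if kept:
            selection.selected.append(cid)
            queue.extend(children.get(cid, []))
    return selection


def resolve_conflicts(
    partials: list[PartialAnswer],
    single_valued: tuple[str, ...] = GlobalConfig.single_valued,
) -> tuple[list[PartialAnswer], list[dict]]:
    """Flag contradictory single-valued statements across partial answers.

    Statements are the ``- subject | predicate | object`` fact lines each
    partial carries.  For a single-valued predicate, differing objects for
    one subject are a conflict; the statement from the partial with the
    higher evidence weight is preferred, equal weights stay unresolved for
    human review.  Partials are returned unchanged; the conflict report
    carries the verification labels.
    """
    if not partials:
        raise DataError("resolve_conflicts requires at least one partial answer")
    claims: dict[tuple[str, str], dict[str, float]] = {}
    for p in partials:
        for line in p.text.splitlines():
            m = _STATEMENT_RE.match(line.strip())
            if not m:
                continue
            subj, pred, obj = (s.strip() for s in m.groups())
            if pred not in single_valued:
                continue
            bucket = claims.setdefault((subj, pred), {})
            bucket[obj] = max(bucket.get(obj, 0.0), p.evidence_weight)
    conflicts = []
    for (subj, pred), objects in sorted(claims.items()):
        if len(objects) < 2:
            continue
        best_w = max(objects.values())
        winners = sorted(o for o, w in objects.items() if w == best_w)
        conflicts.append(
            {
                "subject": subj,
                "predicate": pred,
                "candidates": sorted(objects.items()),
                "resolution": winners[0] if len(winners) == 1 else "unresolved",
                "label": "preferred-by-weight" if len(winners) == 1 else "unresolved-tie",
            }
        )
    return partials, conflicts


def answer_global(
    query: str,
    bundle: IndexBundle,
    cfg: GlobalConfig,
    provider: CompletionProvider,
) -> Answer:
    """Full global pipeline: select -> map -> conflict check -> reduce.

    Partials come from kept communities without a kept child (the finest
    kept evidence); the reduce step is order-independent because partials
    are sorted by community id before synthesis.
    """
    selection = select_communities(bundle, query, cfg, provider)
    if not selection.selected:
        return Answer(
            text=INSUFFICIENT_EVIDENCE,
            metadata={"trace": selection.trace, "partials": [], "conflicts": []},
        )
    children = _children_map(bundle)
    selected = set(selection.selected)
    leaves = [
        cid for cid in sorted(selected)
        if not any(c in selected for c in children.get(cid, []))
    ][: cfg.max_partials]
    rel_weight = {}
    for cid in leaves:
        rel_weight[cid] = sum(w for *_, w in bundle.reports[cid].member_relations)
    partials = []
    for cid in leaves:
        try:
            text = provider.complete(prompts.map_answer_prompt(bundle.reports[cid].summary_text, query))
        except Exception:  # provider failure: skip this partial, flagged
            logger.warning("answer_global: map step failed for %s; partial skipped", cid)
            continue
        partials.append(PartialAnswer(cid, text, rel_weight[cid]))
    if not partials:
        return Answer(
            text=INSUFFICIENT_EVIDENCE,
            metadata={"trace": selection.trace, "partials": [], "conflicts": []},
        )
    partials, conflicts = resolve_conflicts(partials, cfg.single_valued)
    packed = "\n".join(
        f"PARTIAL {p.community_id} (w={p.evidence_weight:g}):\n{p.text}"
        for p in sorted(partials, key=lambda p: p.community_id)
    )
    final = provider.complete(prompts.reduce_answer_prompt(packed, query))
    return Answer(
        text=final,
        citations=[p.community_id for p in partials],
        metadata={"trace": selection.trace, "partials": partials, "conflicts": conflicts},
    )
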