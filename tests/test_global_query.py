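"""Global querying: scoring, θ-pruned traversal, map-reduce, conflicts."""

import random

import pytest

from agrigraph import prompts
from agrigraph.errors import DataError
from agrigraph.global_query import (
    GlobalConfig,
    PartialAnswer,
    answer_global,
    resolve_conflicts,
    score_community,
    select_communities,
    INSUFFICIENT_EVIDENCE,
)
from agrigraph.index_store import CommunityMeta, IndexBundle
from agrigraph.providers import StubCompletionProvider
from agrigraph.summaries import ROOT_ID, CommunityReport


class ScriptedProvider(StubCompletionProvider):
    """Stub whose relevance scores are looked up from the summary text."""

    def __init__(self, scores: dict[str, int]):
        super().__init__()
        self._scores = scores

    def complete(self, req):
        if req.prompt_template_id == prompts.SCORE:
            self.calls.append(req)
            summary = prompts.extract_context(req.filled_prompt)
            return str(self._scores[summary.strip()])
        return super().complete(req)


def hierarchy_bundle(tree: dict[str, str | None], levels: dict[str, int]) -> IndexBundle:
    """Bundle holding only community metadata + reports for traversal tests.

    ``tree`` maps community id -> parent id (None for top level).
    """
    communities = [
        CommunityMeta(cid, levels[cid], parent or "", [])
        for cid, parent in tree.items()
    ]
    reports = {
        cid: CommunityReport(cid, levels[cid], f"summary of {cid}",
                             member_relations=[("h", "r", f"t{cid}", 1.0)])
        for cid in tree
    }
    return IndexBundle([], [], [], [], communities, reports)


def three_level_tree():
    tree = {"top": None, "mid1": "top", "mid2": "top",
            "leaf1": "mid1", "leaf2": "mid1", "leaf3": "mid2"}
    levels = {"top": 2, "mid1": 1, "mid2": 1, "leaf1": 0, "leaf2": 0, "leaf3": 0}
    return tree, levels


class TestScoreCommunity:
    def test_stub_scores_parse_as_integers(self):
        rep = CommunityReport("c", 0, "wheat rust spray")
        score, clamped = score_community(rep, "wheat rust spray", StubCompletionProvider())
        assert (score, clamped) == (5, False)

    def test_out_of_range_clamped_and_flagged(self):
        rep = CommunityReport("c", 0, "anything")
        score, clamped = score_community(rep, "q", ScriptedProvider({"anything": 9}))
        assert (score, clamped) == (5, True)

    def test_non_integer_output_flagged(self):
        rep = CommunityReport("c", 0, "anything")
        score, clamped = score_community(rep, "q", ScriptedProvider({"anything": "maybe"}))
        assert (score, clamped) == (0, True)


class TestSelection:
    def test_discarded_subtree_is_never_scored(self):
        tree, levels = three_level_tree()
        bundle = hierarchy_bundle(tree, levels)
        provider = ScriptedProvider({
            "summary of top": 5, "summary of mid1": 4, "summary of mid2": 2,
            "summary of leaf1": 5, "summary of leaf2": 3, "summary of leaf3": 5,
        })
        sel = select_communities(bundle, "q", GlobalConfig(), provider)
        scored = {s.community_id for s in sel.trace}
        assert "leaf3" not in scored  # child of the discarded mid2
        assert sel.selected == ["top", "mid1", "leaf1", "leaf2"]

    def test_boundary_score_three_is_kept_at_default_threshold(self):
        tree = {"a": None, "b": None}
        bundle = hierarchy_bundle(tree, {"a": 0, "b": 0})
        provider = ScriptedProvider({"summary of a": 3, "summary of b": 5})
        sel = select_communities(bundle, "q", GlobalConfig(threshold=3), provider)
        assert set(sel.selected) == {"a", "b"}

    def test_all_zero_scores_select_nothing(self):
        tree, levels = three_level_tree()
        bundle = hierarchy_bundle(tree, levels)
        provider = ScriptedProvider({f"summary of {c}": 0 for c in tree})
        sel = select_communities(bundle, "q", GlobalConfig(), provider)
        assert sel.selected == [] and len(sel.trace) == 1  # only the top scored

    @pytest.mark.parametrize("seed", range(10))
    def test_selection_matches_reachability_oracle_on_random_trees(self, seed):
        rng = random.Random(seed)
        tree: dict[str, str | None] = {"n0": None}
        levels = {"n0": 0}
        for i in range(1, rng.randint(5, 14)):
            parent = rng.choice(list(tree))
            tree[f"n{i}"] = parent
            levels[f"n{i}"] = 0
        depth = {}
        for cid in tree:
            d, cur = 0, cid
            while tree[cur] is not None:
                cur = tree[cur]
                d += 1
            depth[cid] = d
        max_depth = max(depth.values())
        for cid in tree:
            levels[cid] = max_depth - depth[cid]
        scores = {f"summary of {c}": rng.randint(0, 5) for c in tree}
        bundle = hierarchy_bundle(tree, levels)
        cfg = GlobalConfig(threshold=3)
        sel = select_communities(bundle, "q", cfg, ScriptedProvider(scores))
        # oracle: keep iff own score >= θ and every ancestor kept
        def kept(cid):
            while cid is not None:
                if scores[f"summary of {cid}"] < cfg.threshold:
                    return False
                cid = tree[cid]
            return True

        oracle = {c for c in tree if kept(c)}
        assert set(sel.selected) == oracle
        # pruning soundness: no scored community has a discarded ancestor
        for s in sel.trace:
            parent = tree[s.community_id]
            if parent is not None:
                assert parent in oracle


class TestConflicts:
    def test_higher_weight_statement_preferred(self):
        partials = [
            PartialAnswer("c1", "- dusky fungus | causes | amber blast", 3.0),
            PartialAnswer("c2", "- dusky fungus | causes | teal mold", 1.0),
        ]
        _, conflicts = resolve_conflicts(partials, single_valued=("causes",))
        [c] = conflicts
        assert c["resolution"] == "amber blast" and c["label"] == "preferred-by-weight"

    def test_equal_weights_stay_unresolved(self):
        partials = [
            PartialAnswer("c1", "- x | causes | y", 2.0),
            PartialAnswer("c2", "- x | causes | z", 2.0),
        ]
        _, conflicts = resolve_conflicts(partials, single_valued=("causes",))
        assert conflicts[0]["resolution"] == "unresolved"

    def test_disjoint_subjects_produce_no_conflicts(self):
        partials = [
            PartialAnswer("c1", "- a | causes | b", 1.0),
            PartialAnswer("c2", "- c | causes | d", 1.0),
        ]
        _, conflicts = resolve_conflicts(partials, single_valued=("causes",))
        assert conflicts == []

    def test_multi_valued_predicates_never_conflict(self):
        partials = [
            PartialAnswer("c1", "- pest | harms | rice", 1.0),
            PartialAnswer("c2", "- pest | harms | wheat", 1.0),
        ]
        _, conflicts = resolve_conflicts(partials, single_valued=("causes",))
        assert conflicts == []

    def test_empty_partials_rejected(self):
        with pytest.raises(DataError):
            resolve_conflicts([])


class TestAnswerGlobal:
    def test_single_selected_community(self):
        bundle = hierarchy_bundle({"a": None}, {"a": 0})
        provider = ScriptedProvider({"summary of a": 5})
        ans = answer_global("q", bundle, GlobalConfig(), provider)
        assert ans.citations == ["a"] and "summary of a" in ans.text

    def test_no_relevant_community_falls_back(self):
        bundle = hierarchy_bundle({"a": None}, {"a": 0})
        provider = ScriptedProvider({"summary of a": 0})
        ans = answer_global("q", bundle, GlobalConfig(), provider)
        assert ans.text == INSUFFICIENT_EVIDENCE and ans.citations == []

    def test_partials_come_from_finest_kept_communities(self):
        tree, levels = three_level_tree()
        bundle = hierarchy_bundle(tree, levels)
        provider = ScriptedProvider({
            "summary of top": 5, "summary of mid1": 4, "summary of mid2": 4,
            "summary of leaf1": 5, "summary of leaf2": 1, "summary of leaf3": 1,
        })
        ans = answer_global("q", bundle, GlobalConfig(), provider)
        # mid1 has a kept child (leaf1) so only leaf1 represents it;
        # mid2's children were scored but discarded, so mid2 itself answers
        assert ans.citations == ["leaf1", "mid2"]

    def test_community_order_does_not_change_the_answer(self):
        tree, levels = three_level_tree()
        scores = {"summary of top": 5, "summary of mid1": 5, "summary of mid2": 5,
                  "summary of leaf1": 5, "summary of leaf2": 5, "summary of leaf3": 5}
        b1 = hierarchy_bundle(tree, levels)
        rev = dict(reversed(list(tree.items())))
        b2 = hierarchy_bundle(rev, levels)
        a1 = answer_global("q", b1, GlobalConfig(), ScriptedProvider(dict(scores)))
        a2 = answer_global("q", b2, GlobalConfig(), ScriptedProvider(dict(scores)))
        assert a1.text == a2.text and a1.citations == a2.citations

    def test_cited_communities_were_selected(self, synthetic_index):
        kg, bundle, _, provider, _ = synthetic_index
        some = sorted(kg.entities)[:6]
        ans = answer_global(" ".join(some), bundle, GlobalConfig(), provider)
        selected = {s.community_id for s in ans.metadata["trace"] if s.kept}
        assert set(ans.citations) <= selected
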