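"""Independent oracles used by the test suite.

Each function here recomputes an expected value from first principles
(closed forms, literal double sums, explicit loops), deliberately avoiding
the code paths of the implementations it checks.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

import networkx as nx


def expected_chunk_spans(T: int, S: int, O: int) -> list[tuple[int, int]]:
    """Closed-form sliding-window spans under full coverage.

    The number of windows is ``max(1, ceil((T - S) / (S - O)) + 1)``; window
    i spans ``[i*(S-O), min(i*(S-O) + S, T))``.
    """
    stride = S - O
    n = max(1, math.ceil((T - S) / stride) + 1)
    return [(i * stride, min(i * stride + S, T)) for i in range(n)]


def modularity_double_sum(g: nx.Graph, partition: dict) -> float:
    """Literal pairwise double sum of the modularity definition."""
    nodes = list(g.nodes)
    A = {(u, v): 0.0 for u in nodes for v in nodes}
    for u, v, w in g.edges(data="weight", default=1.0):
        A[(u, v)] += w
        A[(v, u)] += w
    k = {u: sum(A[(u, v)] for v in nodes) for u in nodes}
    two_m = sum(k.values())
    q = 0.0
    for u in nodes:
        for v in nodes:
            if partition[u] == partition[v]:
                q += A[(u, v)] - k[u] * k[v] / two_m
    return q / two_m


def bleu_reference(
    candidate: Sequence[str],
    references: Sequence[Sequence[str]],
    max_order: int = 4,
) -> float:
    """Unsmoothed BLEU from the definition, written with explicit loops."""
    c = len(candidate)
    best_r, best_diff = None, None
    for ref in references:
        diff = abs(len(ref) - c)
        if best_diff is None or diff < best_diff or (diff == best_diff and len(ref) < best_r):
            best_r, best_diff = len(ref), diff
    log_sum = 0.0
    for n in range(1, max_order + 1):
        cand_grams = Counter()
        for i in range(c - n + 1):
            cand_grams[tuple(candidate[i : i + n])] += 1
        clipped = 0
        for gram, count in cand_grams.items():
            best = 0
            for ref in references:
                seen = 0
                for i in range(len(ref) - n + 1):
                    if tuple(ref[i : i + n]) == gram:
                        seen += 1
                best = max(best, seen)
            clipped += min(count, best)
        total = c - n + 1
        if total <= 0 or clipped == 0:
            return 0.0
        log_sum += (1.0 / max_order) * math.log(clipped / total)
    bp = 1.0 if c > best_r else math.exp(1.0 - best_r / c)
    return bp * math.exp(log_sum)
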