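"""QA evaluation metrics: precision, recall, F1, BLEU-4, mean latency.

Precision is the fraction of returned answers that are correct
(``A_c / A_r``), recall the fraction of reference answers recovered
(``A_c / A_s``), and F1 their harmonic mean ``2PR / (P + R)``.  BLEU is
the classic corpus statistic ``BP * exp(sum_n w_n log p_n)`` with modified
(reference-clipped) n-gram precisions up to order N (default 4, uniform
weights), no smoothing — any zero p_n zeroes the score — and a brevity
penalty of ``exp(1 - r/c)`` when the candidate is no longer than the
closest-length reference.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from agrigraph.errors import DataError, UndefinedMetricError


@dataclass(frozen=True)
class EvalCounts:
    """correct/returned/reference answer counts (A_c, A_r, A_s)."""

    correct: int
    returned: int
    reference: int

    def __post_init__(self) -> None:
        if min(self.correct, self.returned, self.reference) < 0:
            raise DataError("counts must be non-negative")
        if self.correct > self.returned or self.correct > self.reference:
            raise DataError("correct count cannot exceed returned or reference counts")


def precision_recall_f1(counts: EvalCounts) -> tuple[float, float, float]:
    """(P, R, F1); zero denominators raise :class:`UndefinedMetricError`."""
    if counts.returned == 0:
        raise UndefinedMetricError("precision undefined: no returned answers")
    if counts.reference == 0:
        raise UndefinedMetricError("recall undefined: no reference answers")
    p = counts.correct / counts.returned
    r = counts.correct / counts.reference
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


@dataclass(frozen=True)
class BleuConfig:
    max_order: int = 4
    smoothing: bool = False  # off by default; add-one on zero counts when on

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise DataError("max_order must be >= 1")

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(1.0 / self.max_order for _ in range(self.max_order))


@dataclass(frozen=True)
class BleuResult:
    bleu: float
    precisions: tuple[float, ...]
    brevity_penalty: float
    candidate_len: int
    reference_len: int


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu(
    candidate: Sequence[str],
    references: Sequence[Sequence[str]],
    cfg: BleuConfig = BleuConfig(),
) -> BleuResult:
    """Sentence BLEU of a tokenized candidate against >= 1 references.

    ``r`` is the length of the reference closest to the candidate length
    (ties to the shorter); modified precisions clip candidate n-gram counts
    at the per-reference maximum.
    """
    if not candidate:
        raise DataError("BLEU undefined for an empty candidate")
    if not references or any(not ref for ref in references):
        raise DataError("BLEU requires at least one non-empty reference")
    c = len(candidate)
    r = min((abs(len(ref) - c), len(ref)) for ref in references)[1]
    precisions = []
    for n in range(1, cfg.max_order + 1):
        cand_counts = _ngrams(candidate, n)
        max_ref: Counter = Counter()
        for ref in references:
            for gram, count in _ngrams(ref, n).items():
                max_ref[gram] = max(max_ref[gram], count)
        clipped = sum(min(count, max_ref[gram]) for gram, count in cand_counts.items())
        total = max(0, c - n + 1)
        if total == 0:
            precisions.append(0.0)
        elif cfg.smoothing and clipped == 0:
            precisions.append(1.0 / (2 * total))
        else:
            precisions.append(clipped / total)
    bp = 1.0 if c > r else math.exp(1.0 - r / c)
    if any(p == 0.0 for p in precisions):
        score = 0.0
    else:
        score = bp * math.exp(sum(w * math.log(p) for w, p in zip(cfg.weights, precisions)))
    return BleuResult(score, tuple(precisions), bp, c, r)


def mean_latency(durations: Sequence[float]) -> float:
    """Arithmetic mean of per-question latencies, in seconds."""
    if not durations:
        raise DataError("mean_latency requires at least one duration")
    return fmean(durations)
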