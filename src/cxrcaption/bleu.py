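"""Sentence-level BLEU: clipped n-gram precision, brevity penalty, score.

BLEU here plays two roles: it is the pairwise similarity that picks each
retrieval subset's medoid caption, and it is the evaluation metric
comparing a served caption with the final report.  The default
configuration is BLEU-4 with uniform weights and add-one smoothing on
orders >= 2; a candidate with zero unigram overlap scores exactly 0, which
keeps "no shared words -> no similarity" true for short clinical
sentences.

The effective reference length for the brevity penalty is the reference
length closest to the candidate's, ties resolved toward the shorter
reference (the original BLEU convention).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .textproc import TokenSequence

SMOOTHING_POLICIES = ("add1_high_orders", "none")


@dataclass(frozen=True)
class BleuConfig:
    """N-gram order, per-order weights and smoothing policy."""

    max_order: int = 4
    weights: tuple[float, ...] = field(default=())
    smoothing: str = "add1_high_orders"

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if not self.weights:
            object.__setattr__(
                self, "weights", tuple(1.0 / self.max_order for _ in range(self.max_order))
            )
        if len(self.weights) != self.max_order:
            raise ValueError("weights length must equal max_order")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.smoothing not in SMOOTHING_POLICIES:
            raise ValueError(f"unknown smoothing policy {self.smoothing!r}")


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def modified_ngram_precision(
    candidate: TokenSequence, references: Sequence[TokenSequence], n: int
) -> tuple[float, int, int]:
    """Clipped n-gram precision of the candidate against the references.

    Returns ``(ratio, matched, total)`` where ``total`` is the number of
    candidate n-grams and ``matched`` the clipped match count (each
    candidate n-gram credited at most its maximum count in any single
    reference).  ``ratio`` is 0 when the candidate has no n-grams.
    """
    if n < 1:
        raise ValueError("n-gram order must be >= 1")
    cand_counts = _ngrams(candidate.tokens, n)
    total = sum(cand_counts.values())
    if total == 0:
        return 0.0, 0, 0
    max_ref: Counter = Counter()
    for ref in references:
        for gram, cnt in _ngrams(ref.tokens, n).items():
            if cnt > max_ref[gram]:
                max_ref[gram] = cnt
    matched = sum(min(cnt, max_ref[gram]) for gram, cnt in cand_counts.items())
    return matched / total, matched, total


def brevity_penalty(candidate_length: int, effective_reference_length: int) -> float:
    """exp(1 - r/c) for short candidates; 1 otherwise; 0 for an empty candidate."""
    if candidate_length < 0 or effective_reference_length < 0:
        raise ValueError("lengths must be non-negative")
    if candidate_length == 0:
        return 0.0 if effective_reference_length > 0 else 1.0
    if candidate_length >= effective_reference_length:
        return 1.0
    return math.exp(1.0 - effective_reference_length / candidate_length)


def effective_reference_length(candidate_length: int, references: Sequence[TokenSequence]) -> int:
    """Closest reference length to the candidate's; ties go to the shorter."""
    best = None
    for ref in references:
        rl = len(ref)
        if best is None or abs(rl - candidate_length) < abs(best - candidate_length) or (
            abs(rl - candidate_length) == abs(best - candidate_length) and rl < best
        ):
            best = rl
    assert best is not None
    return best


def bleu_score(
    candidate: TokenSequence,
    references: Sequence[TokenSequence],
    cfg: BleuConfig | None = None,
) -> float:
    """BLEU of one candidate sequence against one or more references.

    Geometric mean of the per-order modified precisions (weighted per
    ``cfg``), times the brevity penalty.  A zero unigram precision forces a
    score of 0 regardless of smoothing.
    """
    cfg = cfg or BleuConfig()
    if not references:
        raise ValueError("at least one reference is required")
    if all(len(r) == 0 for r in references):
        raise ValueError("references must not all be empty")
    if len(candidate) == 0:
        return 0.0
    log_sum = 0.0
    for order, weight in enumerate(cfg.weights, start=1):
        p, matched, total = modified_ngram_precision(candidate, references, order)
        if order == 1 and matched == 0:
            return 0.0
        if cfg.smoothing == "add1_high_orders" and order >= 2:
            p = (matched + 1) / (total + 1) if total >= 0 else 0.0
        if p == 0.0:
            return 0.0
        log_sum += weight * math.log(p)
    bp = brevity_penalty(len(candidate), effective_reference_length(len(candidate), references))
    return bp * math.exp(log_sum)
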