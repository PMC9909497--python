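"""Independent reference implementations used only as test oracles.

Each function here is written from the textbook definition of the quantity
it computes, deliberately structured differently from the package code it
cross-checks (explicit enumeration instead of Counter arithmetic, all-pairs
counting instead of rank formulas).
"""

from __future__ import annotations

import math
from typing import Sequence


def _ngram_list(tokens: Sequence[str], n: int) -> list[tuple[str, ...]]:
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def reference_bleu(
    candidate: Sequence[str],
    references: Sequence[Sequence[str]],
    max_order: int = 4,
) -> float:
    """BLEU-N, uniform weights, add-one smoothing on orders >= 2, zero
    unigram overlap -> 0, brevity penalty with closest (ties: shorter)
    reference length."""
    if len(candidate) == 0:
        return 0.0
    log_precisions = []
    for n in range(1, max_order + 1):
        cand_grams = _ngram_list(candidate, n)
        total = len(cand_grams)
        matched = 0
        for gram in set(cand_grams):
            cand_count = cand_grams.count(gram)
            best_ref = 0
            for ref in references:
                c = _ngram_list(ref, n).count(gram)
                if c > best_ref:
                    best_ref = c
            matched += min(cand_count, best_ref)
        if n == 1:
            if matched == 0:
                return 0.0
            p = matched / total
        else:
            p = (matched + 1) / (total + 1)
        if p == 0:
            return 0.0
        log_precisions.append(math.log(p))
    geo = math.exp(sum(log_precisions) / max_order)
    # effective reference length: closest, ties toward shorter
    c = len(candidate)
    ref_len = None
    for ref in references:
        r = len(ref)
        if ref_len is None:
            ref_len = r
        else:
            if abs(r - c) < abs(ref_len - c) or (abs(r - c) == abs(ref_len - c) and r < ref_len):
                ref_len = r
    bp = 1.0 if c >= ref_len else math.exp(1.0 - ref_len / c)
    return bp * geo


def brute_force_medoid(
    subset: Sequence[Sequence[str]], max_order: int = 4
) -> tuple[int, float]:
    """Index and mean score of the member maximizing mean pairwise BLEU
    against all other members (ties: shorter, then lexicographic)."""
    n = len(subset)
    if n == 1:
        return 0, 1.0
    best_idx, best_key = None, None
    for i, cand in enumerate(subset):
        scores = [
            reference_bleu(cand, [ref], max_order)
            for j, ref in enumerate(subset)
            if j != i
        ]
        mean = sum(scores) / (n - 1)
        key = (-mean, len(cand), " ".join(cand))
        if best_key is None or key < best_key:
            best_key, best_idx = key, i
    return best_idx, -best_key[0]


def all_pairs_auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
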