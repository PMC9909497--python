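"""Caption retrieval: BLEU-medoid index over label codes.

Training reports are tokenized, their location phrases and numerals
blanked, and grouped into subsets by identical label code.  Within each
subset every member is scored by its mean pairwise BLEU against the other
members; the member with the largest mean ("the BLEU medoid") becomes the
subset's caption.  At serving time a classifier's binarized label code is
looked up exactly; unseen codes can fall back to the nearest code by
Hamming distance on the sign flags.

Duplicate token sequences within a subset are retained conceptually — they
weight common phrasings — but the implementation groups identical
sequences and weights by multiplicity, which leaves every mean unchanged
while making large subsets tractable.  Subsets larger than
``max_subset_unique`` distinct sequences are truncated to the most
frequent distinct sequences (ties by rendered text) before scoring.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .bleu import BleuConfig, bleu_score
from .textproc import TokenSequence, mask_locations_and_numbers, render, tokenize
from .vocab import LabelVector, SignVocabulary, code_key, decode_key

INDEX_SCHEMA_VERSION = 1


class IndexError_(RuntimeError):
    """State errors when querying a caption index."""


@dataclass(frozen=True)
class IndexEntry:
    """Stored caption for one label code: the medoid and subset statistics."""

    caption: TokenSequence
    subset_size: int
    mean_bleu: float

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if not 0.0 <= self.mean_bleu <= 1.0 + 1e-12:
            raise ValueError("mean_bleu must lie in [0, 1]")
        if len(self.caption) == 0:
            raise ValueError("caption must be non-empty")


@dataclass(frozen=True)
class FallbackPolicy:
    """What to do for a label code absent from the index.

    ``nearest_code`` serves the caption of the minimum-Hamming-distance
    stored code (ties: larger subset, then lexicographically smaller code);
    ``error`` raises.
    """

    mode: str = "nearest_code"

    def __post_init__(self) -> None:
        if self.mode not in ("error", "nearest_code"):
            raise ValueError(f"unknown fallback mode {self.mode!r}")


@dataclass
class CaptionIndex:
    entries: dict[str, IndexEntry]
    vocab_fingerprint: str
    bleu_config: BleuConfig
    code_length: int

    def __len__(self) -> int:
        return len(self.entries)


def select_medoid(
    subset: Sequence[TokenSequence],
    cfg: BleuConfig | None = None,
    max_subset_unique: int | None = None,
) -> tuple[TokenSequence, float]:
    """Pick the subset member with the largest mean BLEU against the others.

    Each member is scored as the mean of single-reference BLEU against each
    other member; a singleton subset returns its member with mean 1.  Ties
    break by shorter sequence, then lexicographic rendered text.
    """
    cfg = cfg or BleuConfig()
    if not subset:
        raise ValueError("subset must be non-empty")
    if any(len(s) == 0 for s in subset):
        raise ValueError("subset sequences must be non-empty")
    n_total = len(subset)
    if n_total == 1:
        return subset[0], 1.0

    groups = Counter(s.tokens for s in subset)
    # flags are determined by the tokens in practice; take the min tuple so
    # the choice never depends on subset order
    masks: dict[tuple[str, ...], tuple[bool, ...]] = {}
    for s in subset:
        cur = masks.get(s.tokens)
        if cur is None or s.mask_flags < cur:
            masks[s.tokens] = s.mask_flags
    uniques = sorted(groups, key=lambda t: (-groups[t], render(TokenSequence(t, masks[t]))))
    if max_subset_unique is not None and len(uniques) > max_subset_unique:
        uniques = uniques[:max_subset_unique]
        n_total = sum(groups[u] for u in uniques)
        if n_total == 1:
            only = TokenSequence(uniques[0], masks[uniques[0]])
            return only, 1.0

    seqs = [TokenSequence(u, masks[u]) for u in uniques]
    counts = [groups[u] for u in uniques]
    best: tuple[float, int, str] | None = None
    best_seq: TokenSequence | None = None
    best_mean = 0.0
    for i, cand in enumerate(seqs):
        acc = (counts[i] - 1) * 1.0  # identical duplicates score BLEU 1
        for j, ref in enumerate(seqs):
            if j == i:
                continue
            acc += counts[j] * bleu_score(cand, [ref], cfg)
        mean = acc / (n_total - 1)
        key = (-mean, len(cand), render(cand))
        if best is None or key < best:
            best = key
            best_seq = cand
            best_mean = mean
    assert best_seq is not None
    return best_seq, best_mean


def prepare_sequence(
    text: str, location_lexicon: Iterable[str]
) -> TokenSequence:
    """Tokenize a findings paragraph and blank locations/numbers."""
    return mask_locations_and_numbers(tokenize(text), tuple(location_lexicon))


def build_index(
    corpus: Sequence,  # Sequence[ReportRecord]; duck-typed to avoid an import cycle
    vocab: SignVocabulary,
    cfg: BleuConfig | None = None,
    location_lexicon: Iterable[str] = (),
    max_subset_unique: int | None = 300,
) -> CaptionIndex:
    """Build the caption index from a labeled report corpus.

    Every record must carry findings text and a label vector; records with
    the same label code form one retrieval subset whose medoid (over the
    masked token sequences) becomes the stored caption.
    """
    cfg = cfg or BleuConfig()
    if not corpus:
        raise ValueError("corpus must be non-empty")
    lexicon = tuple(location_lexicon)
    missing = [str(getattr(r, "record_id", "?")) for r in corpus
               if getattr(r, "labels", None) is None or not getattr(r, "findings_text", "")]
    if missing:
        raise ValueError(f"records missing labels or findings text: {missing}")

    subsets: dict[str, list[TokenSequence]] = {}
    for rec in corpus:
        key = code_key(rec.labels)
        if len(key) != len(vocab):
            raise ValueError(f"record {rec.record_id}: label length != vocabulary size")
        seq = prepare_sequence(rec.findings_text, lexicon)
        if len(seq) == 0:
            raise ValueError(f"record {rec.record_id}: empty findings after tokenization")
        subsets.setdefault(key, []).append(seq)

    entries: dict[str, IndexEntry] = {}
    for key in sorted(subsets):
        members = subsets[key]
        winner, mean = select_medoid(members, cfg, max_subset_unique=max_subset_unique)
        entries[key] = IndexEntry(caption=winner, subset_size=len(members), mean_bleu=mean)
    return CaptionIndex(
        entries=entries,
        vocab_fingerprint=vocab.fingerprint(),
        bleu_config=cfg,
        code_length=len(vocab),
    )


def generate_caption(
    labels: LabelVector,
    index: CaptionIndex,
    policy: FallbackPolicy | None = None,
    vocab: SignVocabulary | None = None,
) -> tuple[TokenSequence, str, str]:
    """Serve the caption for a label code.

    Returns ``(caption, provenance, matched_code)`` with provenance
    ``"exact"`` or ``"fallback"``.  When ``vocab`` is given its fingerprint
    is checked against the one recorded at build time.
    """
    policy = policy or FallbackPolicy()
    if not index.entries:
        raise IndexError_("caption index is empty")
    if vocab is not None and vocab.fingerprint() != index.vocab_fingerprint:
        raise IndexError_("vocabulary does not match the one the index was built with")
    key = code_key(labels)
    if len(key) != index.code_length:
        raise IndexError_(
            f"label vector length {len(key)} != index code length {index.code_length}"
        )
    entry = index.entries.get(key)
    if entry is not None:
        return entry.caption, "exact", key
    if policy.mode == "error":
        raise IndexError_(f"label code {key} not present in index")
    # nearest stored code by Hamming distance; ties -> larger subset, then smaller code
    best_key = min(
        index.entries,
        key=lambda k: (
            labels.hamming(decode_key(k)),
            -index.entries[k].subset_size,
            k,
        ),
    )
    return index.entries[best_key].caption, "fallback", best_key


def save_index(index: CaptionIndex, path: str | Path) -> None:
    """Persist an index as versioned JSON; round-trips bit-exact."""
    payload = {
        "schema_version": INDEX_SCHEMA_VERSION,
        "vocab_fingerprint": index.vocab_fingerprint,
        "code_length": index.code_length,
        "bleu_config": {
            "max_order": index.bleu_config.max_order,
            "weights": list(index.bleu_config.weights),
            "smoothing": index.bleu_config.smoothing,
        },
        "entries": {
            key: {
                "tokens": list(e.caption.tokens),
                "mask_flags": list(e.caption.mask_flags),
                "subset_size": e.subset_size,
                "mean_bleu": e.mean_bleu,
            }
            for key, e in sorted(index.entries.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_index(path: str | Path) -> CaptionIndex:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != INDEX_SCHEMA_VERSION:
        raise IndexError_(f"unsupported index schema: {payload.get('schema_version')!r}")
    cfgd = payload["bleu_config"]
    cfg = BleuConfig(
        max_order=cfgd["max_order"],
        weights=tuple(cfgd["weights"]),
        smoothing=cfgd["smoothing"],
    )
    entries = {
        key: IndexEntry(
            caption=TokenSequence(tuple(d["tokens"]), tuple(d["mask_flags"])),
            subset_size=d["subset_size"],
            mean_bleu=d["mean_bleu"],
        )
        for key, d in payload["entries"].items()
    }
    return CaptionIndex(
        entries=entries,
        vocab_fingerprint=payload["vocab_fingerprint"],
        bleu_config=cfg,
        code_length=payload["code_length"],
    )
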