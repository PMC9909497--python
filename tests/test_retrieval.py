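import numpy as np
import pytest

from cxrcaption.bleu import BleuConfig, bleu_score
from cxrcaption.io import ReportRecord
from cxrcaption.retrieval import (
    FallbackPolicy,
    IndexError_,
    build_index,
    generate_caption,
    load_index,
    save_index,
    select_medoid,
)
from cxrcaption.textproc import TokenSequence, tokenize
from cxrcaption.vocab import LabelVector, code_key, decode_key, encode_labels

from oracles import brute_force_medoid

WORDS = ["the", "lung", "is", "clear", "nodule", "mass", "seen", "no", "right", "."]


def _record(i, text, labels):
    return ReportRecord(record_id=f"r{i}", findings_text=text, labels=labels)


class TestSelectMedoid:
    def test_singleton(self):
        s = tokenize("the lung is clear.")
        winner, mean = select_medoid([s])
        assert winner == s and mean == 1.0

    def test_identical_members(self):
        s = tokenize("no nodule is seen.")
        winner, mean = select_medoid([s, s, s])
        assert winner == s and mean == pytest.approx(1.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            select_medoid([])

    def test_matches_brute_force_on_seeded_subsets(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            k = int(rng.integers(3, 11))
            subset = [
                TokenSequence(tuple(rng.choice(WORDS, size=int(rng.integers(2, 10)))))
                for _ in range(k)
            ]
            winner, mean = select_medoid(subset)
            idx, oracle_mean = brute_force_medoid([s.tokens for s in subset])
            assert winner.tokens == subset[idx].tokens
            assert mean == pytest.approx(oracle_mean, abs=1e-9)

    def test_dedup_weighting_equals_plain_enumeration(self):
        # duplicates must weight the mean exactly as if enumerated one by one
        a = tokenize("nodule is seen in the lung.")
        b = tokenize("nodule is seen.")
        c = tokenize("the lung is clear.")
        subset = [a, a, a, b, c]
        winner, mean = select_medoid(subset)
        idx, oracle_mean = brute_force_medoid([s.tokens for s in subset])
        assert winner.tokens == subset[idx].tokens
        assert mean == pytest.approx(oracle_mean, abs=1e-12)


class TestBuildIndex:
    def _corpus(self, vocab):
        return [
            _record(0, "pneumothorax is observed in the lung.",
                    encode_labels({"pneumothorax"}, vocab)),
            _record(1, "nodule is observed measuring 8 mm.",
                    encode_labels({"nodule"}, vocab)),
            _record(2, "the lungs are clear.", encode_labels(set(), vocab)),
        ]

    def test_singleton_subsets_store_masked_sequences(self, vocab, locations):
        corpus = self._corpus(vocab)
        index = build_index(corpus, vocab, location_lexicon=locations)
        assert len(index) == 3
        key = code_key(encode_labels({"nodule"}, vocab))
        entry = index.entries[key]
        assert entry.subset_size == 1 and entry.mean_bleu == 1.0
        assert "___" in entry.caption.tokens  # the numeral was blanked

    def test_two_distinct_codes_two_entries(self, vocab):
        index = build_index(self._corpus(vocab)[:2], vocab)
        assert len(index) == 2

    def test_missing_labels_reported_with_record_id(self, vocab):
        bad = [_record(0, "text.", None)]
        with pytest.raises(ValueError, match="r0"):
            build_index(bad, vocab)

    def test_permutation_invariant(self, vocab, locations):
        rng = np.random.default_rng(4)
        base = tokenize("nodule is seen")
        corpus = []
        for i in range(30):
            signs = {"nodule"} if i % 2 else {"mass"}
            words = list(base.tokens) + [WORDS[int(rng.integers(len(WORDS)))]]
            corpus.append(_record(i, " ".join(words), encode_labels(signs, vocab)))
        i1 = build_index(corpus, vocab, location_lexicon=locations)
        shuffled = list(corpus)
        rng.shuffle(shuffled)
        i2 = build_index(shuffled, vocab, location_lexicon=locations)
        assert i1.entries == i2.entries

    def test_stored_mean_bleu_is_reproducible(self, vocab, locations):
        rng = np.random.default_rng(12)
        corpus = [
            _record(i, " ".join(rng.choice(WORDS, size=6)), encode_labels(set(), vocab))
            for i in range(8)
        ]
        index = build_index(corpus, vocab, location_lexicon=locations)
        (entry,) = index.entries.values()
        from cxrcaption.retrieval import prepare_sequence

        members = [prepare_sequence(r.findings_text, locations) for r in corpus]
        others = [m for m in members if m.tokens != entry.caption.tokens]
        dup = sum(1 for m in members if m.tokens == entry.caption.tokens) - 1
        recomputed = (dup + sum(bleu_score(entry.caption, [m]) for m in others)) / (
            len(members) - 1
        )
        assert entry.mean_bleu == pytest.approx(recomputed, abs=1e-9)


class TestGenerateCaption:
    def _index(self, vocab):
        corpus = [
            _record(0, "the lungs are clear.", encode_labels(set(), vocab)),
            _record(1, "pneumothorax is observed.", encode_labels({"pneumothorax"}, vocab)),
            _record(2, "pneumothorax is seen.", encode_labels({"pneumothorax"}, vocab)),
        ]
        return build_index(corpus, vocab)

    def test_exact_hit(self, vocab):
        index = self._index(vocab)
        labels = encode_labels({"pneumothorax"}, vocab)
        caption, provenance, matched = generate_caption(labels, index, vocab=vocab)
        assert provenance == "exact" and matched == code_key(labels)

    def test_every_training_code_is_exact(self, vocab):
        index = self._index(vocab)
        for key in index.entries:
            _, provenance, matched = generate_caption(decode_key(key), index)
            assert provenance == "exact" and matched == key

    def test_nearest_code_fallback_matches_brute_force(self, vocab):
        index = self._index(vocab)
        query = encode_labels({"pneumothorax", "nodule"}, vocab)
        caption, provenance, matched = generate_caption(query, index)
        assert provenance == "fallback"
        scan = min(
            index.entries,
            key=lambda k: (
                query.hamming(decode_key(k)),
                -index.entries[k].subset_size,
                k,
            ),
        )
        assert matched == scan
        # pneumothorax code is at Hamming 1 (vs 2 for all-negative) and wins
        assert matched == code_key(encode_labels({"pneumothorax"}, vocab))

    def test_tie_breaks_prefer_larger_subset_then_smaller_code(self):
        # 3-sign toy index: query "001" is at distance 1 from both stored codes
        from cxrcaption.retrieval import CaptionIndex, IndexEntry

        entry_a = IndexEntry(caption=tokenize("a"), subset_size=1, mean_bleu=1.0)
        entry_b = IndexEntry(caption=tokenize("b"), subset_size=4, mean_bleu=1.0)
        index = CaptionIndex(
            entries={"000": entry_a, "011": entry_b},
            vocab_fingerprint="x",
            bleu_config=BleuConfig(),
            code_length=3,
        )
        _, provenance, matched = generate_caption(decode_key("001"), index)
        assert provenance == "fallback" and matched == "011"  # bigger subset wins
        index.entries["011"] = IndexEntry(caption=tokenize("b"), subset_size=1, mean_bleu=1.0)
        _, _, matched = generate_caption(decode_key("001"), index)
        assert matched == "000"  # equal subsets: lexicographically smaller code

    def test_error_mode_raises_on_miss(self, vocab):
        index = self._index(vocab)
        query = encode_labels({"pneumothorax", "nodule"}, vocab)
        with pytest.raises(IndexError_):
            generate_caption(query, index, FallbackPolicy("error"))

    def test_empty_index_and_fingerprint_mismatch(self, vocab, small_vocab):
        from cxrcaption.retrieval import CaptionIndex

        empty = CaptionIndex({}, vocab.fingerprint(), BleuConfig(), 23)
        with pytest.raises(IndexError_):
            generate_caption(LabelVector((0,) * 23), empty)
        index = self._index(vocab)
        with pytest.raises(IndexError_, match="vocabulary"):
            generate_caption(
                LabelVector((0,) * 23), index, vocab=small_vocab
            )


class TestPersistence:
    def test_round_trip_is_bit_exact(self, vocab, locations, tmp_path):
        corpus = [
            _record(0, "nodule is seen in the right upper lobe measuring 4 mm.",
                    encode_labels({"nodule"}, vocab)),
            _record(1, "the lungs are clear.", encode_labels(set(), vocab)),
        ]
        index = build_index(corpus, vocab, location_lexicon=locations)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_index(index, p1)
        reloaded = load_index(p1)
        assert reloaded.entries == index.entries
        assert reloaded.bleu_config == index.bleu_config
        save_index(reloaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
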