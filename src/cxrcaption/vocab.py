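"""The abnormal-sign vocabulary and its binary label encoding.

A :class:`SignVocabulary` is an ordered registry of radiographic findings
("abnormal signs"); the position of a sign in the registry is its
``sign_id`` and fixes one bit of every :class:`LabelVector`.  The packaged
default vocabulary holds the 23 signs used throughout the toolkit, ordered
lung parenchyma -> mediastinum -> pleura -> thorax.

Label vectors serialise to fixed-width '0'/'1' strings ("label codes"),
read left to right from sign_id 0; the code is the lookup key of the
caption-retrieval index.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

ANATOMIC_GROUPS = ("lung_parenchyma", "mediastinum", "pleura", "thorax")


class VocabularyError(ValueError):
    """Raised for malformed vocabulary files or unknown sign names."""


@dataclass(frozen=True)
class AbnormalSign:
    """One radiographic finding category.

    Parameters
    ----------
    sign_id
        0-based position in the vocabulary; fixes the sign's bit.
    canonical_name
        Lower-cased preferred surface form, unique in the vocabulary.
    anatomic_group
        One of ``lung_parenchyma``, ``mediastinum``, ``pleura``, ``thorax``.
    lexicon
        Surface phrases (synonyms/parasynonyms) that may denote the sign in
        report text; always contains the canonical name.
    """

    sign_id: int
    canonical_name: str
    anatomic_group: str
    lexicon: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise VocabularyError("sign name must be non-empty")
        if self.anatomic_group not in ANATOMIC_GROUPS:
            raise VocabularyError(
                f"unknown anatomic group {self.anatomic_group!r} for "
                f"{self.canonical_name!r}"
            )
        if self.canonical_name not in self.lexicon:
            raise VocabularyError(
                f"lexicon of {self.canonical_name!r} must contain the canonical name"
            )


@dataclass(frozen=True)
class SignVocabulary:
    """Ordered, immutable collection of :class:`AbnormalSign`."""

    signs: tuple[AbnormalSign, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.signs:
            raise VocabularyError("vocabulary must contain at least one sign")
        names = [s.canonical_name for s in self.signs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise VocabularyError(f"duplicate sign names: {sorted(dupes)}")
        for pos, sign in enumerate(self.signs):
            if sign.sign_id != pos:
                raise VocabularyError(
                    f"sign_id {sign.sign_id} of {sign.canonical_name!r} does not "
                    f"match its position {pos}"
                )
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.signs)

    def __iter__(self):
        return iter(self.signs)

    def names(self) -> tuple[str, ...]:
        return tuple(s.canonical_name for s in self.signs)

    def index_of(self, canonical_name: str) -> int:
        try:
            return self._index[canonical_name]
        except KeyError:
            raise VocabularyError(f"unknown sign name: {canonical_name!r}") from None

    def fingerprint(self) -> str:
        """Checksum binding downstream artifacts (indexes) to this vocabulary."""
        blob = "\n".join(self.names()).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class LabelVector:
    """Binary flags over the vocabulary, one per sign ("1-hot code")."""

    flags: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(f not in (0, 1) for f in self.flags):
            raise ValueError("label flags must be 0 or 1")
        if not self.flags:
            raise ValueError("label vector must have at least one flag")

    def __len__(self) -> int:
        return len(self.flags)

    def positive_indices(self) -> tuple[int, ...]:
        return tuple(i for i, f in enumerate(self.flags) if f)

    def hamming(self, other: "LabelVector") -> int:
        if len(other) != len(self):
            raise ValueError("length mismatch in Hamming distance")
        return sum(a != b for a, b in zip(self.flags, other.flags))


def load_vocabulary(path: str | Path | None = None) -> SignVocabulary:
    """Load a vocabulary file; ``None`` loads the packaged 23-sign default.

    The file is YAML with a top-level ``signs`` list; each entry carries
    ``name``, ``group`` and a ``lexicon`` phrase list.  File order is
    preserved and becomes the bit order.
    """
    if path is None:
        with resources.files("cxrcaption.data").joinpath("vocabulary.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not raw or "signs" not in raw or not raw["signs"]:
        raise VocabularyError("vocabulary file is empty or lacks a 'signs' list")
    signs = []
    for pos, entry in enumerate(raw["signs"]):
        try:
            name = str(entry["name"]).strip().lower()
            group = str(entry["group"]).strip()
            lexicon = tuple(str(p).strip().lower() for p in entry["lexicon"])
        except (KeyError, TypeError) as exc:
            raise VocabularyError(f"malformed sign entry at position {pos}: {entry!r}") from exc
        signs.append(AbnormalSign(pos, name, group, lexicon))
    return SignVocabulary(tuple(signs))


def encode_labels(positive_signs: Iterable[str], vocab: SignVocabulary) -> LabelVector:
    """Build a label vector with 1s exactly at the named signs' positions."""
    flags = [0] * len(vocab)
    for name in positive_signs:
        flags[vocab.index_of(name)] = 1
    return LabelVector(tuple(flags))


def code_key(v: LabelVector) -> str:
    """Serialise a label vector to its fixed-width '0'/'1' lookup key."""
    return "".join(str(f) for f in v.flags)


def decode_key(key: str) -> LabelVector:
    """Inverse of :func:`code_key`."""
    if not key or any(c not in "01" for c in key):
        raise ValueError(f"malformed label code: {key!r}")
    return LabelVector(tuple(int(c) for c in key))


def labels_from_scores(scores: Sequence[float], threshold: float = 0.5) -> LabelVector:
    """Binarize per-sign classifier scores at ``threshold`` (score >= t -> 1)."""
    return LabelVector(tuple(1 if s >= threshold else 0 for s in scores))
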