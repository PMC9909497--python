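"""Deterministic lexicon labeler: findings text -> label vector.

A transparent rule system stands in for a learned report labeler: a sign
is flagged positive when one of its lexicon phrases occurs in the text
outside the scope of a negation cue.  Matching is case-insensitive on the
tokenized text, longest phrase first, and consuming — once a multi-word
phrase matches, its tokens cannot also match a shorter contained phrase
(so "small consolidation" does not additionally fire "consolidation").

Negation uses cue-and-window scoping: a cue ("no", "without", ...) negates
any phrase starting within ``scope_window`` tokens after it, without
crossing a sentence boundary.  Hedged mentions are treated as positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .textproc import tokenize
from .vocab import LabelVector, SignVocabulary

_SENTENCE_BREAKS = {".", ";", "!", "?"}


@dataclass(frozen=True)
class NegationLexicon:
    cues: tuple[str, ...]
    scope_window: int = 6

    def __post_init__(self) -> None:
        if not self.cues:
            raise ValueError("negation lexicon needs at least one cue")
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")


def load_negation_lexicon(path: str | Path | None = None) -> NegationLexicon:
    if path is None:
        with resources.files("cxrcaption.data").joinpath("negation.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return NegationLexicon(
        cues=tuple(str(c).strip().lower() for c in raw["cues"]),
        scope_window=int(raw.get("scope_window", 6)),
    )


def _phrase_table(vocab: SignVocabulary) -> list[tuple[tuple[str, ...], int]]:
    """All lexicon phrases tokenized, longest first, tagged with sign_id."""
    table = []
    for sign in vocab:
        for phrase in sign.lexicon:
            toks = tuple(tokenize(phrase).tokens)
            if toks:
                table.append((toks, sign.sign_id))
    table.sort(key=lambda item: (-len(item[0]), item[0]))
    return table


def label_report(
    text: str, vocab: SignVocabulary, negation: NegationLexicon | None = None
) -> LabelVector:
    """Flag each sign mentioned affirmatively anywhere in the text."""
    negation = negation or load_negation_lexicon()
    tokens = tokenize(text).tokens
    table = _phrase_table(vocab)
    cue_toks = sorted(
        (tuple(tokenize(c).tokens) for c in negation.cues), key=len, reverse=True
    )

    flags = [0] * len(vocab)
    n = len(tokens)
    sentence_start = 0
    active_cues: list[int] = []  # token positions of cues in the current sentence
    i = 0
    while i < n:
        if tokens[i] in _SENTENCE_BREAKS:
            sentence_start = i + 1
            active_cues = []
            i += 1
            continue
        for cue in cue_toks:
            if tuple(tokens[i : i + len(cue)]) == cue:
                active_cues.append(i + len(cue) - 1)
                break
        matched = 0
        sign_id = -1
        for ph, sid in table:
            if tuple(tokens[i : i + len(ph)]) == ph:
                matched, sign_id = len(ph), sid
                break
        if matched:
            negated = any(
                cue_end < i <= cue_end + negation.scope_window and cue_end >= sentence_start
                for cue_end in active_cues
            )
            if not negated:
                flags[sign_id] = 1
            i += matched
        else:
            i += 1
    return LabelVector(tuple(flags))
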