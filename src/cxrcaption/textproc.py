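"""Tokenization and location/number blanking for findings paragraphs.

The retrieval algorithm scores whole findings paragraphs as token
sequences.  Because the image classifier carries no location or size
information, location phrases and numerals are blanked (replaced by a
placeholder token) before captions are indexed or served.

Tokenization is a word-level strategy for English-like report text:
lower-case, punctuation split off, whitespace collapsed.  It is
deliberately simple and swappable; the downstream algorithms only require
determinism and a stable inverse rendering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

BLANK = "___"

# digits with optional decimal part and optional glued unit, e.g. 12, 3.5, 12mm, 40%
_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?[a-z%]*$")
_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?[a-z%]*|[^\W\d_]+|_+|[^\s\w]", re.UNICODE)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list with a parallel blanked-slot mask."""

    tokens: tuple[str, ...]
    mask_flags: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.mask_flags:
            object.__setattr__(self, "mask_flags", tuple(False for _ in self.tokens))
        if len(self.tokens) != len(self.mask_flags):
            raise ValueError("tokens and mask_flags must have equal length")
        if any(t == "" for t in self.tokens):
            raise ValueError("empty-string tokens are not allowed")

    def __len__(self) -> int:
        return len(self.tokens)

    def __bool__(self) -> bool:
        return bool(self.tokens)


def tokenize(text: str) -> TokenSequence:
    """Lower-case word/punctuation tokenization; total on arbitrary unicode."""
    tokens = _TOKEN_RE.findall(text.lower())
    return TokenSequence(tuple(tokens))


def _tokenized_phrases(phrases: Iterable[str]) -> list[tuple[str, ...]]:
    out = {tuple(tokenize(p).tokens) for p in phrases}
    out.discard(())
    # longest first so multi-word phrases win over their own sub-phrases
    return sorted(out, key=lambda t: (-len(t), t))


def mask_locations_and_numbers(
    seq: TokenSequence, location_lexicon: Iterable[str]
) -> TokenSequence:
    """Blank every numeral token and every location-lexicon phrase.

    Multi-word phrases are matched greedily, longest first; each covered
    token becomes the placeholder and is flagged.  Length is preserved and
    the operation is idempotent.
    """
    phrases = _tokenized_phrases(location_lexicon)
    tokens = list(seq.tokens)
    flags = list(seq.mask_flags)
    i = 0
    n = len(tokens)
    while i < n:
        matched = 0
        for ph in phrases:
            k = len(ph)
            if i + k <= n and tuple(tokens[i : i + k]) == ph:
                matched = k
                break
        if matched:
            for j in range(i, i + matched):
                tokens[j] = BLANK
                flags[j] = True
            i += matched
        else:
            if _NUMBER_RE.match(tokens[i]):
                tokens[i] = BLANK
                flags[i] = True
            i += 1
    return TokenSequence(tuple(tokens), tuple(flags))


_NO_SPACE_BEFORE = re.compile(r"^[^\w\s]+$")


def render(seq: TokenSequence, blank_marker: str = BLANK) -> str:
    """Join tokens with spaces, omitting the space before punctuation."""
    parts: list[str] = []
    for tok, flag in zip(seq.tokens, seq.mask_flags):
        out = blank_marker if flag else tok
        if parts and _NO_SPACE_BEFORE.match(tok):
            parts[-1] += out
        else:
            parts.append(out)
    return " ".join(parts)


def load_location_lexicon(path: str | Path | None = None) -> tuple[str, ...]:
    """Read a location lexicon (one phrase per line, '#' comments allowed)."""
    if path is None:
        from importlib import resources

        text = resources.files("cxrcaption.data").joinpath("locations.txt").read_text()
    else:
        text = Path(path).read_text()
    phrases = []
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            phrases.append(line)
    return tuple(phrases)
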