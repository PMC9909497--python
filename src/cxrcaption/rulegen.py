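"""Rule-based caption generation over 8 expression subcategories.

Signs with similar description patterns share a subcategory.  For each
subcategory, every positive member yields one sentence from the
subcategory's positive template ("<sign> is observed ..."); when all
members are negative the subcategory's fixed negative sentence is emitted
instead (device subcategories stay silent).  The per-subcategory results
are linked, in subcategory order, into one paragraph.

A separate fixed normal-findings paragraph (the "normal template") serves
as the baseline captioning arm; it is intentionally a different text from
the all-negative rule paragraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .textproc import TokenSequence, tokenize
from .vocab import LabelVector, SignVocabulary


class RuleTableError(ValueError):
    """Malformed or non-partitioning rule tables."""


@dataclass(frozen=True)
class RuleSubcategory:
    subcat_id: int
    member_signs: tuple[str, ...]
    positive_template: str
    negative_text: str
    emit_negative_when_all_negative: bool

    def __post_init__(self) -> None:
        if not self.member_signs:
            raise RuleTableError(f"subcategory {self.subcat_id} has no members")
        if "{sign}" not in self.positive_template:
            raise RuleTableError(
                f"subcategory {self.subcat_id}: positive template lacks a {{sign}} slot"
            )
        if self.emit_negative_when_all_negative and not self.negative_text:
            raise RuleTableError(
                f"subcategory {self.subcat_id}: negative sentence required but empty"
            )


@dataclass(frozen=True)
class RuleTable:
    subcategories: tuple[RuleSubcategory, ...]


def load_rule_table(path: str | Path | None, vocab: SignVocabulary) -> RuleTable:
    """Load and validate a rule table; ``None`` loads the packaged default.

    Validation enforces a partition: every vocabulary sign appears in
    exactly one subcategory and no unknown signs appear.
    """
    if path is None:
        with resources.files("cxrcaption.data").joinpath("rules.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not raw or "subcategories" not in raw:
        raise RuleTableError("rule file lacks a 'subcategories' list")
    subcats = []
    for entry in raw["subcategories"]:
        subcats.append(
            RuleSubcategory(
                subcat_id=int(entry["id"]),
                member_signs=tuple(str(m).strip().lower() for m in entry["members"]),
                positive_template=str(entry["positive_template"]),
                negative_text=str(entry.get("negative_text", "")),
                emit_negative_when_all_negative=bool(
                    entry.get("emit_negative_when_all_negative", True)
                ),
            )
        )
    seen: dict[str, int] = {}
    vocab_names = set(vocab.names())
    for sc in subcats:
        for name in sc.member_signs:
            if name not in vocab_names:
                raise RuleTableError(f"subcategory {sc.subcat_id}: unknown sign {name!r}")
            if name in seen:
                raise RuleTableError(
                    f"sign {name!r} appears in subcategories {seen[name]} and {sc.subcat_id}"
                )
            seen[name] = sc.subcat_id
    unassigned = vocab_names - set(seen)
    if unassigned:
        raise RuleTableError(f"signs not assigned to any subcategory: {sorted(unassigned)}")
    return RuleTable(tuple(subcats))


def generate_rule_caption(
    labels: LabelVector, table: RuleTable, vocab: SignVocabulary
) -> TokenSequence:
    """Assemble the rule-based caption paragraph for a label vector."""
    if len(labels) != len(vocab):
        raise ValueError("label vector length does not match vocabulary")
    sentences: list[str] = []
    for sc in table.subcategories:
        members_positive = [
            name for name in sc.member_signs if labels.flags[vocab.index_of(name)]
        ]
        if members_positive:
            for name in members_positive:
                sentences.append(sc.positive_template.format(sign=name))
        elif sc.emit_negative_when_all_negative:
            sentences.append(sc.negative_text)
    return tokenize(" ".join(sentences))


def normal_template(path: str | Path | None = None) -> TokenSequence:
    """The fixed normal-findings paragraph used as the baseline arm."""
    if path is None:
        text = resources.files("cxrcaption.data").joinpath("normal_template.txt").read_text()
    else:
        text = Path(path).read_text()
    return tokenize(text.strip())
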