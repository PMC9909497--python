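"""Line-delimited corpus records and their (de)serialization.

A corpus file is JSON-lines: one record per line with fields ``id``,
``findings_text``, and optionally ``labels`` (a fixed-width '0'/'1' code or
a list of sign names), ``scores`` (per-sign floats in [0,1]), ``arm`` and
``split``.  Malformed lines are collected with their line numbers and
reported together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .vocab import LabelVector, SignVocabulary, code_key, decode_key, encode_labels


class CorpusFormatError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("malformed corpus lines:\n" + "\n".join(problems))


@dataclass(frozen=True)
class ReportRecord:
    """One case: id, findings paragraph, labels, optional scores and arm."""

    record_id: str
    findings_text: str
    labels: LabelVector | None = None
    scores: tuple[float, ...] | None = None
    arm: str | None = None
    split: str | None = None


def _parse_line(line: str, lineno: int, vocab: SignVocabulary | None) -> ReportRecord:
    obj = json.loads(line)
    if "id" not in obj:
        raise ValueError("missing 'id'")
    labels = None
    raw_labels = obj.get("labels")
    if raw_labels is not None:
        if isinstance(raw_labels, str):
            labels = decode_key(raw_labels)
        elif isinstance(raw_labels, list):
            if vocab is None:
                raise ValueError("sign-name labels need a vocabulary to decode")
            labels = encode_labels(raw_labels, vocab)
        else:
            raise ValueError(f"unsupported labels field: {raw_labels!r}")
        if vocab is not None and len(labels) != len(vocab):
            raise ValueError(
                f"label code length {len(labels)} != vocabulary size {len(vocab)}"
            )
    scores = obj.get("scores")
    if scores is not None:
        scores = tuple(float(s) for s in scores)
        if any(not 0.0 <= s <= 1.0 for s in scores):
            raise ValueError("scores must lie in [0, 1]")
        if vocab is not None and len(scores) != len(vocab):
            raise ValueError("scores length != vocabulary size")
    return ReportRecord(
        record_id=str(obj["id"]),
        findings_text=str(obj.get("findings_text", "")),
        labels=labels,
        scores=scores,
        arm=obj.get("arm"),
        split=obj.get("split"),
    )


def read_corpus(
    path: str | Path,
    vocab: SignVocabulary | None = None,
    strict: bool = True,
) -> list[ReportRecord]:
    """Parse a JSONL corpus; in strict mode any malformed line is fatal."""
    records: list[ReportRecord] = []
    problems: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(_parse_line(line, lineno, vocab))
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems and strict:
        raise CorpusFormatError(problems)
    return records


def write_corpus(records: Sequence[ReportRecord], path: str | Path) -> None:
    """Write records as JSONL; inverse of :func:`read_corpus`."""
    with open(path, "w") as fh:
        for rec in records:
            obj: dict = {"id": rec.record_id, "findings_text": rec.findings_text}
            if rec.labels is not None:
                obj["labels"] = code_key(rec.labels)
            if rec.scores is not None:
                obj["scores"] = [round(float(s), 10) for s in rec.scores]
            if rec.arm is not None:
                obj["arm"] = rec.arm
            if rec.split is not None:
                obj["split"] = rec.split
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
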