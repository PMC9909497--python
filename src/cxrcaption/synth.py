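"""Synthetic report corpora: label-conditioned findings text and simulated
per-sign classifier outputs.

The generator emulates, at desk scale, a hospital corpus of chest-film
findings paragraphs: a latent 23-bit sign vector is drawn from per-sign
prevalences (the five most common signs default to the frequencies of a
large symptomatic training population: 0.512, 0.173, 0.165, 0.131, 0.092;
the remaining signs are rare), and each positive sign yields one
affirmative sentence built from the sign's surface lexicon, optionally
carrying an inserted location phrase and a millimetre size.  A random
subset of negative signs is explicitly negated ("no pleural effusion is
seen."), mirroring pertinent negatives in real reports.  Phrasing noise
substitutes synonyms and verb variants at a configurable per-sentence
rate.

Classifier outputs stand in for a CNN: per-sign binary calls are drawn at
the configured sensitivity/specificity, and scores are drawn from two beta
distributions conditioned on the call (0.5 + 0.5·Beta(2,4) for positive
calls, 0.5 − 0.5·Beta(2,4) for negative) so thresholding at 0.5 reproduces
the calls exactly.

The same generated text plays the role of the radiologist's final report
in evaluation; resident editing behaviour is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import assign_arm
from .io import ReportRecord, write_corpus
from .textproc import load_location_lexicon
from .vocab import LabelVector, SignVocabulary

# prevalences of the five most common signs in a large symptomatic cohort;
# all other signs default to _RARE_PREVALENCE
_COMMON_PREVALENCES = {
    "thickened bronchovascular markings": 0.512,
    "pleural thickening": 0.173,
    "nodule": 0.165,
    "consolidation": 0.131,
    "aortic arteriosclerosis": 0.092,
}
_RARE_PREVALENCE = 0.02

_VERB_VARIANTS = ("observed", "noted", "demonstrated", "visible")
# signs for which a size in millimetres is plausible report language
_MEASURABLE = {"nodule", "mass", "consolidation", "patchy consolidation", "cavity"}


def default_prevalences(vocab: SignVocabulary) -> tuple[float, ...]:
    return tuple(
        _COMMON_PREVALENCES.get(s.canonical_name, _RARE_PREVALENCE) for s in vocab
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_cases: int = 1000
    prevalences: tuple[float, ...] | None = None  # None -> vocabulary defaults
    classifier_sensitivity: float = 0.85
    classifier_specificity: float = 0.97
    phrasing_noise: float = 0.2
    location_insertion_rate: float = 0.5
    numeral_insertion_rate: float = 0.3
    negative_mention_rate: float = 0.15
    train_fraction: float = 0.7
    rng_seed: int = 0
    cooccurrence_tilt: tuple[tuple[int, int, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        rates = (
            self.classifier_sensitivity,
            self.classifier_specificity,
            self.phrasing_noise,
            self.location_insertion_rate,
            self.numeral_insertion_rate,
            self.negative_mention_rate,
            self.train_fraction,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.prevalences is not None and any(
            not 0.0 <= p <= 1.0 for p in self.prevalences
        ):
            raise ValueError("prevalences must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifierOutput:
    scores: tuple[float, ...]
    binary: tuple[int, ...]


def _resolved_prevalences(cfg: SynthConfig, vocab: SignVocabulary) -> tuple[float, ...]:
    prev = cfg.prevalences if cfg.prevalences is not None else default_prevalences(vocab)
    if len(prev) != len(vocab):
        raise ValueError("prevalences length != vocabulary size")
    return tuple(prev)


def sample_labels(
    cfg: SynthConfig, vocab: SignVocabulary, rng: np.random.Generator
) -> LabelVector:
    """Draw a sign vector; independent Bernoulli unless a tilt is configured.

    The optional co-occurrence tilt is a list of ``(j, i, delta)`` triples
    (j < i): when sign j was drawn positive, the log-odds of sign i are
    shifted by delta before drawing it.
    """
    prev = _resolved_prevalences(cfg, vocab)
    tilt: dict[int, list[tuple[int, float]]] = {}
    for j, i, delta in cfg.cooccurrence_tilt:
        if not 0 <= j < i < len(vocab):
            raise ValueError("tilt entries must satisfy 0 <= j < i < n_signs")
        tilt.setdefault(i, []).append((j, delta))
    flags = []
    for i, p in enumerate(prev):
        if i in tilt and 0.0 < p < 1.0:
            logit = np.log(p / (1.0 - p))
            for j, delta in tilt[i]:
                if flags[j]:
                    logit += delta
            p = 1.0 / (1.0 + np.exp(-logit))
        flags.append(1 if rng.random() < p else 0)
    return LabelVector(tuple(flags))


def _maybe_synonym(sign_lexicon: Sequence[str], noise: float, rng: np.random.Generator) -> str:
    if len(sign_lexicon) > 1 and rng.random() < noise:
        return str(sign_lexicon[1 + int(rng.integers(len(sign_lexicon) - 1))])
    return str(sign_lexicon[0])


def render_report(
    labels: LabelVector,
    cfg: SynthConfig,
    vocab: SignVocabulary,
    rng: np.random.Generator,
    location_lexicon: Sequence[str] | None = None,
) -> str:
    """Label-conditioned findings paragraph; deterministic given the rng state."""
    if len(labels) != len(vocab):
        raise ValueError("label vector length != vocabulary size")
    locations = tuple(location_lexicon) if location_lexicon is not None \
        else load_location_lexicon()
    # single words like "right" are masking targets but poor insertion text
    insertable = [loc for loc in locations if " " in loc] or list(locations)
    sentences: list[str] = []
    for sign in vocab:
        flag = labels.flags[sign.sign_id]
        if flag:
            phrase = _maybe_synonym(sign.lexicon, cfg.phrasing_noise, rng)
            verb = "observed"
            if rng.random() < cfg.phrasing_noise:
                verb = _VERB_VARIANTS[int(rng.integers(len(_VERB_VARIANTS)))]
            sentence = f"{phrase} is {verb}"
            if rng.random() < cfg.location_insertion_rate:
                sentence += f" in the {insertable[int(rng.integers(len(insertable)))]}"
            if sign.canonical_name in _MEASURABLE and rng.random() < cfg.numeral_insertion_rate:
                sentence += f" measuring {int(rng.integers(3, 60))} mm"
            sentences.append(sentence + ".")
        else:
            if rng.random() < cfg.negative_mention_rate:
                phrase = _maybe_synonym(sign.lexicon, cfg.phrasing_noise, rng)
                sentences.append(f"no {phrase} is seen.")
    if not labels.positive_indices():
        sentences.insert(0, "the lungs are clear.")
    if not sentences:
        sentences.append("the lungs are clear.")
    return " ".join(sentences)


def simulate_classifier(
    truth: LabelVector, cfg: SynthConfig, rng: np.random.Generator
) -> ClassifierOutput:
    """Per-sign binary calls at the configured sensitivity/specificity, with
    scores consistent with thresholding at 0.5."""
    scores: list[float] = []
    binary: list[int] = []
    for flag in truth.flags:
        p_call = cfg.classifier_sensitivity if flag else 1.0 - cfg.classifier_specificity
        call = 1 if rng.random() < p_call else 0
        margin = 0.5 * float(rng.beta(2.0, 4.0))
        score = 0.5 + margin if call else 0.5 - margin
        scores.append(round(min(max(score, 0.0), 1.0), 6))
        binary.append(call)
    return ClassifierOutput(scores=tuple(scores), binary=tuple(binary))


def generate_experiment(
    cfg: SynthConfig,
    vocab: SignVocabulary,
    out_path: str | Path | None = None,
    location_lexicon: Sequence[str] | None = None,
) -> list[ReportRecord]:
    """Generate a full three-arm experiment corpus.

    Produces ``n_cases`` records with truth labels, findings text (which
    doubles as the final report), simulated classifier scores, a
    train/test split (first ``train_fraction`` of cases train) and an
    ~1:1:1 arm assignment.  Fully reproducible from ``cfg.rng_seed``; when
    ``out_path`` is given the corpus is also written as JSONL.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    locations = tuple(location_lexicon) if location_lexicon is not None \
        else load_location_lexicon()
    n_train = int(round(cfg.train_fraction * cfg.n_cases))
    records: list[ReportRecord] = []
    for i in range(cfg.n_cases):
        case_id = f"case-{i:06d}"
        labels = sample_labels(cfg, vocab, rng)
        text = render_report(labels, cfg, vocab, rng, locations)
        clf = simulate_classifier(labels, cfg, rng)
        records.append(
            ReportRecord(
                record_id=case_id,
                findings_text=text,
                labels=labels,
                scores=clf.scores,
                arm=assign_arm(case_id, cfg.rng_seed),
                split="train" if i < n_train else "test",
            )
        )
    if out_path is not None:
        write_corpus(records, out_path)
    return records
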