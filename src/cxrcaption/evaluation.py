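"""Evaluation: classification metrics with subsample CIs, arm randomization,
and per-arm BLEU similarity with pairwise t tests.

Point metrics are the usual suspects for per-sign binary classification —
AUC (midrank tie handling, i.e. the probability a random positive outscores
a random negative with ties counted half), area under the precision-recall
curve by step integration, and confusion-matrix metrics at a fixed score
threshold.

Confidence intervals follow a 100-iteration subsampling scheme: each
iteration draws 95% of the cases without replacement, recomputes the
statistic, and the 2.5th/97.5th percentiles of the 100 replicates bound
the interval.  A classical with-replacement bootstrap is available behind
a flag.  Arm comparison uses Welch's two-sided t test.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .bleu import BleuConfig, bleu_score
from .textproc import TokenSequence

ARMS = ("normal_template", "nlp_generated", "rule_based")


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined (e.g. single-class truth for AUC)."""


@dataclass
class MetricSet:
    auc: float | None
    auprc: float | None
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate_ci: bool = False

    def as_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "auprc": self.auprc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


def _confusion(truth: np.ndarray, pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return tp, tn, fp, fn


def classification_metrics(
    scores: Sequence[float],
    truth: Sequence[int],
    threshold: float = 0.5,
) -> MetricSet:
    """Point metrics for one sign.

    AUC/AUPRC need both classes in ``truth``; when one class is absent they
    are set to ``None`` and the threshold metrics are still returned.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    if s.size == 0:
        raise ValueError("empty inputs")
    both_classes = 0 < int(t.sum()) < t.size
    auc = float(roc_auc_score(t, s)) if both_classes else None
    auprc = float(average_precision_score(t, s)) if both_classes else None
    pred = (s >= threshold).astype(int)
    tp, tn, fp, fn = _confusion(t, pred)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / t.size
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return MetricSet(auc=auc, auprc=auprc, accuracy=acc,
                     sensitivity=sens, specificity=spec, f1=f1)


def bootstrap_ci(
    statistic: Callable[[Sequence], float],
    cases: Sequence,
    iterations: int = 100,
    sample_fraction: float = 0.95,
    rng_seed: int = 0,
    with_replacement: bool = False,
) -> tuple[float, float]:
    """95% CI by repeated 95% subsampling (default) or classical bootstrap.

    Iterations where the statistic is undefined (raises
    :class:`MetricUndefinedError` or ``ValueError``) are skipped; more than
    50% skipped is an error.
    """
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must lie in (0, 1]")
    n = len(cases)
    if n == 0:
        raise ValueError("no cases")
    k = max(1, round(sample_fraction * n))
    rng = np.random.default_rng(rng_seed)
    values = []
    skipped = 0
    idx = np.arange(n)
    for _ in range(iterations):
        if with_replacement:
            take = rng.choice(idx, size=n, replace=True)
        else:
            take = rng.choice(idx, size=k, replace=False)
        sub = [cases[i] for i in take]
        try:
            values.append(float(statistic(sub)))
        except (MetricUndefinedError, ValueError):
            skipped += 1
    if skipped > iterations / 2:
        raise MetricUndefinedError(
            f"statistic undefined on {skipped}/{iterations} subsamples"
        )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def assign_arm(case_id: str, rng_seed: int) -> str:
    """Deterministic ~1:1:1 randomization of a case to a captioning arm.

    Hashes ``(seed, case_id)`` so the assignment is reproducible per case
    and uniform over the three arms marginally.
    """
    digest = hashlib.sha256(f"{rng_seed}:{case_id}".encode("utf-8")).digest()
    return ARMS[int.from_bytes(digest[:8], "big") % 3]


@dataclass
class ArmSummary:
    arm: str
    n: int
    bleu_mean: float
    bleu_sd: float | None
    pairwise_p: dict[str, float | None] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n": self.n,
            "bleu_mean": self.bleu_mean,
            "bleu_sd": self.bleu_sd,
            "pairwise_p": dict(self.pairwise_p),
        }


def evaluate_arms(
    cases: Sequence[tuple[str, TokenSequence, TokenSequence]],
    cfg: BleuConfig | None = None,
    equal_var: bool = False,
) -> list[ArmSummary]:
    """Per-arm mean/SD of caption-vs-report BLEU with pairwise t tests.

    ``cases`` holds ``(arm, generated_caption, final_report)`` triples; the
    report is the single BLEU reference.  SD and t tests are left ``None``
    (flagged) for arms with fewer than 2 cases.
    """
    cfg = cfg or BleuConfig()
    per_arm: dict[str, list[float]] = {arm: [] for arm in ARMS}
    for arm, caption, report in cases:
        if arm not in per_arm:
            raise ValueError(f"unknown arm {arm!r}")
        if len(report) == 0:
            raise ValueError("final report must be non-empty")
        per_arm[arm].append(bleu_score(caption, [report], cfg))

    summaries = []
    for arm in ARMS:
        vals = per_arm[arm]
        if not vals:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
        pairwise: dict[str, float | None] = {}
        for other in ARMS:
            if other == arm or not per_arm[other]:
                continue
            if len(vals) < 2 or len(per_arm[other]) < 2:
                pairwise[other] = None
            elif math.isclose(np.var(vals), 0) and math.isclose(np.var(per_arm[other]), 0) \
                    and math.isclose(mean, float(np.mean(per_arm[other]))):
                pairwise[other] = 1.0  # identical constant samples: no evidence
            else:
                res = stats.ttest_ind(vals, per_arm[other], equal_var=equal_var)
                pairwise[other] = float(res.pvalue)
        summaries.append(
            ArmSummary(arm=arm, n=len(vals), bleu_mean=mean, bleu_sd=sd, pairwise_p=pairwise)
        )
    return summaries
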