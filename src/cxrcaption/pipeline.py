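"""End-to-end workflow: simulate -> label -> build index -> caption by arm
-> evaluate.

The pipeline is a pure function of (config, seed): a single master seed is
fanned out to per-stage seeds by hashing the stage name with the seed, so
any stage can be rerun in isolation with the same stream.  Outputs (corpus,
index, report) are deterministic text files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .bleu import BleuConfig
from .evaluation import ARMS, MetricUndefinedError, bootstrap_ci, classification_metrics, evaluate_arms
from .io import ReportRecord, read_corpus, write_corpus
from .labeler import label_report, load_negation_lexicon
from .retrieval import FallbackPolicy, build_index, generate_caption, save_index
from .rulegen import generate_rule_caption, load_rule_table, normal_template
from .synth import SynthConfig, generate_experiment
from .textproc import load_location_lexicon, tokenize
from .vocab import labels_from_scores, load_vocabulary

logger = logging.getLogger("cxrcaption")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable across runs)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full pipeline run."""

    out_dir: str | Path
    seed: int = 0
    n_cases: int = 600
    train_fraction: float = 0.7
    synth: SynthConfig | None = None  # None -> defaults with (n_cases, seed) above
    corpus_path: str | Path | None = None  # skip simulation and read this corpus
    vocab_path: str | Path | None = None
    rules_path: str | Path | None = None
    locations_path: str | Path | None = None
    negation_path: str | Path | None = None
    threshold: float = 0.5
    bleu: BleuConfig = field(default_factory=BleuConfig)
    fallback_mode: str = "nearest_code"
    bootstrap_iterations: int = 100
    max_subset_unique: int | None = 300
    use_labeler_for_training: bool = True


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full workflow and write corpus/index/report files.

    Returns the report dict; files land under ``cfg.out_dir``:
    ``corpus.jsonl``, ``index.json``, ``report.json``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # --- load configuration artifacts -------------------------------------
    t0 = _stage("load")
    try:
        vocab = load_vocabulary(cfg.vocab_path)
        rules = load_rule_table(cfg.rules_path, vocab)
        locations = load_location_lexicon(cfg.locations_path)
        negation = load_negation_lexicon(cfg.negation_path)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    timings["load"] = time.perf_counter() - t0

    # --- simulate or ingest ------------------------------------------------
    t0 = _stage("simulate")
    try:
        if cfg.corpus_path is not None:
            records = read_corpus(cfg.corpus_path, vocab)
        else:
            synth_cfg = cfg.synth or SynthConfig(
                n_cases=cfg.n_cases,
                train_fraction=cfg.train_fraction,
                rng_seed=stage_seed(cfg.seed, "simulate"),
            )
            records = generate_experiment(synth_cfg, vocab, location_lexicon=locations)
        write_corpus(records, out_dir / "corpus.jsonl")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    timings["simulate"] = time.perf_counter() - t0

    train = [r for r in records if (r.split or "train") == "train"]
    test = [r for r in records if r.split == "test"]
    if not train:
        raise PipelineError("simulate", "corpus has no training records")

    # --- label training reports -------------------------------------------
    t0 = _stage("label")
    try:
        if cfg.use_labeler_for_training:
            train = [
                ReportRecord(
                    record_id=r.record_id,
                    findings_text=r.findings_text,
                    labels=label_report(r.findings_text, vocab, negation),
                    scores=r.scores,
                    arm=r.arm,
                    split=r.split,
                )
                for r in train
            ]
        elif any(r.labels is None for r in train):
            raise ValueError("training records lack labels and labeling is disabled")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("label", str(exc)) from exc
    timings["label"] = time.perf_counter() - t0

    # --- build the caption index --------------------------------------------
    t0 = _stage("build-index")
    try:
        index = build_index(
            train, vocab, cfg.bleu, locations, max_subset_unique=cfg.max_subset_unique
        )
        save_index(index, out_dir / "index.json")
    except Exception as exc:
        raise PipelineError("build-index", str(exc)) from exc
    timings["build_index"] = time.perf_counter() - t0
    logger.info("index: %d codes from %d training reports", len(index), len(train))

    # --- caption test cases by assigned arm ---------------------------------
    t0 = _stage("caption")
    policy = FallbackPolicy(cfg.fallback_mode)
    normal = normal_template()
    arm_cases = []
    fallback_count = 0
    try:
        for rec in test:
            if rec.scores is None:
                raise ValueError(f"test record {rec.record_id} lacks classifier scores")
            arm = rec.arm or "normal_template"
            pred = labels_from_scores(rec.scores, cfg.threshold)
            if arm == "normal_template":
                caption = normal
            elif arm == "rule_based":
                caption = generate_rule_caption(pred, rules, vocab)
            elif arm == "nlp_generated":
                caption, provenance, _ = generate_caption(pred, index, policy, vocab)
                fallback_count += provenance == "fallback"
            else:
                raise ValueError(f"record {rec.record_id}: unknown arm {arm!r}")
            arm_cases.append((arm, caption, tokenize(rec.findings_text)))
    except Exception as exc:
        raise PipelineError("caption", str(exc)) from exc
    timings["caption"] = time.perf_counter() - t0

    # --- evaluate ------------------------------------------------------------
    t0 = _stage("evaluate")
    try:
        summaries = evaluate_arms(arm_cases, cfg.bleu) if arm_cases else []
        per_sign = {}
        if test and all(r.labels is not None and r.scores is not None for r in test):
            boot_seed = stage_seed(cfg.seed, "bootstrap")
            for sign in vocab:
                sid = sign.sign_id
                pairs = [(r.scores[sid], r.labels.flags[sid]) for r in test]
                ms = classification_metrics(
                    [p[0] for p in pairs], [p[1] for p in pairs], cfg.threshold
                )
                for metric in ("accuracy", "sensitivity", "specificity", "f1"):
                    def stat(sub, _m=metric):
                        m = classification_metrics(
                            [p[0] for p in sub], [p[1] for p in sub], cfg.threshold
                        )
                        return getattr(m, _m)
                    try:
                        ms.ci[metric] = bootstrap_ci(
                            stat, pairs, iterations=cfg.bootstrap_iterations,
                            rng_seed=boot_seed + sid,
                        )
                    except MetricUndefinedError:
                        ms.degenerate_ci = True
                per_sign[sign.canonical_name] = ms.as_dict()
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    timings["evaluate"] = time.perf_counter() - t0

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_train": len(train),
        "n_test": len(test),
        "n_index_codes": len(index),
        "nlp_fallback_count": fallback_count,
        "arms": {s.arm: s.as_dict() for s in summaries},
        "per_sign_metrics": per_sign,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, allow_nan=False) + "\n"
    )
    logger.info("timings: %s", {k: f"{v:.2f}s" for k, v in timings.items()})
    return report
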