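# Methods

## Problem and approach

`cxrcaption` implements a retrieval-based captioning system for frontal
chest radiographs together with the two baselines it is usually compared
against and the evaluation harness for a three-arm comparison.

The unit of description is a 23-sign vocabulary of radiographic findings
(12 lung-parenchyma, 3 mediastinal, 5 pleural, 3 thoracic signs).  Every
case is summarised as a binary label vector over these signs; the
serialised vector (a fixed-width '0'/'1' string read from sign 0) is the
*label code*.

**Retrieval captioning.**  Training reports are tokenized, their location
phrases and numerals blanked (an image classifier carries no location or
size information, so captions must not pretend to), and grouped into
subsets by identical label code.  Within a subset, each member's mean
pairwise BLEU against the other members is computed, and the member with
the largest mean — the BLEU medoid — is stored as that code's caption.  At
serving time the classifier's per-sign scores are binarized (default
threshold 0.5) and the resulting code looked up; an unseen code falls back
to the stored code at minimum Hamming distance (ties: larger subset, then
lexicographically smaller code), and the provenance (`exact`/`fallback`)
is surfaced so evaluation can stratify.

**Rule-based captioning.**  The 23 signs are partitioned into 8
expression subcategories.  Each positive sign emits one sentence from its
subcategory's template ("&lt;sign&gt; is observed …"); a subcategory whose
members are all negative emits its fixed negative sentence (device
subcategories stay silent).  Only subcategory 1 (focal lung densities
including pneumothorax) and its positive/negative sentences follow
published wording; the remaining groupings and sentences are this
package's editable configuration (`data/rules.yaml`), grouped along the
vocabulary's anatomic groups.

**Normal template.**  A fixed normal-findings paragraph, deliberately a
different text from the all-negative rule paragraph, since the two serve
as distinct comparison arms.

## BLEU

The paper-of-record for this family of systems reports BLEU without
specifying the variant, so the package fixes one and states it everywhere:
sentence-level BLEU-4, uniform weights, add-one smoothing on orders ≥ 2,
and a hard zero when there is no unigram overlap (intuitive for short
clinical sentences).  The brevity penalty uses the closest reference
length, ties resolved toward the shorter reference.  Order, weights and
smoothing are configurable (`BleuConfig`); medoid selection uses
single-reference BLEU per pair.

## Medoid selection at scale

Mean pairwise BLEU over a subset of k members costs O(k²) sentence
comparisons, and the all-negative code concentrates a large share of any
realistic corpus.  Two measures keep this tractable without changing the
estimand:

1. identical token sequences are grouped and weighted by multiplicity
   (exactly equivalent to enumerating duplicates, since BLEU of a sequence
   against itself is 1);
2. subsets with more than `max_subset_unique` distinct sequences
   (default 300) are truncated to the most frequent distinct sequences
   (ties by rendered text) before scoring.

The truncation is a deliberate approximation for very large subsets; it is
deterministic, recorded in the index build config, and can be disabled by
passing `max_subset_unique=None`.

## Lexicon labeler

A transparent stand-in for a learned report labeler: a sign is positive
iff one of its lexicon phrases occurs in the text outside negation scope.
Matching is longest-phrase-first and consuming, so "small consolidation"
does not additionally fire "consolidation".  Negation is cue-and-window:
a cue ("no", "without", "absence of", …) negates phrases starting within 6
tokens after it, never across a sentence boundary.  Hedged mentions
("possible consolidation") count as positive.  Cues and window are
configuration (`data/negation.yaml`).

## Synthetic corpus generator

The generator emulates a symptomatic hospital CXR population at desk
scale.  Defaults (chosen once, before any end-to-end evaluation):

| parameter | default | rationale |
|---|---|---|
| prevalences | 0.512 / 0.173 / 0.165 / 0.131 / 0.092 for the five most common signs, 0.02 for the rest | the five printed training-set frequencies of a large symptomatic cohort; remaining signs rare |
| `phrasing_noise` | 0.2 | per-sentence probability of a synonym or verb substitution; gives each label code a dominant phrasing with plausible variation |
| `location_insertion_rate` | 0.5 | half of positive findings carry a location phrase |
| `numeral_insertion_rate` | 0.3 | sizes in mm for measurable lesions |
| `negative_mention_rate` | 0.15 | pertinent negatives radiologists routinely record |
| `classifier_sensitivity` / `specificity` | 0.85 / 0.97 | an idealized CNN operating point; per-sign calls are independent Bernoulli |
| `train_fraction` | 0.7 | split for index building vs testing |

Signs are drawn independently by default; an optional log-odds
co-occurrence tilt (`cooccurrence_tilt`) lets tests probe correlated
signs.  Classifier scores are `0.5 ± 0.5·Beta(2,4)` conditioned on the
binary call, so thresholding at 0.5 reproduces the calls exactly.

What the generator does **not** model: resident editing of served captions
(the generated findings text doubles as the final report), reporting
time, real sign co-occurrence structure, non-English source reports, and
free-text pathology outside the 23-sign vocabulary.  Passing end-to-end
tests therefore demonstrate internal consistency of the algorithms under
a plausible text model, not clinical performance.

## Evaluation

Per-sign classification metrics: AUC (midrank tie handling — identical to
all-pairs counting with ties scored ½), area under the precision-recall
curve by step integration, and accuracy/sensitivity/specificity/F1 from
the confusion matrix at the score threshold.  Confidence intervals follow
a 100-iteration scheme in which each iteration recomputes the statistic on
a 95% subsample drawn *without* replacement and the 2.5th/97.5th
percentiles are reported; this is the stated procedure of the study design
this harness mirrors, and a classical with-replacement bootstrap is
available behind `with_replacement=True`.  Note the 95%-subsample interval
is much narrower than a classical bootstrap interval: it measures
stability under small data perturbations rather than full sampling
variability.

Arm comparison: per-case BLEU of the served caption against the final
report, summarised per arm as mean ± SD, with two-sided Welch t tests
between arms (arms have unequal n; the equal-variance variant is available
via `equal_var=True`).  Arm assignment hashes (seed, case id) with SHA-256,
giving a reproducible, marginally uniform 1:1:1 randomization.

## Pipeline and determinism

`run_pipeline` chains simulate → label (lexicon labeler on training text)
→ build-index → caption-by-arm → evaluate, writing `corpus.jsonl`,
`index.json` and `report.json`.  A single master seed fans out to
per-stage seeds by hashing the stage name (`stage_seed`), so every stage
can be rerun in isolation and the whole run is a pure function of
(config, seed); reruns are byte-identical.

## Numerical and design notes

- Medoid ties break by highest mean BLEU, then shorter sequence, then
  lexicographic rendered text; index construction is therefore invariant
  to corpus order.
- Number masking targets digit tokens (optionally with decimal point or a
  glued unit); spelled-out numbers are not masked.
- A "token sequence" is the whole findings paragraph, not a sentence: one
  label code per case, matching per-image classifier output at serving
  time.
- Duplicated token sequences within a subset are kept (as multiplicity
  weights): common phrasings legitimately dominate the medoid.
- The end-to-end similarity ordering check uses 5,000 training and 1,500
  test cases, sizes at which every label code of interest accumulates a
  non-trivial subset while a full run stays in the one-minute range.
- Mean BLEU values on the synthetic study (≈0.33 / 0.13 / 0.06 for
  retrieval / rule-based / normal template at the default settings) are
  lower than values reported on real hospital data; the generator's
  random pertinent negatives and location/size insertions put a ceiling on
  achievable similarity.  The qualitative ordering and the gaps between
  arms are the reproducible quantity.

## Known limitations

- The rule table beyond subcategory 1, all sign synonym lexicons, the
  location lexicon and the normal template are authored configuration,
  not published material.
- The lexicon labeler has no uncertainty handling and a fixed negation
  window; it is calibrated to the generator's grammar (100% round-trip at
  zero phrasing noise), not to real reports.
- Subset truncation (above) makes medoids of very large subsets
  approximate.
- BLEU is computed per case and averaged; no corpus-level pooling.
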