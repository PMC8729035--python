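# Methods

This note documents the models, conventions and design choices behind
`ptmppi`, and what the synthetic test suite does and does not demonstrate.

## Data model and conventions

Character offsets are 0-based half-open `[start, end)`; under this
convention a span printed as `137–141, AKT1` covers exactly the four
characters of `AKT1`. Protein pairs are undirected and canonicalized to
lexicographic accession order everywhere (sample pairs, triplet keys,
participant-marker assignment). The label vocabulary is six PTM types
(phosphorylation, dephosphorylation, methylation, acetylation,
ubiquitination, deubiquitination) plus one `Negative` class; the vocabulary
is configurable at the readers.

The knowledge-base extract is read as a minimal 4-column TSV rather than a
full MITAB parse: only the document id, the two accessions and the
interaction type feed the pipeline. Mention annotations use the
PubTator-style 6-column layout produced by gene NER/normalization tools;
offsets are assumed to be character-based (the format itself does not say).

## Dataset construction

Order of operations: exact-duplicate collapse (unordered pair + document +
type, first occurrence kept) → self-relation removal → abstract-availability
check → normalization → noise filter → negative generation → split. Rows
whose abstract is unavailable are dropped with a logged reason.

**Gene→accession mapping.** A gene id maps to an ordered accession list.
If any candidate equals an annotated participant, that participant wins;
otherwise the first accession is returned. List order is therefore
semantically meaningful and preserved exactly by the readers.

**Noise filter.** A positive sample is kept iff both participant
accessions occur in the normalized abstract and the label's trigger stem is
mentioned. Stems: `phosphoryl`, `dephosphoryl`, `methyl`, `demethyl`,
`acetyl`, `ubiquitin`, `deubiquitin`. Matching is case-insensitive
substring on the normalized text, with one disambiguation: a base-stem
match (`phosphoryl`, `methyl`, `ubiquitin`) immediately preceded by `de`
does not count, otherwise "dephosphorylation" would satisfy a
phosphorylation label and leak across complementary types. The plain
substring behaviour remains available behind `reject_de_prefix=False`.
Only the stem of the sample's own label is required, not any stem. The
filter runs on the normalized abstract; raw and normalized text share all
non-entity characters, so the choice only matters if an accession string
itself contains a stem, which the accession format precludes.

**Negatives.** Every unordered pair of distinct mentioned accessions not
annotated for the abstract is emitted once as `Negative` — including pairs
whose annotated positive was dropped by the noise filter, which stay
excluded: a noisy knowledge-base row is still an annotation, not evidence
of absence.

**Split.** Document-level, stratified by label. Documents are assigned
greedily, largest label-load first with seeded tie shuffling, each to the
part where it least increases the total per-label deviation from the ratio
quotas; labels are weighted inversely by frequency so rare PTM classes are
balanced as carefully as the Negative bulk. On corpora with one positive
per document this lands within one document of every per-class ratio
target. Default ratios 0.7/0.1/0.2. The algorithm is a design choice; the
constraints (stratification, disjoint PubMed ids) are the contract.

## Classifier input

Participants are masked as `PROTPART1`/`PROTPART2` with `PROTPART1` the
lexicographically smaller accession, making masking symmetric in the pair
and extraction deterministic; since the relation is undirected the label is
unaffected by this choice. Bystander accessions become `PRTIG1..PRTIGn`,
numbered by first occurrence. Masking is invertible via the stored
marker map. Inputs are truncated to a 512-unit budget with 2 units reserved
for boundary markers (payload 510), prefix-preserving, with the tokenizer
injected (whitespace at test scale; a sub-word tokenizer would slot in
unchanged because truncation semantics are tokenizer-independent).

## Reference backbone

The classifier contract is `predict_proba(masked_text) → 7-vector`; any
model satisfying it drops into calibration and extraction unchanged. The
shipped reference backbone is a multinomial logistic model over unigram +
adjacent-bigram bag features, trained by seeded mini-batch SGD
(defaults: 30 epochs, batch 32, learning rate 0.5, L2 1e-4) with 30%
Bernoulli feature dropout. Dropout plus seed-dependent shuffling gives
ensemble members genuine disagreement, which the confidence-variation
machinery needs. Bigrams matter: a negative pair from the same abstract
shares every unigram with the positive pair, and only marker-adjacent
bigrams (e.g. `of__protpart2`) make the trigger–participant association
linearly separable.

The best epoch is snapshot by **validation macro-F1** rather than lowest
loss, which favours minority classes under heavy imbalance; ties keep the
earliest epoch, and `snapshot_best=False` keeps the final epoch instead.
Class imbalance is handled only through this checkpoint metric — no
reweighting. Ensembles of M models (default 10) differ only in seed
(`base_seed + i`), so training order is irrelevant.

## Calibration and selective prediction

Ensemble aggregation is the member mean; the prediction is its argmax
(lowest index on ties), the confidence its maximum, and the confidence SD
the population standard deviation (divisor M) of the members' probability
for the predicted class — exactly zero when members agree exactly.

ECE uses K = 10 equally spaced bins, half-open `(lo, hi]` with the first
bin closed at 0; empty bins contribute zero. The scored population is
configurable: all predictions, or (default for reporting) only
positive-class predictions — thresholding and human evaluation operate on
positive predictions, so that is the population whose calibration matters.

Per-class dual thresholds take a percentile (default the 50th, linear
interpolation) of the confidences and confidence SDs of the train-set
predictions of each **predicted** class — predicted, not gold, because at
inference gold is unknown. Selection is inclusive on both cutoffs
(confidence ≥ minimum, SD ≤ maximum); classes with no train predictions are
omitted with a warning and their predictions rejected. Negative-class
predictions are never selected as triplets.

## Extraction

Abstracts are processed independently with constant memory per document:
enumerate the C(n,2) pairs of the n unique mentioned accessions
(lexicographic order, no self-pairs), mask, score, and emit positive
predictions as canonical triplets. Triplet keys include the PTM — the
at-most-one-PTM-per-pair assumption applies per prediction, so the same
pair may surface with different PTMs from different abstracts. Support is
counted in distinct PubMed ids (an abstract contributing the same triplet
twice counts once); the multi-abstract filter keeps triplets with support
≥ 2, computed over the high-quality tier, so the tiers nest:
all ⊇ high-quality ⊇ multi-abstract.

## Evaluation

Micro and macro averages are over positive classes with Negative as
background: micro recall = correct positive predictions / gold positives,
micro precision = correct positive predictions / positive predictions, and
the macro average is the unweighted mean over positive classes with gold
support. Human-evaluation precision counts `Not-sure` verdicts in the
denominator (an unconfirmable prediction is not a correct one), while
error-category shares exclude them (they are not errors); headline
precisions round to 1 decimal, shares to the nearest integer, and a
truncation mode exists because one released per-PTM figure was printed
truncated. Similarity diagnostics use lowercase unigram count vectors
(split on non-alphanumerics) and cosine similarity; the stop-word list for
common-word summaries is a small default and configurable, as these
diagnostics are qualitative.

`ptmppi.reference_tables` stores the released human-evaluation,
knowledge-base-comparison and noise-audit count tables of the original
full-scale extraction run; the package recomputes all percentages from
those counts rather than hard-coding them.

## Synthetic fixtures

The corpus generator emulates every external input: abstracts built from
template sentences with UniProt-pattern accessions, gene-mention
annotations with exact spans, candidate lists where participants hide
behind decoys (exercising the annotated-match rule) while bystanders lead
their lists (exercising the fallback), knowledge-base rows, and distractor
sentences with off-type trigger words. Noise is planted exactly:
false-positive rows lack the trigger word or a participant mention;
false-negative relations are described in text but unannotated; a ledger
records every planted fact, so recovery tests compare filter decisions to
ground truth row by row, not just in aggregate. The default PTM mix is
phosphorylation-heavy (73/16/5/3/2/1), mirroring curated PTM interaction
databases; tests that need every class well-supported pass a balanced mix
explicitly.

The ensemble simulator draws a per-sample true posterior peaked at
`true_accuracy` (default 0.7) on a prior-sampled class, samples the gold
label from it, and has members report
`softmax(temperature · log p + jitter · noise)`. Temperature 1 with zero
jitter is perfectly calibrated by construction; temperature > 1 is
overconfident; jitter creates inter-member variance. The default class
prior is heavily Negative-skewed like the real task.

What passing tests show: the arithmetic of every operation, the exactness
of the aggregation/ECE formulas, planted-parameter recovery, and the
qualitative calibration phenomena (near-zero ECE when calibrated, ECE
monotone in distortion, ensemble averaging beating individual overconfident
members, threshold selection raising precision). What they do not show:
performance on natural language — template sentences have none of the
lexical variety, negation, or discourse structure of real abstracts, so
classifier scores here say nothing about real-corpus F1.

## Problem sizes and numerical choices

Synthetic suites use 240–500 documents, ensembles of 10 models, and
10,000-sample calibration simulations, sized so the full pipeline remains a
seconds-scale computation. Formula-oracle comparisons use 1,000 random
instances at 1e-12 tolerance; stochastic calibration assertions aggregate
over 20–24 seeds; noise-recovery assertions use binomial interval bounds.
All randomness is seeded; datasets, training and extraction are
byte-deterministic given inputs and seed.

## Known limitations

- The reference backbone is a linear bag-of-features model: adequate for
  contract exercise and template corpora, not a substitute for a
  fine-tuned transformer on real text.
- Direction (enzyme vs. substrate) and modification sites are out of
  scope; triplets are undirected and site-free.
- UniProt isoform semantics are not resolved; the first-accession fallback
  is a heuristic that can pick a non-canonical accession.
- The stem-based trigger filter cannot distinguish protein methylation
  from DNA methylation, a known error mode of the approach.
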