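# ptmppi

Distant-supervision extraction of post-translational-modification (PTM)
annotated protein–protein interactions (PPIs) from biomedical abstracts,
with ensemble confidence calibration and selective prediction.

## The problem

Interaction databases curate hundreds of thousands of human PPIs, but only a
small fraction carry a PTM annotation (phosphorylation, acetylation,
methylation, ubiquitination and their reversals), because PTM curation is
manual. This package implements a literature-mining pipeline that surfaces
candidate triplets `<ProteinA, PTM, ProteinB>` (UniProt accessions,
undirected) from abstracts to support human curators:

1. **Dataset construction by distant supervision.** Knowledge-base rows
   `<PubMed id, UniProtA, UniProtB, PTM type>` are projected onto
   gene-annotated abstracts: duplicates (unordered pair + document + type)
   and self-relations are removed, each gene mention is rewritten to a
   UniProt accession (preferring an annotated participant in the gene's
   candidate list, falling back to the first accession), noisy positives are
   dropped when a participant accession or the label's trigger stem
   (`phosphoryl`, `methyl`, `acetyl`, ...) is absent from the abstract, and
   every co-mentioned but unannotated pair becomes a `Negative` sample. The
   train/validation/test split is at document level, stratified by
   interaction type, so no PubMed id leaks between splits.
2. **Entity-masked relation classification.** For a candidate pair the two
   participants are replaced by `PROTPART1`/`PROTPART2` and every bystander
   protein by `PRTIG1..PRTIGn`; the classifier is a pluggable 7-way
   probabilistic backbone (6 PTMs + Negative). A seeded bag-of-features
   multinomial logistic reference backbone with mini-batch SGD and feature
   dropout is included; checkpoints are selected by validation macro-F1.
3. **Ensemble confidence calibration.** An ensemble of M models (default
   M = 10, identical except for seed) is aggregated per input x_j:

       p(y_j = c) = (1/M) Σ_i p(y_i = c | x_j)        (member mean)
       p̂_j = max_c p(y_j = c),  ŷ_j = argmax_c p(y_j = c)
       std(p̂_j) = sqrt( (1/M) Σ_i (p(y_i = ŷ_j | x_j) − p̂_j)² )

   Calibration is measured by expected calibration error over K = 10
   equally spaced confidence bins,
   `ECE = Σ_k (|B_k|/n)·|accu(B_k) − conf(B_k)|`.
4. **Selective prediction and large-scale extraction.** Per-class dual
   cutoffs — a minimum confidence and a maximum confidence SD, both the
   train-set median of that class's predictions — keep minority PTM classes
   on their own confidence scale. At corpus scale every abstract's C(n,2)
   protein pairs are scored; positive predictions become canonical
   triplets, deduplicated with per-triplet document support, and optionally
   restricted to triplets seen in ≥ 2 distinct abstracts.
5. **Evaluation utilities.** Positive-class micro/macro metrics (Negative
   as background), human-evaluation table aggregation, knowledge-base
   recall, train-set cosine-similarity diagnostics and common-word
   summaries. A synthetic-fixtures module generates corpora with planted
   relations and controllable false-positive/false-negative noise, and
   simulated ensembles with controllable miscalibration, so the entire
   pipeline is testable offline.

## Worked example

The package ships a fully traced one-document example (a synthetic
reconstruction of a glucocorticoid-resistance abstract in which the AKT1
kinase phosphorylates the NR3C1 receptor):

```python
from ptmppi import worked_example as we
from ptmppi.kb_dataset import normalize_abstract, generate_negatives
from ptmppi.transform import mask_participants

annotated = (we.INTERACTION.iu1, we.INTERACTION.iu2)   # P04150, P31749
na = normalize_abstract(we.PUBMED_ID, we.ABSTRACT, we.MENTIONS,
                        we.ID_MAPPING, annotated)
print(na.unique_accessions())
print(sorted(n.pair for n in generate_negatives(na, [annotated])))
print(dict(mask_participants(na, annotated).marker_map))
```

prints

```
['P31749', 'P04150', 'P60484']
[('P04150', 'P60484'), ('P31749', 'P60484')]
{'PROTPART2': 'P31749', 'PROTPART1': 'P04150', 'PRTIG1': 'P60484'}
```

AKT1 (gene 207) and NR3C1 (gene 2908) resolve to the annotated participants
P31749 and P04150 even though neither is first in its candidate list, while
the bystander PTEN (gene 5728) falls back to the first accession P60484 and
becomes `PRTIG1`; the two pairs involving P60484 are emitted as negatives.
The masked classifier input reads "… PROTPART2 impairs
glucocorticoid-induced gene expression by direct phosphorylation of
PROTPART1 …" (participant markers are assigned in canonical lexicographic
order).

A command-line interface covers the full pipeline (`ptmppi build-dataset`,
`train`, `calibrate`, `report-calibration`, `extract`, `filter`,
`human-eval`, `kb-recall`, `simulate-corpus`); see `ptmppi --help`.

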