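"""Published evaluation counts for the original large-scale extraction run.

The full-scale run (an ensemble of ten fine-tuned biomedical transformers
applied to 18 million abstracts) is far beyond desk scale, but its human
evaluation and knowledge-base comparison were released as count tables.
These counts are inputs to the aggregation operations in
:mod:`ptmppi.evaluation`; reproducing the headline percentages from them
is pure arithmetic and serves as a worked example of those operations.
"""

from __future__ import annotations

#: Human verdicts on a random sample of high-quality predictions
#: (30 per PTM where available). category -> PTM -> count.
HUMAN_EVAL_HIGH_QUALITY: dict[str, dict[str, int]] = {
    "Correct": {
        "acetylation": 0,
        "dephosphorylation": 11,
        "methylation": 11,
        "phosphorylation": 6,
        "ubiquitination": 0,
    },
    "Incorrect-DNA-methylation": {
        "acetylation": 0,
        "dephosphorylation": 0,
        "methylation": 2,
        "phosphorylation": 0,
        "ubiquitination": 0,
    },
    "Incorrect-NER": {
        "acetylation": 0,
        "dephosphorylation": 2,
        "methylation": 1,
        "phosphorylation": 3,
        "ubiquitination": 0,
    },
    "Incorrect-no-trigger-word": {
        "acetylation": 0,
        "dephosphorylation": 1,
        "methylation": 0,
        "phosphorylation": 2,
        "ubiquitination": 4,
    },
    "Incorrect-opposite-type": {
        "acetylation": 0,
        "dephosphorylation": 1,
        "methylation": 0,
        "phosphorylation": 0,
        "ubiquitination": 0,
    },
    "Incorrect-relationship-not-described": {
        "acetylation": 0,
        "dephosphorylation": 14,
        "methylation": 4,
        "phosphorylation": 19,
        "ubiquitination": 0,
    },
    "Not-sure": {
        "acetylation": 1,
        "dephosphorylation": 0,
        "methylation": 1,
        "phosphorylation": 0,
        "ubiquitination": 0,
    },
}

#: Human verdicts on the multi-abstract-supported subset of the above.
HUMAN_EVAL_MULTI_ABSTRACT: dict[str, dict[str, int]] = {
    "Correct": {"methylation": 4, "phosphorylation": 16},
    "Incorrect-NER": {"methylation": 0, "phosphorylation": 2},
    "Incorrect-not-related-to-PPI": {"methylation": 0, "phosphorylation": 1},
    "Incorrect-relationship-not-described": {"methylation": 0, "phosphorylation": 7},
    "Not-sure": {"methylation": 0, "phosphorylation": 4},
}

#: Comparison with a curated PTM knowledge base (per-PTM counts).
#: reference_with_uniprot = unique reference triplets carrying UniProt ids;
#: matched = extracted triplets found in the reference; matched_hq = the
#: high-quality subset of those; rule_based = reference triplets sourced by
#: the incumbent rule-based text-mining system.
KB_COMPARISON: dict[str, dict[str, int]] = {
    "acetylation": {
        "reference_total": 141,
        "reference_unique": 73,
        "reference_with_uniprot": 12,
        "matched": 0,
        "matched_hq": 0,
        "rule_based": 0,
    },
    "methylation": {
        "reference_total": 7,
        "reference_unique": 4,
        "reference_with_uniprot": 4,
        "matched": 0,
        "matched_hq": 0,
        "rule_based": 0,
    },
    "phosphorylation": {
        "reference_total": 21050,
        "reference_unique": 8949,
        "reference_with_uniprot": 8805,
        "matched": 3270,
        "matched_hq": 815,
        "rule_based": 358,
    },
    "ubiquitination": {
        "reference_total": 2,
        "reference_unique": 1,
        "reference_with_uniprot": 0,
        "matched": 0,
        "matched_hq": 0,
        "rule_based": 0,
    },
}

#: Label-quality audit of the noise-reduced training data:
#: PTM -> (correct, not_sure) verdict counts.
TRAINING_NOISE_AUDIT: dict[str, tuple[int, int]] = {
    "acetylation": (4, 1),
    "dephosphorylation": (6, 4),
    "deubiquitination": (1, 1),
    "methylation": (4, 6),
    "phosphorylation": (6, 4),
    "ubiquitination": (2, 3),
}
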