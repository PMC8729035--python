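"""Corpus-scale triplet extraction.

Each abstract is processed independently (constant memory per document): the
C(n,2) unordered pairs of its mentioned proteins are enumerated, masked,
scored by the ensemble, and positive predictions are emitted as canonical
undirected <ProteinA, PTM, ProteinB> triplets. Quality tiers: all
predictions, high-quality (passing the per-class dual thresholds), and
high-quality supported by at least two distinct abstracts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .backbone import BackboneModel, ensemble_member_probs
from .calibration import ensemble_aggregate
from .transform import enumerate_pairs, mask_participants
from .types import (
    ALL_LABELS,
    NEGATIVE_LABEL,
    ClassThresholds,
    ExtractionSummary,
    NormalizedAbstract,
    TripletPrediction,
    canonical_pair,
)


def extract_from_abstract(
    normalized: NormalizedAbstract,
    models: Sequence[BackboneModel],
    thresholds: ClassThresholds | None = None,
) -> list[TripletPrediction]:
    """Predict every enumerated pair of one abstract; emit positive triplets.

    Negative-class predictions are evaluated but not emitted. When
    ``thresholds`` is given, each triplet's ``high_quality`` flag records
    the dual-threshold decision.
    """
    accs = normalized.unique_accessions()
    out: list[TripletPrediction] = []
    for pair in enumerate_pairs(accs):
        masked = mask_participants(normalized, pair)
        member = ensemble_member_probs(models, masked.text)
        agg = ensemble_aggregate(
            member,
            sample_id=f"{normalized.pubmed_id}:{pair[0]}-{pair[1]}",
            labels=models[0].labels,
        )
        if agg.pred_class == NEGATIVE_LABEL:
            continue
        hq = False
        if thresholds is not None and thresholds.covers(agg.pred_class):
            hq = (
                agg.confidence >= thresholds.conf_min[agg.pred_class]
                and agg.confidence_sd <= thresholds.sd_max[agg.pred_class]
            )
        out.append(
            TripletPrediction(
                pair=pair,
                ptm=agg.pred_class,
                pubmed_id=normalized.pubmed_id,
                confidence=agg.confidence,
                confidence_sd=agg.confidence_sd,
                high_quality=hq,
            )
        )
    return out


@dataclass(frozen=True)
class UniqueTriplet:
    """A deduplicated triplet with its distinct supporting documents."""

    pair: tuple[str, str]
    ptm: str
    support: tuple[str, ...]  # sorted distinct PubMed ids

    @property
    def n_abstracts(self) -> int:
        return len(self.support)


def dedupe_triplets(predictions: Iterable[TripletPrediction]) -> list[UniqueTriplet]:
    """Collapse predictions to unique (canonical pair, PTM) triplets.

    Support is the set of distinct PubMed ids contributing the triplet.
    Output is sorted by (pair, ptm) for determinism.
    """
    support: dict[tuple[tuple[str, str], str], set[str]] = defaultdict(set)
    for p in predictions:
        support[(canonical_pair(*p.pair), p.ptm)].add(p.pubmed_id)
    return [
        UniqueTriplet(pair=key[0], ptm=key[1], support=tuple(sorted(ids)))
        for key, ids in sorted(support.items())
    ]


def multi_abstract_filter(
    triplets: Iterable[UniqueTriplet], min_abstracts: int = 2
) -> list[UniqueTriplet]:
    """Keep triplets supported by at least ``min_abstracts`` distinct documents."""
    return [t for t in triplets if t.n_abstracts >= min_abstracts]


def summarize_extraction(
    predictions: Sequence[TripletPrediction],
    ptm_types: Sequence[str] = tuple(l for l in ALL_LABELS if l != NEGATIVE_LABEL),
) -> ExtractionSummary:
    """Tiered per-PTM counts: all / high-quality / multi-abstract, with uniques.

    The multi-abstract tier is computed over high-quality predictions only,
    so the tiers are nested at both prediction and unique-triplet level.
    """
    summary = ExtractionSummary()
    hq_preds = [p for p in predictions if p.high_quality]
    hq_unique = dedupe_triplets(hq_preds)
    ma_keys = {
        (t.pair, t.ptm) for t in multi_abstract_filter(hq_unique)
    }
    ma_preds = [p for p in hq_preds if (p.pair, p.ptm) in ma_keys]
    for ptm in ptm_types:
        rows = [p for p in predictions if p.ptm == ptm]
        hq_rows = [p for p in hq_preds if p.ptm == ptm]
        ma_rows = [p for p in ma_preds if p.ptm == ptm]
        summary.per_ptm[ptm] = {
            "all": len(rows),
            "all_unique": len(dedupe_triplets(rows)),
            "high_quality": len(hq_rows),
            "high_quality_unique": len(dedupe_triplets(hq_rows)),
            "multi_abstract": len(ma_rows),
            "multi_abstract_unique": len(dedupe_triplets(ma_rows)),
        }
    return summary


__all__ = [
    "extract_from_abstract",
    "UniqueTriplet",
    "dedupe_triplets",
    "multi_abstract_filter",
    "summarize_extraction",
]
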