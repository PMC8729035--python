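"""Distantly supervised dataset construction.

The builder projects knowledge-base PTM interactions onto gene-annotated
abstracts: deduplicate and drop self-relations, replace gene mentions with
UniProt accessions (preferring the annotated participant over the mapping's
first entry), drop positives whose participants or trigger stem are absent
from the abstract (false-positive noise reduction), enumerate co-mentioned
but unannotated pairs as negatives, and split at document level stratified by
interaction type so no PubMed id leaks across train/validation/test.
"""

from __future__ import annotations

import json
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .types import (
    NEGATIVE_LABEL,
    CorpusBundle,
    DatasetSplit,
    GeneMention,
    InteractionRecord,
    LabeledSample,
    NormalizedAbstract,
    canonical_pair,
)

#: Trigger stem required in the abstract for each positive label.
TRIGGER_STEMS: dict[str, str] = {
    "phosphorylation": "phosphoryl",
    "dephosphorylation": "dephosphoryl",
    "methylation": "methyl",
    "demethylation": "demethyl",
    "acetylation": "acetyl",
    "ubiquitination": "ubiquitin",
    "deubiquitination": "deubiquitin",
}

#: Stems whose match must not be immediately preceded by "de", otherwise the
#: reversal PTM would satisfy the base label (e.g. "dephosphorylation" would
#: count as a phosphorylation trigger).
_DE_PREFIXED = {"phosphoryl", "methyl", "ubiquitin"}


def deduplicate(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse exact duplicates (unordered pair + PubMed id + type).

    The first occurrence is kept; order is otherwise preserved.
    """
    seen: set[tuple] = set()
    out: list[InteractionRecord] = []
    for r in records:
        key = (r.pubmed_id, r.pair, r.ptm_type)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def remove_self_relations(
    records: Sequence[InteractionRecord],
) -> list[InteractionRecord]:
    """Drop rows where both participants are the same accession."""
    return [r for r in records if r.iu1 != r.iu2]


def map_gene_to_uniprot(
    ncbi_gene_id: int,
    candidates: Sequence[str],
    annotated: Iterable[str],
) -> str:
    """Resolve a gene id to one accession from its ordered candidate list.

    If any candidate equals an annotated participant accession, that
    participant is returned; otherwise the first candidate is the fallback.
    """
    if not candidates:
        raise ValueError(f"gene {ncbi_gene_id} has an empty candidate list")
    annotated_set = set(annotated)
    for u in candidates:
        if u in annotated_set:
            return u
    return candidates[0]


def normalize_abstract(
    pubmed_id: str,
    text: str,
    mentions: Sequence[GeneMention],
    id_mapping: Mapping[int, Sequence[str]],
    annotated: Iterable[str] = (),
) -> NormalizedAbstract:
    """Replace each gene mention in-place with its mapped UniProt accession.

    Mentions must be non-overlapping and match the text slice exactly; the
    surrounding text is preserved byte-for-byte and entity spans are
    recomputed for the rewritten text.
    """
    ordered = sorted(mentions, key=lambda m: m.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping mentions at [{prev.start},{prev.end}) and "
                f"[{cur.start},{cur.end}) in {pubmed_id}"
            )
    annotated = tuple(annotated)
    pieces: list[str] = []
    entities: list[tuple[str, tuple[int, int]]] = []
    cursor = 0
    out_len = 0
    for m in ordered:
        if m.end > len(text) or text[m.start : m.end] != m.text:
            raise ValueError(
                f"mention {m.text!r} at [{m.start},{m.end}) does not match "
                f"abstract {pubmed_id}"
            )
        if m.ncbi_gene_id not in id_mapping:
            raise KeyError(f"gene {m.ncbi_gene_id} missing from id mapping")
        acc = map_gene_to_uniprot(m.ncbi_gene_id, id_mapping[m.ncbi_gene_id], annotated)
        gap = text[cursor : m.start]
        pieces.append(gap)
        out_len += len(gap)
        entities.append((acc, (out_len, out_len + len(acc))))
        pieces.append(acc)
        out_len += len(acc)
        cursor = m.end
    pieces.append(text[cursor:])
    return NormalizedAbstract(pubmed_id, "".join(pieces), tuple(entities))


@dataclass(frozen=True)
class FilterDecision:
    kept: bool
    reason: str = ""  # "missing-participant" | "missing-trigger" | ""


def trigger_present(text: str, label: str, *, reject_de_prefix: bool = True) -> bool:
    """Case-insensitive stem search for ``label``'s trigger in ``text``.

    With ``reject_de_prefix`` (default) a base-stem match immediately
    preceded by "de" does not count, so "dephosphorylation" alone never
    satisfies a phosphorylation label.
    """
    stem = TRIGGER_STEMS[label]
    low = text.lower()
    pos = low.find(stem)
    while pos != -1:
        if not (
            reject_de_prefix
            and stem in _DE_PREFIXED
            and pos >= 2
            and low[pos - 2 : pos] == "de"
        ):
            return True
        pos = low.find(stem, pos + 1)
    return False


def noise_filter(sample: LabeledSample, *, reject_de_prefix: bool = True) -> FilterDecision:
    """Keep a positive sample only if the abstract plausibly describes it.

    Kept iff both participant accessions occur in the normalized text and
    the label's trigger stem is mentioned. Dropped samples carry a
    machine-readable reason.
    """
    if sample.label == NEGATIVE_LABEL:
        raise ValueError("noise_filter applies to positive samples only")
    if sample.pair[0] not in sample.text or sample.pair[1] not in sample.text:
        return FilterDecision(False, "missing-participant")
    if not trigger_present(sample.text, sample.label, reject_de_prefix=reject_de_prefix):
        return FilterDecision(False, "missing-trigger")
    return FilterDecision(True)


def generate_negatives(
    normalized: NormalizedAbstract,
    positive_pairs: Iterable[tuple[str, str]],
) -> list[LabeledSample]:
    """Emit every co-mentioned unannotated distinct pair as a Negative.

    Pairs are canonical and each is emitted once; output order is
    lexicographic for determinism.
    """
    annotated = {canonical_pair(*p) for p in positive_pairs}
    accs = sorted(set(normalized.unique_accessions()))
    out: list[LabeledSample] = []
    for i, a in enumerate(accs):
        for b in accs[i + 1 :]:
            if (a, b) not in annotated:
                out.append(
                    LabeledSample(
                        pubmed_id=normalized.pubmed_id,
                        pair=(a, b),
                        label=NEGATIVE_LABEL,
                        text=normalized.text,
                    )
                )
    return out


def split_dataset(
    samples: Sequence[LabeledSample],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified document-level split with disjoint PubMed-id sets.

    All samples sharing a PubMed id land in one part. Documents are
    assigned greedily, largest label-load first with seeded tie shuffling,
    each to the part where it least increases the total per-label deviation
    from the ratio quotas (labels weighted inversely by frequency so rare
    PTM classes are balanced as carefully as the Negative bulk), which
    keeps per-PTM proportions as close to ``ratios`` as document
    granularity allows.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    parts = ("train", "val", "test")
    by_doc: dict[str, list[LabeledSample]] = defaultdict(list)
    for s in samples:
        by_doc[s.pubmed_id].append(s)

    label_totals: Counter = Counter()
    doc_counts: dict[str, Counter] = {}
    for pmid, ss in by_doc.items():
        c = Counter(s.label for s in ss)
        doc_counts[pmid] = c
        label_totals.update(c)

    weights = {lab: 1.0 / n for lab, n in label_totals.items()}
    rng = random.Random(seed)
    docs = sorted(by_doc)
    rng.shuffle(docs)  # seeded tie order
    docs.sort(key=lambda p: -sum(doc_counts[p].values()))

    assigned: dict[str, Counter] = {p: Counter() for p in parts}
    placement: dict[str, str] = {}
    for pmid in docs:
        c = doc_counts[pmid]
        best, best_cost = None, None
        for j, part in enumerate(parts):
            # marginal increase in weighted deviation from the quotas
            cost = 0.0
            for lab, n in c.items():
                quota = ratios[j] * label_totals[lab]
                a = assigned[part][lab]
                cost += weights[lab] * (abs(a + n - quota) - abs(a - quota))
            if best_cost is None or cost < best_cost:
                best, best_cost = part, cost
        placement[pmid] = best
        assigned[best].update(c)

    buckets: dict[str, list[LabeledSample]] = {p: [] for p in parts}
    for s in samples:
        part = placement[s.pubmed_id]
        buckets[part].append(
            LabeledSample(s.pubmed_id, s.pair, s.label, s.text, split=part)
        )
    return DatasetSplit(buckets["train"], buckets["val"], buckets["test"], seed)


@dataclass
class BuildReport:
    """Bookkeeping emitted alongside a built dataset."""

    kb_rows: int = 0
    after_dedup: int = 0
    after_self_removal: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    positives_kept: int = 0
    negatives: int = 0
    per_split_per_label: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def build_dataset(
    bundle: CorpusBundle,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    *,
    reject_de_prefix: bool = True,
) -> tuple[DatasetSplit, BuildReport]:
    """Run the full dataset construction pipeline on one corpus bundle.

    Order of operations: deduplicate -> self-relation removal -> abstract
    availability check -> normalization -> noise filter -> negative
    generation -> stratified document split.
    """
    report = BuildReport(kb_rows=len(bundle.interactions))
    records = deduplicate(bundle.interactions)
    report.after_dedup = len(records)
    records = remove_self_relations(records)
    report.after_self_removal = len(records)

    drops: Counter = Counter()
    by_doc: dict[str, list[InteractionRecord]] = defaultdict(list)
    for r in records:
        if r.pubmed_id not in bundle.abstracts:
            drops["missing-abstract"] += 1
            continue
        by_doc[r.pubmed_id].append(r)

    samples: list[LabeledSample] = []
    for pmid in sorted(by_doc):
        recs = by_doc[pmid]
        text = bundle.abstracts[pmid]
        mentions = bundle.mentions.get(pmid, [])
        annotated = sorted({a for r in recs for a in (r.iu1, r.iu2)})
        try:
            normalized = normalize_abstract(
                pmid, text, mentions, bundle.id_mapping, annotated
            )
        except (ValueError, KeyError):
            drops["normalization-failed"] += len(recs)
            continue
        kept_pairs: list[tuple[str, str]] = []
        for r in recs:
            cand = LabeledSample(pmid, r.pair, r.ptm_type, normalized.text)
            decision = noise_filter(cand, reject_de_prefix=reject_de_prefix)
            if decision.kept:
                samples.append(cand)
                kept_pairs.append(r.pair)
            else:
                drops[decision.reason] += 1
        # negatives are generated against everything annotated for the
        # abstract (kept or dropped): a dropped noisy positive is still
        # annotated in the knowledge base, so its pair is not a negative.
        samples.extend(generate_negatives(normalized, [r.pair for r in recs]))

    report.dropped = dict(drops)
    report.positives_kept = sum(1 for s in samples if s.label != NEGATIVE_LABEL)
    report.negatives = sum(1 for s in samples if s.label == NEGATIVE_LABEL)

    split = split_dataset(samples, ratios, seed)
    for part in ("train", "val", "test"):
        counts = Counter(s.label for s in getattr(split, part))
        report.per_split_per_label[part] = dict(counts)
    return split, report


__all__ = [
    "TRIGGER_STEMS",
    "deduplicate",
    "remove_self_relations",
    "map_gene_to_uniprot",
    "normalize_abstract",
    "trigger_present",
    "noise_filter",
    "FilterDecision",
    "generate_negatives",
    "split_dataset",
    "build_dataset",
    "BuildReport",
]
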