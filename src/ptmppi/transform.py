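"""Masked classifier-input construction.

A (normalized abstract, candidate pair) is turned into the relation
classifier's input by replacing the two queried accessions with the fixed
markers ``PROTPART1``/``PROTPART2`` and every other mentioned accession with
``PRTIG1..PRTIGn``. The pair is canonicalized first (PROTPART1 = the
lexicographically smaller accession) so masking is symmetric in the pair and
deterministic. Inputs are truncated to a fixed token budget (512 units with
2 reserved for boundary markers) by a pluggable tokenizer.
"""

from __future__ import annotations

import re
from typing import Sequence

from .types import (
    LabeledSample,
    MaskedInput,
    NormalizedAbstract,
    TokenBudget,
    canonical_pair,
)

#: UniProt accession pattern (6-character primary accession forms).
UNIPROT_ACCESSION_RE = re.compile(
    r"\b(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9])\b"
)


def scan_accessions(pubmed_id: str, text: str) -> NormalizedAbstract:
    """Recover entity spans from a normalized text by accession pattern.

    A normalized abstract stores proteins as UniProt accessions in plain
    text; scanning for the accession pattern reconstructs the entity list
    when the original span bookkeeping is not at hand (e.g. samples read
    back from disk).
    """
    entities = tuple(
        (m.group(0), (m.start(), m.end()))
        for m in UNIPROT_ACCESSION_RE.finditer(text)
    )
    return NormalizedAbstract(pubmed_id, text, entities)


def mask_participants(
    normalized: NormalizedAbstract, pair: tuple[str, str]
) -> MaskedInput:
    """Mask the queried pair and all bystander proteins in a normalized text.

    Every entity span is rewritten: pair members to their PROTPART marker,
    each other accession to its PRTIG marker, numbered 1..n by first
    occurrence. Raises ``ValueError`` if either pair member is not
    mentioned (the caller skips such pairs).
    """
    a, b = canonical_pair(*pair)
    mentioned = set(normalized.unique_accessions())
    if a not in mentioned or b not in mentioned:
        missing = [x for x in (a, b) if x not in mentioned]
        raise ValueError(f"pair member(s) {missing} absent from abstract")

    markers: dict[str, str] = {a: "PROTPART1", b: "PROTPART2"}
    next_idx = 1
    for acc in normalized.unique_accessions():
        if acc not in markers:
            markers[acc] = f"PRTIG{next_idx}"
            next_idx += 1

    pieces: list[str] = []
    cursor = 0
    for acc, (start, end) in normalized.entities:
        pieces.append(normalized.text[cursor:start])
        pieces.append(markers[acc])
        cursor = end
    pieces.append(normalized.text[cursor:])

    marker_map = tuple((markers[acc], acc) for acc in normalized.unique_accessions())
    return MaskedInput(text="".join(pieces), marker_map=marker_map, pair=(a, b))


def unmask(masked: MaskedInput) -> str:
    """Invert masking via the marker map (restores the normalized text)."""
    text = masked.text
    # longer marker names first so PRTIG10 is not clobbered by PRTIG1
    for marker, acc in sorted(masked.marker_map, key=lambda kv: -len(kv[0])):
        text = text.replace(marker, acc)
    return text


def truncate_tokens(
    tokens: Sequence[str], budget: TokenBudget = TokenBudget()
) -> list[str]:
    """Prefix-preserving truncation to the payload budget (510 by default)."""
    return list(tokens[: budget.payload_max])


def whitespace_tokenize(text: str) -> list[str]:
    """Default test-scale tokenizer: lowercase whitespace split."""
    return text.lower().split()


def mask_sample(sample: LabeledSample) -> MaskedInput:
    """Mask a stored labelled sample (entity spans recovered by pattern)."""
    return mask_participants(
        scan_accessions(sample.pubmed_id, sample.text), sample.pair
    )


def prepare_classifier_samples(
    samples: Sequence[LabeledSample],
) -> list[LabeledSample]:
    """Replace each sample's text with its pair-masked classifier input."""
    return [
        LabeledSample(s.pubmed_id, s.pair, s.label, mask_sample(s).text, s.split)
        for s in samples
    ]


def enumerate_pairs(accessions: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n,2) unordered distinct pairs in lexicographic order."""
    uniq = sorted(set(accessions))
    return [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]


__all__ = [
    "UNIPROT_ACCESSION_RE",
    "scan_accessions",
    "mask_sample",
    "prepare_classifier_samples",
    "mask_participants",
    "unmask",
    "truncate_tokens",
    "whitespace_tokenize",
    "enumerate_pairs",
]
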