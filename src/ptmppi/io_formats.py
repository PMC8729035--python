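"""Readers and writers for the pipeline's external text formats.

Formats handled here:

* knowledge-base extract: 4-column TSV ``pubmed_id \\t uniprot_a \\t uniprot_b
  \\t ptm_type``;
* gene-mention annotations: PubTator-style tab-separated lines
  ``docid \\t start \\t end \\t mention \\t type \\t ncbi_gene_id``;
* NCBI-gene -> UniProt mapping: TSV ``gene_id \\t acc1,acc2,...`` (accession
  order is meaningful: it drives the first-accession fallback rule);
* labelled samples and triplet predictions: JSON lines, UTF-8.

Every reader is the exact inverse of its writer on valid data, and parsing is
order-stable. Errors name the offending 1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from .types import (
    ALL_LABELS,
    PTM_TYPES,
    GeneMention,
    InteractionRecord,
    LabeledSample,
    TripletPrediction,
)


class FormatError(ValueError):
    """Malformed input file; the message names the file line."""


def _norm_ptm(value: str) -> str:
    return value.strip().lower()


def read_interactions(
    path: str | Path, vocabulary: Iterable[str] = PTM_TYPES
) -> list[InteractionRecord]:
    """Parse a knowledge-base extract TSV into interaction records.

    Interaction types are matched case-insensitively against ``vocabulary``
    (default: the six PTM labels); unknown types and rows without exactly
    four columns raise :class:`FormatError` naming the row.
    """
    vocab = {_norm_ptm(v) for v in vocabulary}
    records: list[InteractionRecord] = []
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise FormatError(
                f"{path}: row {lineno}: expected 4 tab-separated columns, "
                f"got {len(fields)}"
            )
        pmid, iu1, iu2, ptm = (f.strip() for f in fields)
        ptm = _norm_ptm(ptm)
        if ptm not in vocab:
            raise FormatError(
                f"{path}: row {lineno}: unknown interaction type {ptm!r}"
            )
        records.append(InteractionRecord(pmid, iu1, iu2, ptm))
    return records


def write_interactions(path: str | Path, records: Iterable[InteractionRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.pubmed_id}\t{r.iu1}\t{r.iu2}\t{r.ptm_type}\n")


def read_mentions(path: str | Path) -> dict[str, list[GeneMention]]:
    """Parse PubTator-style annotation lines into per-document mention lists.

    Offsets are 0-based half-open character offsets. Mentions keep input
    order per document (overlaps are preserved, not resolved here).
    """
    out: dict[str, list[GeneMention]] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise FormatError(
                f"{path}: row {lineno}: expected 6 tab-separated columns, "
                f"got {len(fields)}"
            )
        pmid, start_s, end_s, text, _mtype, gene_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: non-integer offset") from exc
        if end <= start:
            raise FormatError(
                f"{path}: row {lineno}: span [{start}, {end}) is empty or inverted"
            )
        try:
            gene = int(gene_s)
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: non-integer gene id") from exc
        out.setdefault(pmid, []).append(GeneMention(start, end, text, gene))
    return out


def write_mentions(path: str | Path, mentions: Mapping[str, list[GeneMention]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pmid, ms in mentions.items():
            for m in ms:
                fh.write(
                    f"{pmid}\t{m.start}\t{m.end}\t{m.text}\tGene\t{m.ncbi_gene_id}\n"
                )


def read_id_mapping(path: str | Path) -> dict[int, list[str]]:
    """Parse a gene-id -> ordered accession-list TSV.

    The accession list may be comma- or tab-separated; list order is
    preserved exactly (the first accession is the mapping fallback).
    Duplicate gene rows and empty accession lists are errors.
    """
    mapping: dict[int, list[str]] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            gene = int(fields[0].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: non-integer gene id") from exc
        rest = fields[1:]
        accs: list[str] = []
        for chunk in rest:
            accs.extend(a.strip() for a in chunk.split(",") if a.strip())
        if not accs:
            raise FormatError(f"{path}: row {lineno}: empty accession list")
        if gene in mapping:
            raise FormatError(f"{path}: row {lineno}: duplicate gene id {gene}")
        mapping[gene] = accs
    return mapping


def write_id_mapping(path: str | Path, mapping: Mapping[int, list[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, accs in mapping.items():
            fh.write(f"{gene}\t{','.join(accs)}\n")


def read_abstracts(path: str | Path) -> dict[str, str]:
    """Parse ``pubmed_id \\t text`` lines (newlines in text JSON-escaped)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t", 1)
        if len(fields) != 2:
            raise FormatError(f"{path}: row {lineno}: expected pubmed_id<TAB>text")
        out[fields[0]] = json.loads(f'"{fields[1]}"') if "\\" in fields[1] else fields[1]
    return out


def write_abstracts(path: str | Path, abstracts: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pmid, text in abstracts.items():
            escaped = json.dumps(text)[1:-1]
            fh.write(f"{pmid}\t{escaped}\n")


def write_samples(path: str | Path, samples: Iterable[LabeledSample]) -> None:
    """Write labelled samples as JSON lines (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            fh.write(
                json.dumps(
                    {
                        "pubmed_id": s.pubmed_id,
                        "pair": list(s.pair),
                        "label": s.label,
                        "text": s.text,
                        "split": s.split,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_samples(path: str | Path) -> list[LabeledSample]:
    samples: list[LabeledSample] = []
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        obj = json.loads(line)
        if obj["label"] not in ALL_LABELS:
            raise FormatError(f"{path}: row {lineno}: unknown label {obj['label']!r}")
        samples.append(
            LabeledSample(
                pubmed_id=obj["pubmed_id"],
                pair=tuple(obj["pair"]),
                label=obj["label"],
                text=obj["text"],
                split=obj.get("split", ""),
            )
        )
    return samples


def write_triplets(path: str | Path, triplets: Iterable[TripletPrediction]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triplets:
            fh.write(
                json.dumps(
                    {
                        "pair": list(t.pair),
                        "ptm": t.ptm,
                        "pubmed_id": t.pubmed_id,
                        "confidence": t.confidence,
                        "confidence_sd": t.confidence_sd,
                        "high_quality": t.high_quality,
                    }
                )
                + "\n"
            )


def read_triplets(path: str | Path) -> list[TripletPrediction]:
    out: list[TripletPrediction] = []
    for line in _lines(path):
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(
            TripletPrediction(
                pair=tuple(obj["pair"]),
                ptm=obj["ptm"],
                pubmed_id=obj["pubmed_id"],
                confidence=obj["confidence"],
                confidence_sd=obj["confidence_sd"],
                high_quality=obj.get("high_quality", False),
            )
        )
    return out


def _lines(path: str | Path) -> Iterable[str]:
    with open(path, encoding="utf-8") as fh:
        yield from fh
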