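"""Core domain types shared across the pipeline.

Conventions used throughout:

* Character offsets are 0-based, half-open ``[start, end)``.
* Protein pairs are undirected; the canonical form orders the two UniProt
  accessions lexicographically.
* The label vocabulary is six PTM types plus a single ``Negative`` class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The six post-translational modification relation labels.
PTM_TYPES: tuple[str, ...] = (
    "phosphorylation",
    "dephosphorylation",
    "methylation",
    "acetylation",
    "ubiquitination",
    "deubiquitination",
)

#: Label for protein pairs co-mentioned in an abstract with no annotated PTM.
NEGATIVE_LABEL = "Negative"

#: Full 7-way classification vocabulary, Negative last.
ALL_LABELS: tuple[str, ...] = PTM_TYPES + (NEGATIVE_LABEL,)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an undirected accession pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One knowledge-base row: a PTM interaction evidenced by one abstract."""

    pubmed_id: str
    iu1: str
    iu2: str
    ptm_type: str

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.iu1, self.iu2)


@dataclass(frozen=True)
class GeneMention:
    """A gene-name span in an abstract, normalized to an NCBI gene id."""

    start: int
    end: int
    text: str
    ncbi_gene_id: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"mention span [{self.start}, {self.end}) is empty or inverted"
            )


@dataclass(frozen=True)
class NormalizedAbstract:
    """An abstract with every gene mention replaced by a UniProt accession.

    ``entities`` lists ``(accession, (start, end))`` spans into ``text``,
    one per input mention, in left-to-right order.
    """

    pubmed_id: str
    text: str
    entities: tuple[tuple[str, tuple[int, int]], ...]

    def unique_accessions(self) -> list[str]:
        """Distinct mentioned accessions in first-occurrence order."""
        seen: dict[str, None] = {}
        for acc, _ in self.entities:
            seen.setdefault(acc)
        return list(seen)


@dataclass(frozen=True)
class LabeledSample:
    """A (normalized abstract, unordered participant pair, label) unit."""

    pubmed_id: str
    pair: tuple[str, str]
    label: str
    text: str
    split: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        if self.pair[0] == self.pair[1]:
            raise ValueError(f"self-pair {self.pair} is not a valid sample")
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class DatasetSplit:
    """Document-level train/validation/test partition of labelled samples."""

    train: list[LabeledSample]
    val: list[LabeledSample]
    test: list[LabeledSample]
    seed: int

    def pubmed_ids(self, part: str) -> set[str]:
        return {s.pubmed_id for s in getattr(self, part)}


@dataclass
class CorpusBundle:
    """Everything the dataset builder consumes for one corpus."""

    abstracts: dict[str, str]
    interactions: list[InteractionRecord]
    mentions: dict[str, list[GeneMention]]
    id_mapping: dict[int, list[str]]

    def validate(self) -> None:
        """Check cross-references; raise ``ValueError`` on the first breach."""
        for rec in self.interactions:
            if rec.pubmed_id not in self.abstracts:
                raise ValueError(
                    f"interaction for PubMed {rec.pubmed_id} has no abstract"
                )
        for pmid, ms in self.mentions.items():
            text = self.abstracts.get(pmid)
            if text is None:
                continue
            for m in ms:
                if m.end > len(text) or text[m.start : m.end] != m.text:
                    raise ValueError(
                        f"mention {m.text!r} at [{m.start}, {m.end}) does not "
                        f"match abstract {pmid}"
                    )
        for gene, accs in self.id_mapping.items():
            if not accs:
                raise ValueError(f"gene {gene} maps to an empty accession list")


@dataclass(frozen=True)
class MaskedInput:
    """Classifier input with participants and bystander proteins masked.

    The queried pair is replaced by ``PROTPART1``/``PROTPART2`` (canonical
    lexicographic order: PROTPART1 is the smaller accession) and every other
    mentioned accession by ``PRTIG1..PRTIGn`` in first-occurrence order.
    """

    text: str
    marker_map: tuple[tuple[str, str], ...]
    pair: tuple[str, str]


@dataclass(frozen=True)
class TokenBudget:
    """Sequence-length contract: 512 units minus 2 reserved boundary markers."""

    max_units: int = 512
    reserved: int = 2

    @property
    def payload_max(self) -> int:
        return self.max_units - self.reserved


@dataclass
class EnsemblePrediction:
    """Aggregated ensemble output for one input sample."""

    sample_id: str
    member_probs: "object"  # (M, C) array
    mean_probs: "object"  # (C,) array
    pred_class: str
    confidence: float
    confidence_sd: float
    gold_label: str | None = None
    pubmed_id: str = ""
    pair: tuple[str, str] = ("", "")


@dataclass
class ClassThresholds:
    """Per-class dual cutoffs: minimum confidence and maximum confidence SD."""

    conf_min: dict[str, float]
    sd_max: dict[str, float]
    percentile: float = 50.0
    provenance: str = "train"

    def covers(self, label: str) -> bool:
        return label in self.conf_min and label in self.sd_max


@dataclass(frozen=True)
class TripletPrediction:
    """A canonical undirected <ProteinA, PTM, ProteinB> prediction."""

    pair: tuple[str, str]
    ptm: str
    pubmed_id: str
    confidence: float
    confidence_sd: float
    high_quality: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))

    @property
    def key(self) -> tuple[tuple[str, str], str]:
        return (self.pair, self.ptm)


@dataclass
class ExtractionSummary:
    """Tiered per-PTM counts mirroring the large-scale extraction summary."""

    per_ptm: dict[str, dict[str, int]] = field(default_factory=dict)

    def totals(self) -> dict[str, int]:
        keys = (
            "all",
            "all_unique",
            "high_quality",
            "high_quality_unique",
            "multi_abstract",
            "multi_abstract_unique",
        )
        return {k: sum(row.get(k, 0) for row in self.per_ptm.values()) for k in keys}
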