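"""Seeded synthetic fixtures emulating every external input of the pipeline.

Two generators:

* :func:`generate_corpus` emits a knowledge-base extract, abstracts,
  gene-mention annotations and a gene->accession mapping with planted PTM
  relations, plus a ground-truth ledger. The two distant-supervision noise
  kinds are planted at controllable rates: false-positive noise (the
  knowledge base annotates a relation the abstract does not describe —
  realized as a missing trigger word or a missing participant mention) and
  false-negative noise (the abstract describes a relation the knowledge
  base does not annotate).
* :func:`generate_ensemble_outputs` simulates per-member probability
  matrices from a known true posterior, with a sharpening ``temperature``
  (1 = perfectly calibrated, larger = overconfident) and per-member logit
  ``jitter`` creating inter-model variance.

Both are deterministic per seed. Synthetic accessions follow UniProt-like
6-character patterns so parsers are exercised realistically; the texts are
template sentences, not natural language (distractor sentences with
bystander proteins and off-type trigger words are included so masking and
noise filtering are exercised non-trivially).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kb_dataset import TRIGGER_STEMS
from .types import (
    PTM_TYPES,
    CorpusBundle,
    GeneMention,
    InteractionRecord,
    canonical_pair,
)

#: Surface word planted in text for each PTM label.
TRIGGER_WORDS: dict[str, str] = {ptm: ptm for ptm in PTM_TYPES}

#: Per-PTM mix mirroring the heavy phosphorylation skew of curated PTM
#: interactions (roughly 73% of positives are phosphorylation).
DEFAULT_PTM_MIX: dict[str, float] = {
    "phosphorylation": 0.73,
    "dephosphorylation": 0.16,
    "methylation": 0.05,
    "acetylation": 0.03,
    "ubiquitination": 0.02,
    "deubiquitination": 0.01,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Knobs of the synthetic corpus generator."""

    n_documents: int = 100
    ptm_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_PTM_MIX.items())
    proteins_min: int = 3
    proteins_max: int = 6
    false_positive_noise_rate: float = 0.0
    false_negative_noise_rate: float = 0.0
    trigger_insertion_rate: float = 0.3
    duplicate_rate: float = 0.0
    self_relation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.ptm_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ptm_mix must sum to 1, got {total}")
        for name in (
            "false_positive_noise_rate",
            "false_negative_noise_rate",
            "trigger_insertion_rate",
            "duplicate_rate",
            "self_relation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.proteins_min < 2:
            raise ValueError("need at least 2 proteins per abstract to plant relations")
        if self.proteins_max < self.proteins_min:
            raise ValueError("proteins_max < proteins_min")


@dataclass(frozen=True)
class PlantedRelation:
    """Ground truth for one knowledge-base row."""

    pubmed_id: str
    pair: tuple[str, str]
    ptm: str
    noise: str = ""  # "" | "missing-trigger" | "missing-participant"


@dataclass
class GroundTruth:
    """Planting ledger emitted alongside a generated corpus."""

    relations: list[PlantedRelation] = field(default_factory=list)
    false_negative_pairs: list[tuple[str, tuple[str, str], str]] = field(
        default_factory=list
    )  # (pubmed_id, pair, ptm described in text but unannotated)
    duplicate_rows: int = 0
    self_relation_rows: int = 0


def _accession(rng: np.random.Generator) -> str:
    """A UniProt-like 6-character accession, e.g. ``Q4X9K2``."""
    first = rng.choice(list("OPQ"))
    digits = "0123456789"
    upper = "ABCDEFGHIJKLMNPRSTUVWXYZ"
    body = (
        rng.choice(list(digits))
        + "".join(rng.choice(list(upper + digits), size=3))
        + rng.choice(list(digits))
    )
    return first + body


def generate_corpus(spec: CorpusSpec) -> tuple[CorpusBundle, GroundTruth]:
    """Generate a corpus bundle plus its planting ledger (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    labels = [l for l, _ in spec.ptm_mix]
    weights = np.array([w for _, w in spec.ptm_mix])

    abstracts: dict[str, str] = {}
    interactions: list[InteractionRecord] = []
    mentions: dict[str, list[GeneMention]] = {}
    id_mapping: dict[int, list[str]] = {}
    truth = GroundTruth()

    next_gene_id = 1000
    used_accs: set[str] = set()

    for doc in range(spec.n_documents):
        pmid = f"90{doc:06d}"
        n_prot = int(rng.integers(spec.proteins_min, spec.proteins_max + 1))
        accs: list[str] = []
        genes: list[int] = []
        gene_names: list[str] = []
        for _ in range(n_prot):
            acc = _accession(rng)
            while acc in used_accs:
                acc = _accession(rng)
            used_accs.add(acc)
            gene = next_gene_id
            next_gene_id += 1
            accs.append(acc)
            genes.append(gene)
            gene_names.append(f"GEN{gene}")

        ptm = labels[int(rng.choice(len(labels), p=weights))]
        i0, i1 = 0, 1
        pair = canonical_pair(accs[i0], accs[i1])

        noise = ""
        if rng.random() < spec.false_positive_noise_rate:
            noise = (
                "missing-trigger" if rng.random() < 0.5 else "missing-participant"
            )

        # mapping lists: participants sit mid-list behind decoys (found via
        # the annotated-match rule); bystanders lead their list (fallback).
        for idx, (gene, acc) in enumerate(zip(genes, accs)):
            decoy1, decoy2 = _accession(rng), _accession(rng)
            if idx in (i0, i1):
                id_mapping[gene] = [decoy1, acc, decoy2]
            else:
                id_mapping[gene] = [acc, decoy2]

        # false-negative noise: a second relation described in text only;
        # planted only in noise-free documents so the planted noise flag
        # stays exact (an fn trigger could otherwise satisfy the fp row)
        fn_pair_idx: tuple[int, int] | None = None
        fn_ptm = ""
        if (
            noise == ""
            and n_prot >= 4
            and rng.random() < spec.false_negative_noise_rate
        ):
            fn_pair_idx = (2, 3)
            fn_ptm = labels[int(rng.choice(len(labels), p=weights))]

        sentences: list[tuple[str, list[int]]] = []  # (template, gene indexes)
        if noise == "missing-participant":
            sentences.append(("{0} is studied in depth here .", [i0]))
        elif noise == "missing-trigger":
            sentences.append(("{0} interacts strongly with {1} in cells .", [i0, i1]))
        else:
            sentences.append(
                (
                    "{0} mediates direct " + TRIGGER_WORDS[ptm] + " of {1} in cells .",
                    [i0, i1],
                )
            )
        if fn_pair_idx is not None:
            sentences.append(
                (
                    "{0} catalyses " + TRIGGER_WORDS[fn_ptm] + " of {1} in vitro .",
                    list(fn_pair_idx),
                )
            )
        mentioned = {g for _, gs in sentences for g in gs}
        excluded = {i1} if noise == "missing-participant" else set()
        for idx in range(n_prot):
            if idx not in mentioned and idx not in excluded:
                sentences.append(("{0} is expressed in this tissue .", [idx]))
        # off-type distractor trigger, never from the planted labels' families
        if noise != "missing-trigger" and rng.random() < spec.trigger_insertion_rate:
            planted_stems = {TRIGGER_STEMS[ptm]} | (
                {TRIGGER_STEMS[fn_ptm]} if fn_ptm else set()
            )
            distractors = [
                l
                for l in labels
                if not any(
                    TRIGGER_STEMS[l] in s or s in TRIGGER_STEMS[l]
                    for s in planted_stems
                )
            ]
            if distractors:
                d = distractors[int(rng.integers(len(distractors)))]
                sentences.append(
                    ("unrelated " + TRIGGER_WORDS[d] + " pathways are reviewed .", [])
                )

        order = rng.permutation(len(sentences))
        text_parts: list[str] = []
        doc_mentions: list[GeneMention] = []
        offset = 0
        for si in order:
            template, gidx = sentences[si]
            rendered = template
            # left-to-right placeholder substitution with offset tracking
            for slot, gi in enumerate(gidx):
                name = gene_names[gi]
                pos = rendered.index("{%d}" % slot)
                rendered = rendered.replace("{%d}" % slot, name, 1)
                doc_mentions.append(
                    GeneMention(offset + pos, offset + pos + len(name), name, genes[gi])
                )
            text_parts.append(rendered)
            offset += len(rendered) + 1  # single space joiner
        abstracts[pmid] = " ".join(text_parts)
        doc_mentions.sort(key=lambda m: m.start)
        mentions[pmid] = doc_mentions

        interactions.append(InteractionRecord(pmid, pair[0], pair[1], ptm))
        truth.relations.append(PlantedRelation(pmid, pair, ptm, noise))
        if fn_pair_idx is not None:
            truth.false_negative_pairs.append(
                (pmid, canonical_pair(accs[2], accs[3]), fn_ptm)
            )
        if rng.random() < spec.duplicate_rate:
            interactions.append(InteractionRecord(pmid, pair[1], pair[0], ptm))
            truth.duplicate_rows += 1
        if rng.random() < spec.self_relation_rate:
            interactions.append(InteractionRecord(pmid, accs[0], accs[0], ptm))
            truth.self_relation_rows += 1

    bundle = CorpusBundle(
        abstracts=abstracts,
        interactions=interactions,
        mentions=mentions,
        id_mapping=id_mapping,
    )
    bundle.validate()
    return bundle, truth


@dataclass(frozen=True)
class EnsembleSimSpec:
    """Knobs of the ensemble-output simulator."""

    n_samples: int = 2000
    class_prior: tuple[float, ...] = (0.003, 0.004, 0.005, 0.008, 0.02, 0.11, 0.85)
    true_accuracy: float = 0.7
    temperature: float = 1.0
    member_jitter: float = 0.0
    M: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_prior) - 1.0) > 1e-9:
            raise ValueError("class_prior must sum to 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.member_jitter < 0:
            raise ValueError("member_jitter must be non-negative")


def generate_ensemble_outputs(
    spec: EnsembleSimSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (n, M, C) member probabilities, gold labels, true posteriors.

    For each sample a true posterior is drawn peaked on a prior-sampled
    class (peak height jittered around ``true_accuracy``) and the gold
    label is sampled from it, so a member reporting the true posterior is
    perfectly calibrated by construction. Members report
    ``softmax(temperature * log p + jitter * noise)``: temperature 1 /
    jitter 0 reproduces the posterior exactly; temperature > 1 is
    overconfident, < 1 underconfident.
    """
    rng = np.random.default_rng(spec.seed)
    C = len(spec.class_prior)
    prior = np.asarray(spec.class_prior)
    n, M = spec.n_samples, spec.M

    ks = rng.choice(C, size=n, p=prior)
    # peak logit chosen so softmax puts ~true_accuracy on the target class
    p = np.clip(spec.true_accuracy, 1.0 / C + 1e-6, 1 - 1e-6)
    base_a = np.log(p / (1 - p) * (C - 1))
    logits = rng.normal(0.0, 0.5, size=(n, C))
    logits[np.arange(n), ks] += base_a + rng.normal(0.0, 0.75, size=n)
    logits -= logits.max(axis=1, keepdims=True)
    posterior = np.exp(logits)
    posterior /= posterior.sum(axis=1, keepdims=True)

    gold = np.array([rng.choice(C, p=posterior[j]) for j in range(n)])

    log_p = np.log(posterior)
    member_logits = spec.temperature * log_p[:, None, :]
    if spec.member_jitter > 0:
        member_logits = member_logits + spec.member_jitter * rng.normal(
            size=(n, M, C)
        )
    else:
        member_logits = np.broadcast_to(member_logits, (n, M, C)).copy()
    member_logits -= member_logits.max(axis=2, keepdims=True)
    member_probs = np.exp(member_logits)
    member_probs /= member_probs.sum(axis=2, keepdims=True)
    return member_probs, gold, posterior


__all__ = [
    "CorpusSpec",
    "PlantedRelation",
    "GroundTruth",
    "generate_corpus",
    "EnsembleSimSpec",
    "generate_ensemble_outputs",
    "DEFAULT_PTM_MIX",
    "TRIGGER_WORDS",
]
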