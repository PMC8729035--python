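"""Worked data-preparation example: one fully traced abstract.

A synthetic reconstruction of a published data-preparation illustration: a
glucocorticoid-resistance abstract (PubMed 24291004) in which the AKT1
kinase phosphorylates the NR3C1 glucocorticoid receptor. The visible
phrases and every printed mention offset are reproduced exactly; the two
stretches elided in the published illustration are padded with neutral
filler so the offsets still hold, which makes this a synthetic stand-in for
the real abstract, not a copy of it.

The example exercises the whole preparation path: gene-mention
normalization with both mapping rules (annotated-participant match for
genes 2908 and 207, first-accession fallback for gene 5728), noise
filtering, negative-pair generation, and participant masking.
"""

from __future__ import annotations

from .types import CorpusBundle, GeneMention, InteractionRecord

PUBMED_ID = "24291004"

#: Knowledge-base row: phosphorylation between the pair below.
INTERACTION = InteractionRecord(
    pubmed_id=PUBMED_ID, iu1="P04150", iu2="P31749", ptm_type="phosphorylation"
)

_HEAD = (
    "Glucocorticoid resistance is a major obstacle in relapsed T cell acute "
    "lymphoblastic leukemia. In our genomic study here we identify the "
)  # exactly 137 characters, so the first mention starts at offset 137

ABSTRACT = (
    _HEAD
    + "AKT1 kinase as a major negative regulator of the NR3C1 glucocorticoid "
    "receptor protein activity driving glucocorticoid resistance in T-ALL. "
    "Mechanistically, AKT1 impairs glucocorticoid-induced gene expression by "
    "direct phosphorylation of NR3C1 at position S134 and blocking "
    "glucocorticoid-induced NR3C1 translocation to the nucleus. Moreover, we "
    "demonstrate that loss of PTEN and consequent AKT1 activation can "
    "effectively block glucocorticoid-induced apoptosis and induce resistance "
    "to glucocorticoid therapy. Conversely, pharmacologic inhibition of AKT "
    "with MK2206 effectively restores glucocorticoid-induced NR3C1 "
    "translocation to the nucleus in vitro and in vivo."
)

#: Gene mentions with their exact character spans (0-based, half-open).
MENTIONS = [
    GeneMention(137, 141, "AKT1", 207),
    GeneMention(186, 191, "NR3C1", 2908),
    GeneMention(294, 298, "AKT1", 207),
    GeneMention(375, 380, "NR3C1", 2908),
    GeneMention(434, 439, "NR3C1", 2908),
    GeneMention(508, 512, "PTEN", 5728),
    GeneMention(528, 532, "AKT1", 207),
    GeneMention(748, 753, "NR3C1", 2908),
]

#: NCBI gene -> ordered UniProt accession lists. For 2908 and 207 the
#: annotated participant sits mid-list (the annotated-match rule finds it);
#: for 5728 neither participant appears, so the first accession wins.
ID_MAPPING: dict[int, list[str]] = {
    2908: ["E5KQF5", "E5KQF6", "F1D8N4", "P04150", "B7Z7I2"],
    207: ["B0LPE5", "P31749", "B3KVH4"],
    5728: ["P60484", "F6KD01"],
}

#: The two co-mentioned pairs not annotated in the knowledge base.
EXPECTED_NEGATIVE_PAIRS = [("P04150", "P60484"), ("P31749", "P60484")]


def bundle() -> CorpusBundle:
    """The example as a one-document corpus bundle (validated)."""
    b = CorpusBundle(
        abstracts={PUBMED_ID: ABSTRACT},
        interactions=[INTERACTION],
        mentions={PUBMED_ID: list(MENTIONS)},
        id_mapping={k: list(v) for k, v in ID_MAPPING.items()},
    )
    b.validate()
    return b
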