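"""Scoring, human-evaluation aggregation and distribution-shift diagnostics.

Classification metrics are computed over the positive (PTM) classes with the
Negative class as background: micro precision = correct positive predictions
/ positive-prediction count, micro recall = correct positive predictions /
gold-positive count, and the macro average is the unweighted mean over
positive classes that have gold support. All metric values are percentages
in [0, 100].

Human-evaluation tables count verdicts per (category, PTM): a ``Correct``
row, any number of ``Incorrect-*`` rows, and a ``Not-sure`` row. Precision
counts Not-sure in the denominator (the reviewer could not confirm the
prediction); error-category shares are over incorrect verdicts only.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .types import ALL_LABELS, NEGATIVE_LABEL

CORRECT = "Correct"
NOT_SURE = "Not-sure"


@dataclass
class EvalReport:
    """Per-class and aggregate classification metrics (percent scale)."""

    labels: tuple[str, ...]
    per_class: dict[str, dict[str, float]]  # precision/recall/f1/support
    micro: dict[str, float]
    macro: dict[str, float]
    confusion: np.ndarray
    zero_division_flags: list[str] = field(default_factory=list)


def classification_report(
    gold: Sequence[str],
    pred: Sequence[str],
    labels: Sequence[str] = ALL_LABELS,
    negative_label: str = NEGATIVE_LABEL,
) -> EvalReport:
    """Score aligned gold/predicted label lists.

    Per-class precision/recall/F1 are reported for every positive class;
    micro averages treat the Negative class as background; the macro
    average is over positive classes with gold support > 0. Zero-division
    cells yield 0 and are flagged.
    """
    if len(gold) != len(pred):
        raise ValueError("gold and predicted label lists must be aligned")
    vocab = set(labels)
    for lab in list(gold) + list(pred):
        if lab not in vocab:
            raise ValueError(f"label {lab!r} outside vocabulary")
    positive = [l for l in labels if l != negative_label]
    p, r, f, support = precision_recall_fscore_support(
        gold, pred, labels=positive, zero_division=0
    )
    per_class: dict[str, dict[str, float]] = {}
    flags: list[str] = []
    for i, cls in enumerate(positive):
        per_class[cls] = {
            "precision": 100.0 * p[i],
            "recall": 100.0 * r[i],
            "f1": 100.0 * f[i],
            "support": int(support[i]),
        }
        n_pred = sum(1 for x in pred if x == cls)
        if n_pred == 0 or support[i] == 0:
            flags.append(cls)
    mp, mr, mf, _ = precision_recall_fscore_support(
        gold, pred, labels=positive, average="micro", zero_division=0
    )
    micro = {
        "precision": 100.0 * mp,
        "recall": 100.0 * mr,
        "f1": 100.0 * mf,
        "support": int(sum(support)),
    }
    with_support = [cls for i, cls in enumerate(positive) if support[i] > 0]
    macro = {
        key: (
            float(np.mean([per_class[c][key] for c in with_support]))
            if with_support
            else 0.0
        )
        for key in ("precision", "recall", "f1")
    }
    macro["support"] = int(sum(support))
    cm = confusion_matrix(gold, pred, labels=list(labels))
    return EvalReport(
        labels=tuple(labels),
        per_class=per_class,
        micro=micro,
        macro=macro,
        confusion=cm,
        zero_division_flags=flags,
    )


# ---------------------------------------------------------------------------
# human-evaluation tables

HumanEvalTable = Mapping[str, Mapping[str, int]]  # category -> PTM -> count


def _round(value: float, mode: str) -> float:
    if mode == "1-decimal":
        return round(value, 1)
    if mode == "nearest-integer":
        return float(round(value))
    if mode == "truncate":
        return float(math.floor(value))
    raise ValueError(f"unknown rounding mode {mode!r}")


def human_eval_precision(
    table: HumanEvalTable, rounding: str = "1-decimal"
) -> dict[str, float]:
    """Precision per PTM and overall from a human-verdict table.

    Precision = Correct / all evaluated (incorrect and Not-sure verdicts
    both count against). Returns a dict of per-PTM percentages plus an
    ``"overall"`` entry.
    """
    if not table:
        raise ValueError("empty table")
    ptms = sorted({ptm for row in table.values() for ptm in row})
    out: dict[str, float] = {}
    total_correct = total_all = 0
    for ptm in ptms:
        correct = table.get(CORRECT, {}).get(ptm, 0)
        evaluated = sum(row.get(ptm, 0) for row in table.values())
        total_correct += correct
        total_all += evaluated
        if evaluated:
            out[ptm] = _round(100.0 * correct / evaluated, rounding)
    if total_all == 0:
        raise ValueError("table has zero evaluated predictions")
    out["overall"] = _round(100.0 * total_correct / total_all, rounding)
    return out


def error_category_shares(table: HumanEvalTable) -> dict[str, float]:
    """Share of each Incorrect-* category among all incorrect verdicts.

    Not-sure verdicts are excluded from the denominator; shares are
    rounded to the nearest integer percent.
    """
    incorrect = {
        cat: sum(row.values())
        for cat, row in table.items()
        if cat not in (CORRECT, NOT_SURE)
    }
    denom = sum(incorrect.values())
    if denom == 0:
        raise ValueError("table has no incorrect predictions")
    return {cat: float(round(100.0 * n / denom)) for cat, n in incorrect.items()}


def noise_audit_report(
    counts: Mapping[str, tuple[int, int]]
) -> dict[str, dict[str, float]]:
    """Correct / Not-sure proportions of a label-quality audit.

    ``counts`` maps PTM -> (correct, not_sure). Percentages are rounded to
    the nearest integer; an ``"overall"`` row aggregates all PTMs.
    """
    out: dict[str, dict[str, float]] = {}
    tc = tn = 0
    for ptm, (correct, not_sure) in counts.items():
        total = correct + not_sure
        if total == 0:
            raise ValueError(f"zero audited samples for {ptm}")
        tc += correct
        tn += not_sure
        out[ptm] = {
            "correct_pct": float(round(100.0 * correct / total)),
            "not_sure_pct": float(round(100.0 * not_sure / total)),
        }
    if tc + tn == 0:
        raise ValueError("empty audit table")
    out["overall"] = {
        "correct_pct": float(round(100.0 * tc / (tc + tn))),
        "not_sure_pct": float(round(100.0 * tn / (tc + tn))),
    }
    return out


# ---------------------------------------------------------------------------
# knowledge-base recall

def kb_recall(
    predicted: Iterable[tuple[tuple[str, str], str]],
    reference: Iterable[tuple[tuple[str, str], str]],
) -> tuple[float, int]:
    """Recall (%) of reference triplets among predictions, plus match count.

    Both sides are (canonical unordered pair, PTM) keys; recall is
    100 · |predicted ∩ reference| / |reference|, rounded to 1 decimal.
    """
    pred_set = {(tuple(sorted(pair)), ptm) for pair, ptm in predicted}
    ref_set = {(tuple(sorted(pair)), ptm) for pair, ptm in reference}
    if not ref_set:
        raise ValueError("empty reference set")
    matched = len(pred_set & ref_set)
    return round(100.0 * matched / len(ref_set), 1), matched


def recall_percent(matched: int, reference_total: int) -> float:
    """Recall (%) from already-tallied counts, rounded to 1 decimal."""
    if reference_total <= 0:
        raise ValueError("reference total must be positive")
    return round(100.0 * matched / reference_total, 1)


# ---------------------------------------------------------------------------
# distribution-shift diagnostics

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _unigrams(text: str) -> Counter:
    return Counter(_TOKEN_RE.findall(text.lower()))


def similarity_to_train(
    queries: Sequence[str], train: Sequence[str]
) -> list[float]:
    """Max cosine similarity of each query abstract to any training abstract.

    Abstracts are unigram count vectors; an empty query scores 0 with a
    warning left to the caller's logging.
    """
    if not train:
        raise ValueError("empty training set")
    train_counts = [_unigrams(t) for t in train]
    train_norms = [math.sqrt(sum(v * v for v in c.values())) for c in train_counts]
    out: list[float] = []
    for q in queries:
        qc = _unigrams(q)
        qn = math.sqrt(sum(v * v for v in qc.values()))
        if qn == 0:
            out.append(0.0)
            continue
        best = 0.0
        for tc, tn in zip(train_counts, train_norms):
            if tn == 0:
                continue
            dot = sum(v * tc.get(k, 0) for k, v in qc.items())
            best = max(best, dot / (qn * tn))
        out.append(best)
    return out


#: Minimal default stop-word list for common-word summaries.
DEFAULT_STOP_WORDS = frozenset(
    "a an and are as at be by for from has have in is it of on or that the this "
    "to was we were which with".split()
)


def common_words(
    texts: Iterable[str],
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS,
    top_n: int | None = None,
) -> list[tuple[str, int]]:
    """Ranked lowercase unigram frequencies over a group of abstracts.

    Stop words are removed; ranking is by descending count with
    alphabetical tie-break.
    """
    counts: Counter = Counter()
    for text in texts:
        counts.update(t for t in _TOKEN_RE.findall(text.lower()) if t not in stop_words)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n] if top_n is not None else ranked


__all__ = [
    "EvalReport",
    "classification_report",
    "HumanEvalTable",
    "human_eval_precision",
    "error_category_shares",
    "noise_audit_report",
    "kb_recall",
    "recall_percent",
    "similarity_to_train",
    "DEFAULT_STOP_WORDS",
    "common_words",
    "CORRECT",
    "NOT_SURE",
]
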