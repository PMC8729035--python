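"""Reference relation-classification backbone and the ensemble contract.

The pipeline treats the classifier as a pluggable contract: anything that
maps a masked abstract to a 7-way probability vector (``predict_proba``)
drops in. The reference implementation is a bag-of-words multinomial
logistic model trained by seeded stochastic mini-batch gradient descent with
Bernoulli feature dropout, so ensemble members trained from different seeds
genuinely disagree — the property the downstream confidence-variation
machinery depends on. The best epoch is snapshot by validation macro-F1
(not lowest loss), which favours the minority PTM classes under the heavy
class imbalance typical of distant supervision; ties go to the earliest
epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from .transform import whitespace_tokenize
from .types import ALL_LABELS, LabeledSample


@dataclass(frozen=True)
class Hyperparams:
    """Reference-backbone training knobs.

    Defaults are sized for desk-scale corpora: 30 epochs of mini-batch SGD
    (batch 32, learning rate 0.5) with 30% feature dropout and light L2.
    """

    epochs: int = 30
    learning_rate: float = 0.5
    batch_size: int = 32
    dropout: float = 0.3
    l2: float = 1e-4
    #: snapshot the best-validation-F1 epoch; False keeps the final epoch
    snapshot_best: bool = True


@dataclass
class BackboneModel:
    """Trained bag-of-words softmax classifier (deterministic at inference)."""

    vocab: dict[str, int]
    weights: np.ndarray  # (V, C)
    bias: np.ndarray  # (C,)
    labels: tuple[str, ...]
    seed: int
    history: list[float] = field(default_factory=list)  # per-epoch val macro-F1
    best_epoch: int = -1

    def featurize(self, text: str) -> np.ndarray:
        x = np.zeros(len(self.vocab))
        for tok in _features(text):
            idx = self.vocab.get(tok)
            if idx is not None:
                x[idx] += 1.0
        return x

    def predict_proba(self, masked_text: str) -> np.ndarray:
        """Class-probability vector for one masked input (sums to 1)."""
        if not masked_text.strip():
            raise ValueError("empty input text")
        logits = self.featurize(masked_text) @ self.weights + self.bias
        logits -= logits.max()
        e = np.exp(logits)
        return e / e.sum()

    def predict_label(self, masked_text: str) -> str:
        return self.labels[int(np.argmax(self.predict_proba(masked_text)))]

    def save(self, path: str | Path) -> None:
        obj = {
            "vocab": self.vocab,
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "labels": list(self.labels),
            "seed": self.seed,
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "BackboneModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            vocab=obj["vocab"],
            weights=np.asarray(obj["weights"]),
            bias=np.asarray(obj["bias"]),
            labels=tuple(obj["labels"]),
            seed=obj["seed"],
            history=obj["history"],
            best_epoch=obj["best_epoch"],
        )


def _features(text: str) -> list[str]:
    """Unigram + adjacent-bigram bag features.

    Bigrams let a linear model tie a trigger word to the masked
    participant markers (e.g. ``of__protpart2``), which unigrams alone
    cannot: a negative pair from the same abstract shares every unigram
    with the positive pair.
    """
    toks = whitespace_tokenize(text)
    return toks + [f"{a}__{b}" for a, b in zip(toks, toks[1:])]


def _build_vocab(texts: Sequence[str]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for text in texts:
        for tok in _features(text):
            vocab.setdefault(tok, len(vocab))
    return vocab


def _count_matrix(texts: Sequence[str], vocab: dict[str, int]) -> np.ndarray:
    X = np.zeros((len(texts), len(vocab)))
    for i, text in enumerate(texts):
        for tok in _features(text):
            idx = vocab.get(tok)
            if idx is not None:
                X[i, idx] += 1.0
    return X


def train_backbone(
    train: Sequence[LabeledSample],
    val: Sequence[LabeledSample],
    hyperparams: Hyperparams = Hyperparams(),
    seed: int = 0,
    labels: tuple[str, ...] = ALL_LABELS,
) -> BackboneModel:
    """Train one reference model; snapshot the epoch with best val macro-F1.

    Fully reproducible given ``seed`` (shuffling, initialization and
    dropout masks all derive from it).
    """
    if not train:
        raise ValueError("empty training set")
    if not val:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(seed)
    label_index = {lab: i for i, lab in enumerate(labels)}
    vocab = _build_vocab([s.text for s in train])
    X = _count_matrix([s.text for s in train], vocab)
    y = np.array([label_index[s.label] for s in train])
    Xv = _count_matrix([s.text for s in val], vocab)
    yv = np.array([label_index[s.label] for s in val])

    n, V, C = len(train), len(vocab), len(labels)
    W = rng.normal(0.0, 0.01, size=(V, C))
    b = np.zeros(C)
    hp = hyperparams

    best_f1, best_epoch = -1.0, -1
    best_W, best_b = W.copy(), b.copy()
    history: list[float] = []
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            Xb = X[idx]
            if hp.dropout > 0:
                mask = rng.random(V) >= hp.dropout
                Xb = Xb * (mask / (1.0 - hp.dropout))
            logits = Xb @ W + b
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            P = e / e.sum(axis=1, keepdims=True)
            P[np.arange(len(idx)), y[idx]] -= 1.0
            gW = Xb.T @ P / len(idx) + hp.l2 * W
            gb = P.mean(axis=0)
            W -= hp.learning_rate * gW
            b -= hp.learning_rate * gb
        logits_v = Xv @ W + b
        pred_v = logits_v.argmax(axis=1)
        f1 = f1_score(yv, pred_v, average="macro", zero_division=0)
        history.append(float(f1))
        if (f1 > best_f1) if hp.snapshot_best else (epoch == hp.epochs - 1):
            # strict inequality: ties keep the earliest epoch
            best_f1, best_epoch = f1, epoch
            best_W, best_b = W.copy(), b.copy()

    return BackboneModel(
        vocab=vocab,
        weights=best_W,
        bias=best_b,
        labels=tuple(labels),
        seed=seed,
        history=history,
        best_epoch=best_epoch,
    )


def build_ensemble(
    train: Sequence[LabeledSample],
    val: Sequence[LabeledSample],
    M: int = 10,
    base_seed: int = 0,
    hyperparams: Hyperparams = Hyperparams(),
) -> list[BackboneModel]:
    """Train M models identical except for seed (``base_seed + i``)."""
    if M < 1:
        raise ValueError("ensemble size must be >= 1")
    return [
        train_backbone(train, val, hyperparams, seed=base_seed + i)
        for i in range(M)
    ]


def ensemble_member_probs(
    models: Sequence[BackboneModel], masked_text: str
) -> np.ndarray:
    """Stack per-member probability vectors into an (M, C) matrix."""
    return np.stack([m.predict_proba(masked_text) for m in models])


__all__ = [
    "Hyperparams",
    "BackboneModel",
    "train_backbone",
    "build_ensemble",
    "ensemble_member_probs",
]
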