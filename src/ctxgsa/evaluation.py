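"""Automatic evaluation of predicted pathways against ground truths.

Predicted and ground-truth pathway names are free text, so agreement is
scored semantically: both lists are embedded with a deterministic text
encoder, and every prediction-truth pair gets a cosine similarity.  With a
similarity threshold t, matching is many-to-many:

* HIT  — fraction of ground truths matched by at least one prediction
  (coverage, per truth column);
* ACC  — fraction of predictions matching at least one ground truth
  (precision, per prediction row);
* harmonic mean — 2*HIT*ACC / (HIT + ACC), 0 when both are 0.

A sweep over thresholds (default 0.5-0.9) and a top-K truncation of a
ranked prediction list summarize performance.  The shipped
:class:`StubEncoder` hashes character trigrams into a fixed-dimension
unit vector; it is an offline, deterministic stand-in for a biomedical
sentence encoder and preserves the property that texts sharing more
trigrams are more similar.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np


class EmbeddingBackend(Protocol):
    """Batch text encoder contract: texts in, unit-norm row vectors out."""

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


@dataclass
class SimilarityMatrix:
    """Cosine similarities: rows = predictions, cols = ground truths."""

    predictions: list[str]
    truths: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.predictions), len(self.truths))
        if self.values.shape != expected:
            raise ValueError(f"matrix shape {self.values.shape} != {expected}")


@dataclass
class MetricResult:
    """HIT/ACC/harmonic-mean at one similarity threshold."""

    threshold: float
    hit: float
    acc: float
    harmonic: float
    acc_undefined: bool = False  # no predictions: ACC defined as 0, flagged


class StubEncoder:
    """Character-trigram hashing encoder producing L2-normalized vectors.

    Each lowercase character trigram of the input is hashed (stable MD5,
    independent of the interpreter's hash seed) into one of ``dim``
    buckets; the bucket-count vector is L2-normalized.  Identical strings
    map to identical vectors and shared trigrams raise cosine similarity.
    """

    def __init__(self, dim: int = 512):
        self.dim = dim

    def _vector(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        t = " " + text.lower().strip() + " "
        grams = [t[i : i + 3] for i in range(max(len(t) - 2, 1))]
        for g in grams:
            h = int.from_bytes(hashlib.md5(g.encode()).digest()[:8], "big")
            v[h % self.dim] += 1.0
        norm = np.linalg.norm(v)
        if norm == 0:
            v[0] = 1.0
            norm = 1.0
        return v / norm

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self._vector(t) for t in texts]) if texts else np.zeros((0, self.dim))


def stub_encoder(texts: Sequence[str], dim: int = 512) -> np.ndarray:
    """Functional wrapper around :class:`StubEncoder`."""
    return StubEncoder(dim=dim).embed(texts)


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def similarity_matrix(
    preds: Sequence[str],
    truths: Sequence[str],
    backend: EmbeddingBackend,
) -> SimilarityMatrix:
    """Pairwise cosine similarity between predictions and ground truths.

    Encoder outputs are re-normalized to unit length before the dot
    product, so identical strings always score 1.0.  An empty prediction
    list yields a well-defined empty matrix (metrics then report HIT 0 and
    ACC 0 with a flag).
    """
    if not truths:
        raise ValueError("ground-truth list is empty")
    if not preds:
        return SimilarityMatrix(
            predictions=[], truths=list(truths), values=np.zeros((0, len(truths)))
        )
    p = _unit_rows(np.asarray(backend.embed(list(preds)), dtype=float))
    t = _unit_rows(np.asarray(backend.embed(list(truths)), dtype=float))
    return SimilarityMatrix(predictions=list(preds), truths=list(truths), values=p @ t.T)


def hit_ratio(sim: SimilarityMatrix, threshold: float) -> float:
    """Fraction of ground-truth columns with at least one similarity >=
    threshold (many-to-many; inclusive comparison)."""
    if sim.values.shape[1] == 0:
        raise ValueError("no ground truths")
    if sim.values.shape[0] == 0:
        return 0.0
    return float((sim.values.max(axis=0) >= threshold).sum() / sim.values.shape[1])


def accuracy(sim: SimilarityMatrix, threshold: float) -> float:
    """Fraction of prediction rows with at least one similarity >=
    threshold.  Defined as 0 when there are no predictions (flagged in
    :func:`threshold_sweep`)."""
    if sim.values.shape[0] == 0:
        return 0.0
    return float((sim.values.max(axis=1) >= threshold).sum() / sim.values.shape[0])


def harmonic_mean(hit: float, acc: float) -> float:
    """2*HIT*ACC / (HIT + ACC); 0 in the degenerate all-zero limit."""
    if not (0.0 <= hit <= 1.0 and 0.0 <= acc <= 1.0):
        raise ValueError("hit and acc must lie in [0, 1]")
    if hit + acc == 0.0:
        return 0.0
    return 2.0 * hit * acc / (hit + acc)


DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


def threshold_sweep(
    sim: SimilarityMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[MetricResult]:
    """One :class:`MetricResult` per threshold (ascending).  HIT and ACC
    are non-increasing in the threshold by construction."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    out = []
    no_preds = sim.values.shape[0] == 0
    for t in thresholds:
        h = hit_ratio(sim, t)
        a = accuracy(sim, t)
        out.append(
            MetricResult(
                threshold=float(t),
                hit=h,
                acc=a,
                harmonic=harmonic_mean(h, a),
                acc_undefined=no_preds,
            )
        )
    return out


def topk_evaluate(
    ranked_preds: Sequence[str],
    truths: Sequence[str],
    backend: EmbeddingBackend,
    k: int,
    threshold: float,
) -> MetricResult:
    """Metrics on the first ``k`` predictions of a ranked list (e.g. ranked
    by enrichment p-value or relevance score)."""
    if k <= 0:
        raise ValueError("k must be positive")
    sim = similarity_matrix(list(ranked_preds)[:k], truths, backend)
    h = hit_ratio(sim, threshold)
    a = accuracy(sim, threshold)
    return MetricResult(
        threshold=float(threshold),
        hit=h,
        acc=a,
        harmonic=harmonic_mean(h, a),
        acc_undefined=sim.values.shape[0] == 0,
    )


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Proportion expressed as a percentage, rounded to ``ndigits``.

    The error-accounting helper used in reports (e.g. missed ground truths
    out of all ground truths)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, ndigits)
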