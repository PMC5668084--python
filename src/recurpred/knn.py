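"""Correlation-distance k-nearest-neighbor voting.

A query sample is classified by the labels of its k nearest training samples
under d(x, y) = 1 - Pearson r(x, y), computed over a selected gene set. The
default k = 1 classifies by the single nearest neighbor. Pearson r is
invariant to positive affine rescaling of either profile, so the vote is
robust to per-sample scaling/offset differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VOTE_RECURRENT = 1
VOTE_NON_RECURRENT = -1


class ConstantProfileError(ValueError):
    """Pearson correlation is undefined for a constant expression profile."""


def _center_normalize(matrix: np.ndarray, what: str) -> np.ndarray:
    """Columns centered and scaled to unit norm; constant columns are an error."""
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0)
        raise ConstantProfileError(
            f"constant {what} profile(s) over the selected genes at column(s) "
            f"{bad[:5].tolist()}: correlation distance undefined"
        )
    return centered / norms


def correlation_distance(x, y) -> float:
    """1 - Pearson r, in [0, 2]. Vectors must be non-constant with length >= 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("correlation_distance needs two equal-length vectors (n >= 2)")
    xn = _center_normalize(x[:, None], "query")[:, 0]
    yn = _center_normalize(y[:, None], "query")[:, 0]
    return float(np.clip(1.0 - xn @ yn, 0.0, 2.0))


@dataclass
class NeighborModel:
    """Training expression restricted to the selected genes, plus labels.

    ``values`` is genes x training samples; ``labels`` holds +1 (recurrent)
    or -1 (non-recurrent) per training sample. ``k`` must be odd so majority
    votes cannot tie; ``class_weighted`` optionally weights votes inversely
    to training class frequency for unbalanced cohorts.
    """

    values: np.ndarray
    labels: np.ndarray
    k: int = 1
    class_weighted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("values must be genes x samples matching labels")
        if self.values.shape[0] < 1:
            raise ValueError("selected gene list must be non-empty")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        if self.k > len(self.labels):
            raise ValueError("k exceeds the number of training samples")
        for lab in (VOTE_RECURRENT, VOTE_NON_RECURRENT):
            if not (self.labels == lab).any():
                raise ValueError("need at least one training sample per class")
        self._normed = _center_normalize(self.values, "training")
        if self.class_weighted:
            n_pos = (self.labels == VOTE_RECURRENT).sum()
            n_neg = (self.labels == VOTE_NON_RECURRENT).sum()
            self._weights = np.where(self.labels == VOTE_RECURRENT,
                                     1.0 / n_pos, 1.0 / n_neg)
        else:
            self._weights = np.ones(len(self.labels))


def predict_votes(model: NeighborModel, queries: np.ndarray) -> np.ndarray:
    """Vote (+1/-1) for each query column (genes x queries).

    Distance ties are broken deterministically by the smallest training-sample
    index; a tied weighted majority falls to the non-recurrent side (cannot
    occur for unweighted odd k).
    """
    q = np.asarray(queries, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    if q.shape[0] != model.values.shape[0]:
        raise ValueError("query gene dimension does not match the model")
    qn = _center_normalize(q, "query")
    dist = 1.0 - model._normed.T @ qn  # train x queries
    votes = np.empty(q.shape[1], dtype=int)
    for j in range(q.shape[1]):
        # stable sort: equal distances resolve to the lower training index
        nearest = np.argsort(dist[:, j], kind="stable")[: model.k]
        tally = float(np.sum(model.labels[nearest] * model._weights[nearest]))
        votes[j] = VOTE_RECURRENT if tally > 0 else VOTE_NON_RECURRENT
    return votes


def predict_vote(model: NeighborModel, query) -> int:
    """Vote for a single query expression vector."""
    return int(predict_votes(model, np.asarray(query, dtype=float))[0])
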