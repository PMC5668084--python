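"""Monte-Carlo leave-k-out ensemble of correlation-distance 1-NN classifiers.

The training cohort is repeatedly split at random into a model-building set
(n - k_out samples) and k_out held-out samples; each repetition re-ranks all
genes by Welch t on its own building set (no selection leakage), keeps the
top m, and stores a nearest-neighbor member. Defaults mirror the study
design: 500 repetitions holding out 5 of 153 training samples, so each
member fits on 148.

A training sample's risk score is the average +/-1 vote over exactly those
members in which it was held out (out-of-bag averaging): in-sample votes
from a 1-NN would be trivially correct. External samples are scored by all
members. Scores lie in [-1, +1]; the default cutoff 0 calls score > 0
high-risk, and |score| < 0.5 flags a low-confidence / medium-risk call.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CLASS_NON_RECURRENT,
    CLASS_RECURRENT,
    ExpressionMatrix,
    ROLE_TRAIN,
    read_expression,
    write_expression,
)
from .knn import NeighborModel, VOTE_NON_RECURRENT, VOTE_RECURRENT, predict_votes
from .selection import rank_order, welch_t_matrix

logger = logging.getLogger(__name__)

MEDIUM_RISK_BAND = 0.5


@dataclass
class SplitPlan:
    """Random leave-k_out-out splits of ``n`` training samples."""

    splits: list  # [(train_idx, test_idx), ...]
    n: int
    k_out: int
    reps: int
    seed: int


def make_splits(n: int, k_out: int, reps: int, seed: int) -> SplitPlan:
    """reps independent uniform without-replacement draws of k_out test indices."""
    if not 0 < k_out < n:
        raise ValueError(f"k_out must satisfy 0 < k_out < n, got k_out={k_out}, n={n}")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    splits = []
    for _ in range(reps):
        test = np.sort(rng.choice(n, k_out, replace=False))
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        splits.append((train, test))
    return SplitPlan(splits=splits, n=n, k_out=k_out, reps=reps, seed=seed)


@dataclass
class Member:
    train_idx: np.ndarray  # positions within the training cohort
    test_idx: np.ndarray
    gene_idx: np.ndarray   # positions within the full gene list


@dataclass
class EnsembleModel:
    """Trained resampling ensemble over one training cohort."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray      # training cohort sample IDs
    values: np.ndarray          # genes x training samples (log2)
    labels: np.ndarray          # +1 recurrent / -1 non-recurrent
    members: list
    m: int
    k: int = 1
    class_weighted: bool = False
    seed: int = 0
    k_out: int = 5
    redraw_count: int = 0
    signature: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def reps(self) -> int:
        return len(self.members)

    def member_gene_ids(self, i: int) -> list:
        return self.gene_ids[self.members[i].gene_idx].tolist()

    def signature_genes(self, size: int | None = None) -> list:
        sig = self.signature if size is None else self.signature.head(size)
        return sig["gene_id"].tolist()


def _labels_to_votes(classes: np.ndarray) -> np.ndarray:
    votes = np.where(classes == CLASS_RECURRENT, VOTE_RECURRENT, VOTE_NON_RECURRENT)
    unknown = ~np.isin(classes, [CLASS_RECURRENT, CLASS_NON_RECURRENT])
    if unknown.any():
        raise ValueError(f"unlabeled training samples: {np.flatnonzero(unknown)[:5].tolist()}")
    return votes


def _aggregate_signature(members, gene_ids: np.ndarray, reps: int) -> pd.DataFrame:
    counts = np.zeros(len(gene_ids), dtype=int)
    for mem in members:
        counts[mem.gene_idx] += 1
    sel = np.flatnonzero(counts)
    order = np.lexsort((gene_ids[sel].astype(str), -counts[sel]))
    sel = sel[order]
    return pd.DataFrame({
        "gene_id": gene_ids[sel],
        "n_selected": counts[sel],
        "frequency": counts[sel] / reps,
    })


def train_ensemble(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    plan: SplitPlan,
    m: int,
    k: int = 1,
    class_weighted: bool = False,
) -> EnsembleModel:
    """Fit one ensemble member per split of the training cohort.

    ``samples`` is restricted to labeled, non-reference, role=train rows.
    Gene ranking uses only each split's building samples. A split whose
    building set lacks a class is redrawn deterministically (logged).
    """
    train_tab = samples[
        (samples["role"] == ROLE_TRAIN) & (~samples["is_reference"])
    ]
    ids = train_tab["sample_id"].to_numpy(object)
    if len(ids) != plan.n:
        raise ValueError(f"split plan built for n={plan.n} but cohort has {len(ids)}")
    sub = expr.subset_samples(ids)
    labels = _labels_to_votes(train_tab["class"].to_numpy(object))
    if not 1 <= m <= sub.n_genes:
        raise ValueError(f"m must be in [1, {sub.n_genes}], got {m}")

    redraw_rng = np.random.default_rng(np.random.SeedSequence(plan.seed, spawn_key=(1,)))

    def _degenerate(train_idx):
        # a building set must keep >= 2 samples per class for the t ranking
        return min((labels[train_idx] == VOTE_RECURRENT).sum(),
                   (labels[train_idx] == VOTE_NON_RECURRENT).sum()) < 2

    members: list[Member] = []
    redraws = 0
    for train_idx, test_idx in plan.splits:
        while _degenerate(train_idx):
            redraws += 1
            test_idx = np.sort(redraw_rng.choice(plan.n, plan.k_out, replace=False))
            train_idx = np.setdiff1d(np.arange(plan.n), test_idx, assume_unique=True)
        t = welch_t_matrix(sub.values[:, train_idx], labels[train_idx] == VOTE_RECURRENT)
        gene_idx = rank_order(t, sub.gene_ids)[:m]
        members.append(Member(train_idx=train_idx, test_idx=test_idx, gene_idx=gene_idx))
    if redraws:
        logger.info("train_ensemble: redrew %d splits that emptied a class", redraws)

    return EnsembleModel(
        gene_ids=sub.gene_ids,
        sample_ids=sub.sample_ids,
        values=sub.values,
        labels=labels,
        members=members,
        m=m,
        k=k,
        class_weighted=class_weighted,
        seed=plan.seed,
        k_out=plan.k_out,
        redraw_count=redraws,
        signature=_aggregate_signature(members, sub.gene_ids, plan.reps),
    )


def _scores_frame(sample_ids, sums, counts, cutoff: float = 0.0,
                  band: float = MEDIUM_RISK_BAND) -> pd.DataFrame:
    with np.errstate(invalid="ignore"):
        score = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    call = np.where(score > cutoff, "high", "low").astype(object)
    conf = np.where(np.abs(score - cutoff) < band, "medium_risk", "high_confidence").astype(object)
    never = counts == 0
    call[never] = ""
    conf[never] = ""
    if never.any():
        logger.warning("%d sample(s) were never held out and received no score", never.sum())
    return pd.DataFrame({
        "sample_id": np.asarray(sample_ids, dtype=object),
        "score": score,
        "n_votes": counts.astype(int),
        "call": call,
        "confidence": conf,
    })


def score_internal(model: EnsembleModel, cutoff: float = 0.0) -> pd.DataFrame:
    """Out-of-bag risk scores for the training cohort.

    Each sample is voted on only by members in which it was held out, so the
    averaged score is an honest internal cross-validation estimate.
    """
    n = len(model.sample_ids)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for mem in model.members:
        nn = NeighborModel(
            model.values[np.ix_(mem.gene_idx, mem.train_idx)],
            model.labels[mem.train_idx],
            k=model.k,
            class_weighted=model.class_weighted,
        )
        votes = predict_votes(nn, model.values[np.ix_(mem.gene_idx, mem.test_idx)])
        sums[mem.test_idx] += votes
        counts[mem.test_idx] += 1
    return _scores_frame(model.sample_ids, sums, counts, cutoff)


def score_external(model: EnsembleModel, expr: ExpressionMatrix,
                   cutoff: float = 0.0) -> pd.DataFrame:
    """Risk scores for new samples: every member votes on every sample.

    Only expression is consumed — clinical outcomes are never read here,
    which is what makes a blind external validation possible. All genes used
    by any member must be present in ``expr``.
    """
    used = np.zeros(len(model.gene_ids), dtype=bool)
    for mem in model.members:
        used[mem.gene_idx] = True
    needed = model.gene_ids[used]
    missing = sorted(set(needed) - set(expr.gene_ids))
    if missing:
        raise KeyError(f"validation matrix lacks {len(missing)} model gene(s): {missing[:10]}")
    # reorder query rows into the model's gene space
    pos = pd.Index(expr.gene_ids).get_indexer(model.gene_ids[used])
    lookup = np.full(len(model.gene_ids), -1)
    lookup[np.flatnonzero(used)] = np.arange(used.sum())
    qvalues = expr.values[pos, :]

    n = expr.n_samples
    sums = np.zeros(n)
    for mem in model.members:
        nn = NeighborModel(
            model.values[np.ix_(mem.gene_idx, mem.train_idx)],
            model.labels[mem.train_idx],
            k=model.k,
            class_weighted=model.class_weighted,
        )
        votes = predict_votes(nn, qvalues[lookup[mem.gene_idx], :])
        sums += votes
    counts = np.full(n, model.reps)
    return _scores_frame(expr.sample_ids, sums, counts, cutoff)


def write_scores(scores: pd.DataFrame, path: str) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False,
                       na_values=[""]).astype({"score": float})


def save_model(model: EnsembleModel, out_dir: str) -> None:
    """Persist as a directory: model.json + training submatrix TSV.

    The TSV is restricted to the union of member gene lists; member gene
    indices are stored as gene IDs so the bundle is self-describing.
    """
    os.makedirs(out_dir, exist_ok=True)
    used = np.zeros(len(model.gene_ids), dtype=bool)
    for mem in model.members:
        used[mem.gene_idx] = True
    union_ids = model.gene_ids[used]
    sub = ExpressionMatrix(union_ids, model.sample_ids, model.values[used, :])
    write_expression(sub, os.path.join(out_dir, "training_submatrix.tsv"))
    payload = {
        "config": {
            "m": model.m, "k": model.k, "k_out": model.k_out,
            "reps": model.reps, "seed": model.seed,
            "class_weighted": model.class_weighted,
        },
        "redraw_count": model.redraw_count,
        "labels": {str(s): int(l) for s, l in zip(model.sample_ids, model.labels)},
        "members": [
            {
                "train_ids": model.sample_ids[mem.train_idx].tolist(),
                "test_ids": model.sample_ids[mem.test_idx].tolist(),
                "gene_ids": model.gene_ids[mem.gene_idx].tolist(),
            }
            for mem in model.members
        ],
        "signature": model.signature.to_dict(orient="list"),
    }
    with open(os.path.join(out_dir, "model.json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(model_dir: str) -> EnsembleModel:
    with open(os.path.join(model_dir, "model.json"), encoding="utf-8") as fh:
        payload = json.load(fh)
    sub = read_expression(os.path.join(model_dir, "training_submatrix.tsv"))
    sample_pos = {s: i for i, s in enumerate(sub.sample_ids)}
    gene_pos = {g: i for i, g in enumerate(sub.gene_ids)}
    labels = np.array([payload["labels"][str(s)] for s in sub.sample_ids], dtype=int)
    members = [
        Member(
            train_idx=np.array([sample_pos[s] for s in mem["train_ids"]]),
            test_idx=np.array([sample_pos[s] for s in mem["test_ids"]]),
            gene_idx=np.array([gene_pos[g] for g in mem["gene_ids"]]),
        )
        for mem in payload["members"]
    ]
    cfg = payload["config"]
    return EnsembleModel(
        gene_ids=sub.gene_ids,
        sample_ids=sub.sample_ids,
        values=sub.values,
        labels=labels,
        members=members,
        m=cfg["m"],
        k=cfg["k"],
        class_weighted=cfg["class_weighted"],
        seed=cfg["seed"],
        k_out=cfg["k_out"],
        redraw_count=payload["redraw_count"],
        signature=pd.DataFrame(payload["signature"]),
    )
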