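"""Gene selection: rank genes by class-separation Welch t statistic.

Selection is by |t| magnitude only — the ranking feeds a classifier embedded
in a resampling loop, so no p-values or multiple-testing correction are
involved. Sign convention: positive t means higher expression in the
recurrent group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CLASS_NON_RECURRENT, CLASS_RECURRENT, ExpressionMatrix


def welch_t(group_a, group_b) -> float:
    """Unequal-variance t statistic, (mean_a - mean_b) / sqrt(s2a/na + s2b/nb).

    ``group_a`` is the recurrent group. Degenerate cases: zero variance in
    both groups with equal means gives 0; zero standard error with unequal
    means gives a signed infinity (ranked first).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    diff = a.mean() - b.mean()
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(se2))


def welch_t_matrix(values: np.ndarray, recurrent_mask: np.ndarray) -> np.ndarray:
    """Row-wise Welch t for a genes x samples matrix (vectorized)."""
    rec = values[:, recurrent_mask]
    non = values[:, ~recurrent_mask]
    na, nb = rec.shape[1], non.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each class needs at least 2 samples")
    diff = rec.mean(axis=1) - non.mean(axis=1)
    se2 = rec.var(axis=1, ddof=1) / na + non.var(axis=1, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    zero_se = se2 == 0.0
    if zero_se.any():
        d = diff[zero_se]
        t[zero_se] = np.choose(np.sign(d).astype(int) + 1, [-np.inf, 0.0, np.inf])
    return t


def _as_recurrent_mask(labels, sample_ids) -> np.ndarray:
    """Accept string labels, +/-1, or 0/1 aligned with sample_ids."""
    arr = np.asarray(labels)
    if arr.shape[0] != len(sample_ids):
        raise ValueError("labels must align with the matrix sample IDs")
    if arr.dtype.kind in "OU<SU":
        valid = np.isin(arr, [CLASS_RECURRENT, CLASS_NON_RECURRENT])
        if not valid.all():
            raise ValueError(f"unlabeled samples present: {np.asarray(sample_ids)[~valid][:5]}")
        return arr == CLASS_RECURRENT
    return np.asarray(arr, dtype=float) > 0


def rank_order(t: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by |t| descending, ties by gene_id lexicographic."""
    lex = np.argsort(np.asarray(gene_ids, dtype=str))
    lex_rank = np.empty_like(lex)
    lex_rank[lex] = np.arange(len(lex))
    return np.lexsort((lex_rank, -np.abs(t)))


def rank_genes(expr: ExpressionMatrix, labels) -> pd.DataFrame:
    """Welch-t ranking of every gene on the given samples.

    Returns a DataFrame (gene_id, t_statistic, abs_rank) ordered by |t|
    descending; rank 1 is the strongest separator. Requires >= 2 samples in
    each class.
    """
    mask = _as_recurrent_mask(labels, expr.sample_ids)
    t = welch_t_matrix(expr.values, mask)
    order = rank_order(t, expr.gene_ids)
    return pd.DataFrame({
        "gene_id": expr.gene_ids[order],
        "t_statistic": t[order],
        "abs_rank": np.arange(1, expr.n_genes + 1),
    })


def select_top(ranking: pd.DataFrame, m: int) -> list:
    """Top-m gene IDs in rank order."""
    if not 1 <= m <= len(ranking):
        raise ValueError(f"m must be in [1, {len(ranking)}], got {m}")
    return ranking["gene_id"].head(m).tolist()


def write_ranking(ranking: pd.DataFrame, path: str) -> None:
    ranking.to_csv(path, sep="\t", index=False, float_format="%.6g")
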