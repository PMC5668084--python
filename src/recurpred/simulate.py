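"""Synthetic FFPE-microarray recurrence cohorts.

Generates a log2 expression matrix, a clinical sample table with censored
disease-free survival (DFS), and a ground-truth record, with the statistical
structure the downstream analysis assumes:

* a latent per-patient risk class whose hazard of recurrence is ``hr_true``
  times the baseline — the quantity the Cox evaluation should recover;
* an observed recurrence label (event before censoring), which is how a
  retrospective outcome-selected cohort is labeled;
* a planted differentially expressed signature separating the observed
  outcome groups, plus per-batch additive offsets and a replicated reference
  sample in every processing batch;
* administrative censoring, uniform loss to follow-up, and a minimum
  follow-up for event-free patients (retrospective enrollment rule).

The generator is deterministic given (config, seed): identical inputs yield
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CLASS_NON_RECURRENT,
    CLASS_RECURRENT,
    ExpressionMatrix,
    ROLE_TRAIN,
    ROLE_VALIDATION,
    STAGES,
    validate_sample_table,
)

# stage frequencies conditional on the latent risk class, matching the
# published cohort composition (81% stage I overall; low-risk patients are
# overwhelmingly stage I, high-risk patients skew to IB and beyond)
_STAGE_PROBS_LOW = (50 / 101, 48 / 101, 1 / 101, 1 / 101, 1 / 101)
_STAGE_PROBS_HIGH = (18 / 110, 55 / 110, 10 / 110, 4 / 110, 23 / 110)


@dataclass
class SimConfig:
    """Cohort generator settings.

    Defaults emulate the study conditions: 211 patients selected ~1:1 by
    recurrence status, 58 reserved for blind validation, 20 processing
    batches each carrying a replicated reference sample, and a true
    recurrence hazard ratio of 4.5 between latent risk classes. Expression
    effect size and DE fraction are calibration choices producing a
    moderate-signal cohort (the study reports no per-gene effect sizes).
    """

    n_genes: int = 2000
    n_samples: int = 211
    frac_recurrent: float = 0.5
    frac_de_genes: float = 0.05
    effect_size_delta: float = 0.22
    gene_sd_range: tuple = (0.3, 0.8)
    n_batches: int = 20
    batch_sd: float = 0.15
    hr_true: float = 4.5
    baseline_median_dfs_months: float = 240.0
    weibull_shape: float = 1.0
    censor_admin_months: float = 120.0
    loss_followup_range: tuple = (24.0, 120.0)
    min_followup_nonrecurrent: float = 48.0
    stage_probs: dict = field(
        default_factory=lambda: {"low": _STAGE_PROBS_LOW, "high": _STAGE_PROBS_HIGH}
    )
    frac_validation: float = 58 / 211
    force_exact_ratio: bool = True
    baseline_mean: float = 7.0
    baseline_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_recurrent", "frac_de_genes", "frac_validation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("n_genes >= 1 and n_samples >= 2 required")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.hr_true <= 0:
            raise ValueError("hr_true must be positive")
        if self.gene_sd_range[0] <= 0 or self.gene_sd_range[1] < self.gene_sd_range[0]:
            raise ValueError("gene_sd_range must be 0 < low <= high")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        for key in ("low", "high"):
            p = np.asarray(self.stage_probs[key], dtype=float)
            if len(p) != len(STAGES) or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
                raise ValueError(f"stage_probs[{key!r}] must be a probability vector "
                                 f"over {STAGES}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_sd_range"] = list(self.gene_sd_range)
        d["loss_followup_range"] = list(self.loss_followup_range)
        d["stage_probs"] = {k: list(v) for k, v in self.stage_probs.items()}
        return d


@dataclass
class LatentTruth:
    """Ground truth for recovery tests; never read by the pipeline itself."""

    sample_ids: np.ndarray
    latent_class: np.ndarray      # 1 = recurrence-prone (high hazard)
    realized_class: np.ndarray    # observed label used for training
    gene_ids: np.ndarray
    de_mask: np.ndarray           # planted differential expression indicator
    true_delta: np.ndarray        # signed log2 shift (0 for non-DE genes)

    def n_de(self) -> int:
        return int(self.de_mask.sum())


def _draw_patients(n: int, cfg: SimConfig, rng: np.random.Generator):
    """Latent class, stage, DFS time, event indicator for n patients."""
    z = (rng.random(n) < cfg.frac_recurrent).astype(int)
    stage_low = rng.choice(len(STAGES), size=n, p=np.asarray(cfg.stage_probs["low"], float)
                           / np.sum(cfg.stage_probs["low"]))
    stage_high = rng.choice(len(STAGES), size=n, p=np.asarray(cfg.stage_probs["high"], float)
                            / np.sum(cfg.stage_probs["high"]))
    stage = np.where(z == 1, stage_high, stage_low)

    # proportional-hazards Weibull (shape 1 = exponential) with rate scaled
    # so the latent low-risk class has the configured median DFS
    lam = math.log(2.0) / cfg.baseline_median_dfs_months ** cfg.weibull_shape
    rate = lam * np.where(z == 1, cfg.hr_true, 1.0)
    t_event = (rng.exponential(1.0, n) / rate) ** (1.0 / cfg.weibull_shape)

    lo, hi = cfg.loss_followup_range
    censor = np.minimum(cfg.censor_admin_months, rng.uniform(lo, hi, n))
    event = t_event <= censor

    # retrospective enrollment: event-free patients need a minimum follow-up;
    # short-censored non-events get their censoring time redrawn beyond the
    # minimum, which may reveal an event (label flips are intentional)
    short = (~event) & (censor < cfg.min_followup_nonrecurrent)
    if short.any():
        censor[short] = rng.uniform(
            cfg.min_followup_nonrecurrent, max(cfg.censor_admin_months,
                                               cfg.min_followup_nonrecurrent + 1e-9),
            short.sum(),
        )
        event = t_event <= censor

    dfs = np.where(event, t_event, censor)
    return z, stage, dfs, event.astype(int)


def generate_cohort(config: SimConfig):
    """Simulate one cohort.

    Returns ``(ExpressionMatrix, sample table, LatentTruth)``. The expression
    matrix contains the patient columns followed by one replicated reference
    sample per batch (same underlying profile, fresh noise, sharing each
    batch's additive offsets).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    if cfg.force_exact_ratio:
        # retrospective outcome-balanced selection: draw a patient pool and
        # keep n//2 recurrent plus the non-recurrent remainder (odd n leaves
        # the extra sample on the non-recurrent side)
        n_rec, n_non = n // 2, n - n // 2
        pool = max(3 * n, n + 40)
        z, stage, dfs, event = _draw_patients(pool, cfg, rng)
        rec_idx = np.flatnonzero(event == 1)
        non_idx = np.flatnonzero(event == 0)
        if len(rec_idx) < n_rec or len(non_idx) < n_non:
            raise ValueError(
                f"n_samples={n} cannot be met as a 1:1 cohort (pool of {pool} "
                f"yielded {len(rec_idx)} recurrent, {len(non_idx)} non-recurrent)"
            )
        keep = np.sort(np.concatenate([
            rng.choice(rec_idx, n_rec, replace=False),
            rng.choice(non_idx, n_non, replace=False),
        ]))
        z, stage, dfs, event = z[keep], stage[keep], dfs[keep], event[keep]
    else:
        z, stage, dfs, event = _draw_patients(n, cfg, rng)

    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object)
    realized = np.where(event == 1, CLASS_RECURRENT, CLASS_NON_RECURRENT)

    # gene-level truth
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(cfg.n_genes)], dtype=object)
    n_de = round(cfg.frac_de_genes * cfg.n_genes)
    de_mask = np.zeros(cfg.n_genes, dtype=bool)
    de_mask[rng.choice(cfg.n_genes, n_de, replace=False)] = True
    sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    true_delta = np.where(de_mask, sign * cfg.effect_size_delta, 0.0)

    # expression: baseline + outcome-group shift (DE genes) + batch + noise
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    gene_sd = rng.uniform(*cfg.gene_sd_range, cfg.n_genes)

    batch_ids = np.array([f"B{b + 1:02d}" for b in range(cfg.n_batches)], dtype=object)
    batch_of = batch_ids[rng.permutation(n) % cfg.n_batches]
    batch_offsets = rng.normal(0.0, cfg.batch_sd, (cfg.n_batches, cfg.n_genes))
    batch_pos = {b: i for i, b in enumerate(batch_ids)}

    is_rec = (realized == CLASS_RECURRENT).astype(float)
    values = (
        mu[:, None]
        + true_delta[:, None] * is_rec[None, :]
        + batch_offsets[[batch_pos[b] for b in batch_of], :].T
        + rng.normal(0.0, 1.0, (cfg.n_genes, n)) * gene_sd[:, None]
    )

    # one replicated reference sample per batch: shared profile, shared batch
    # offset, fresh technical noise
    ref_profile = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    ref_values = (
        ref_profile[:, None]
        + batch_offsets.T
        + rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_batches)) * gene_sd[:, None]
    )
    ref_ids = np.array([f"REF_{b}" for b in batch_ids], dtype=object)

    expr = ExpressionMatrix(
        gene_ids,
        np.concatenate([sample_ids, ref_ids]),
        np.hstack([values, ref_values]),
    )

    # train/validation roles on patients only
    n_val = round(cfg.frac_validation * n)
    roles = np.full(n, ROLE_TRAIN, dtype=object)
    roles[rng.choice(n, n_val, replace=False)] = ROLE_VALIDATION

    patients = pd.DataFrame({
        "sample_id": sample_ids,
        "class": realized,
        "stage": np.asarray(STAGES, dtype=object)[stage],
        "dfs_months": np.round(dfs, 4),
        "event": event,
        "batch": batch_of,
        "role": roles,
        "is_reference": False,
    })
    refs = pd.DataFrame({
        "sample_id": ref_ids,
        "class": "",
        "stage": "",
        "dfs_months": np.nan,
        "event": np.nan,
        "batch": batch_ids,
        "role": "",
        "is_reference": True,
    })
    samples = validate_sample_table(pd.concat([patients, refs], ignore_index=True))

    truth = LatentTruth(
        sample_ids=sample_ids,
        latent_class=z.astype(int),
        realized_class=realized,
        gene_ids=gene_ids,
        de_mask=de_mask,
        true_delta=true_delta,
    )
    return expr, samples, truth


def write_truth(truth: LatentTruth, path: str) -> None:
    """Tab-delimited ground truth (sample block, then gene block)."""
    rows = []
    for sid, z, c in zip(truth.sample_ids, truth.latent_class, truth.realized_class):
        rows.append(("sample", sid, int(z), c, ""))
    for gid, de, d in zip(truth.gene_ids, truth.de_mask, truth.true_delta):
        rows.append(("gene", gid, int(de), "", repr(float(d))))
    pd.DataFrame(rows, columns=["kind", "id", "flag", "label", "delta"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str) -> LatentTruth:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str}, keep_default_na=False)
    s = df[df["kind"] == "sample"]
    g = df[df["kind"] == "gene"]
    return LatentTruth(
        sample_ids=s["id"].to_numpy(object),
        latent_class=s["flag"].to_numpy(int),
        realized_class=s["label"].to_numpy(object),
        gene_ids=g["id"].to_numpy(object),
        de_mask=g["flag"].to_numpy(int).astype(bool),
        true_delta=g["delta"].astype(float).to_numpy(),
    )
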