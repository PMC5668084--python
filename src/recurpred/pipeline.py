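"""End-to-end orchestration: simulate/load -> QC -> train -> predict -> evaluate.

The pipeline enforces the blinding protocol of a true external validation:
the predict stage receives validation expression through a blinded view that
strips clinical columns, and outcomes are consumed only by the evaluate
stage, after all predictions are fixed. Training-set (out-of-bag) and
validation evaluations are reported side by side so the hazard-ratio
similarity between them — the robustness check of the training procedure —
can be read off directly.

All randomness derives from one master seed: each stage's seed is
``SeedSequence(master_seed, spawn_key=(crc32(stage_name),))``, so stages are
independently reproducible and two runs with the same inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import io as rio
from . import simulate as sim
from . import survival as surv

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """All tunables of a full run, echoed verbatim into every output."""

    # data: either paths to an existing cohort, or a synthetic one
    expression_path: str | None = None
    samples_path: str | None = None
    outcomes_path: str | None = None
    simulate: dict | None = None        # SimConfig field overrides

    # ensemble
    reps: int = 500
    k_out: int = 5
    m: int = 100
    k: int = 1
    class_weighted: bool = False

    # evaluation
    cutoff: float = 0.0
    confidence_band: float = 0.5
    qc_threshold: float = 0.95
    horizon_months: float = 60.0
    strata: dict | None = None

    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.simulate is None and (self.expression_path is None or
                                      self.samples_path is None):
            raise ValueError("either simulate: or expression/samples paths are required")
        if self.reps < 1 or self.k_out < 1 or self.m < 1:
            raise ValueError("reps, k_out and m must be positive")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_cohort(config: RunConfig):
    """Returns (expr, samples, truth-or-None). Simulated cohorts get a stage seed."""
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
        sim_cfg = sim.SimConfig(**overrides)
        expr, samples, truth = sim.generate_cohort(sim_cfg)
        return expr, samples, truth
    expr = rio.read_expression(config.expression_path)
    samples = rio.read_sample_table(config.samples_path)
    expr, samples = rio.align(expr, samples)
    return expr, samples, None


def _outcomes_table(config: RunConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Outcome columns, consumed only by the evaluate stage."""
    if config.outcomes_path is not None:
        return rio.read_sample_table(config.outcomes_path)
    has_outcomes = (~samples["is_reference"]) & samples["class"].isin(
        [rio.CLASS_RECURRENT, rio.CLASS_NON_RECURRENT]
    ) & samples["dfs_months"].notna()
    return samples[has_outcomes].copy()


def run_blind_validation(config: RunConfig) -> dict:
    """Execute the full pipeline and return the paired evaluation report.

    Stages run strictly in order; the external scores exist before the
    validation outcome table is first read. If ``config.out_dir`` is set,
    the model bundle, score tables, truth file (for simulated cohorts) and
    report JSON are written there.
    """
    config.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    expr, samples, truth = _load_cohort(config)
    timings["load"] = time.perf_counter() - t0

    # --- QC on reference samples (skipped when the design lacks them) -------
    t0 = time.perf_counter()
    qc_report = None
    ref_batches = samples.loc[samples["is_reference"], "batch"].nunique()
    if ref_batches >= 2:
        qc_report = rio.batch_qc(expr, samples, threshold=config.qc_threshold)
        if not qc_report.passed:
            logger.warning("batch QC failed: min correlation %.4f < %.4f",
                           qc_report.min_correlation, qc_report.threshold)
    timings["qc"] = time.perf_counter() - t0

    # --- train on the training cohort only ----------------------------------
    t0 = time.perf_counter()
    train_tab = samples[(samples["role"] == rio.ROLE_TRAIN) & (~samples["is_reference"])]
    plan = ens.make_splits(len(train_tab), config.k_out, config.reps,
                           stage_seed(config.seed, "train"))
    model = ens.train_ensemble(expr, samples, plan, m=config.m, k=config.k,
                               class_weighted=config.class_weighted)
    timings["train"] = time.perf_counter() - t0

    # --- predict: internal out-of-bag + blinded external --------------------
    t0 = time.perf_counter()
    internal_scores = ens.score_internal(model, cutoff=config.cutoff)
    blinded = rio.blind_sample_table(samples)
    val_ids = blinded.loc[
        (blinded["role"] == rio.ROLE_VALIDATION) & (~blinded["is_reference"]),
        "sample_id",
    ]
    external_scores = None
    if len(val_ids):
        external_scores = ens.score_external(model, expr.subset_samples(val_ids),
                                             cutoff=config.cutoff)
    timings["predict"] = time.perf_counter() - t0

    # --- evaluate: outcomes are read only past this point -------------------
    t0 = time.perf_counter()
    outcomes = _outcomes_table(config, samples)
    training_eval = surv.evaluate_cohort(
        internal_scores, outcomes, strata=config.strata,
        horizon=config.horizon_months, cutoff=config.cutoff,
    )
    validation_eval = None
    if external_scores is not None:
        val_outcomes = outcomes[outcomes["sample_id"].isin(set(val_ids))]
        if len(val_outcomes) == 0:
            raise ValueError("no outcomes available for the validation samples; "
                             "evaluation of the blind set is impossible")
        validation_eval = surv.evaluate_cohort(
            external_scores, val_outcomes, strata=config.strata,
            horizon=config.horizon_months, cutoff=config.cutoff,
        )
    timings["evaluate"] = time.perf_counter() - t0

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_training": int(len(train_tab)),
        "n_validation": int(len(val_ids)),
        "split_redraws": model.redraw_count,
        "signature_size": int(len(model.signature)),
        "qc": json.loads(qc_report.to_json()) if qc_report else None,
        "training": training_eval,
        "validation": validation_eval,
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
    }

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        ens.save_model(model, os.path.join(config.out_dir, "model"))
        ens.write_scores(internal_scores,
                         os.path.join(config.out_dir, "scores_training_oob.tsv"))
        if external_scores is not None:
            ens.write_scores(external_scores,
                             os.path.join(config.out_dir, "scores_validation.tsv"))
        if truth is not None:
            sim.write_truth(truth, os.path.join(config.out_dir, "truth.tsv"))
        surv.report_to_json(report, os.path.join(config.out_dir, "report.json"))
    return report
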