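#!/usr/bin/env python
"""Blind external validation and survival evaluation.

Scores the 58 held-out patients from expression alone (their outcome columns
are stripped before prediction), then — and only then — joins outcomes to
produce the paired training/validation evaluation: KM curves by predicted
risk, 5-year DFS separation, log-rank, Cox hazard ratios with 95% CIs
overall and for stage I / IA / IB, and the training ROC.

The headline comparison is training vs validation HR: similar values
indicate the resampling procedure did not overfit.
"""

import json

import recurpred as rp
from recurpred.ensemble import read_scores
from recurpred.io import ROLE_VALIDATION, blind_sample_table
from recurpred.survival import plot_km, plot_roc

COHORT_DIR = "scratch/cohort"


def main() -> None:
    expr = rp.read_expression(f"{COHORT_DIR}/expression.tsv")
    samples = rp.read_sample_table(f"{COHORT_DIR}/samples.tsv")
    expr, samples = rp.align(expr, samples)
    model = rp.load_model("scratch/model")

    # --- predict stage: expression only, clinical columns blinded ----------
    blinded = blind_sample_table(samples)
    val_ids = blinded.loc[(blinded["role"] == ROLE_VALIDATION)
                          & (~blinded["is_reference"]), "sample_id"]
    val_scores = rp.score_external(model, expr.subset_samples(val_ids))
    from recurpred.ensemble import write_scores
    write_scores(val_scores, "results/scores_validation.tsv")

    # --- evaluate stage: outcomes are read only from here on ----------------
    outcomes = samples[~samples["is_reference"]]
    oob_scores = read_scores("results/scores_training_oob.tsv")
    training_eval = rp.evaluate_cohort(oob_scores, outcomes)
    validation_eval = rp.evaluate_cohort(
        val_scores, outcomes[outcomes["sample_id"].isin(set(val_ids))])

    report = {"training": training_eval, "validation": validation_eval}
    with open("results/report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)

    t_all = training_eval["strata"]["all"]
    v_all = validation_eval["strata"]["all"]
    cls = training_eval["classification"]
    print(f"training   HR={t_all['cox']['hr']:.2f} "
          f"(95% CI {t_all['cox']['ci_low']:.2f}-{t_all['cox']['ci_high']:.2f}), "
          f"5y-DFS diff={t_all['dfs_diff_at_horizon']:.0%}")
    if v_all.get("estimable"):
        print(f"validation HR={v_all['cox']['hr']:.2f} "
              f"(95% CI {v_all['cox']['ci_low']:.2f}-{v_all['cox']['ci_high']:.2f}), "
              f"5y-DFS diff={v_all['dfs_diff_at_horizon']:.0%}")
    for stage in ("I", "IA", "IB"):
        blk = training_eval["strata"][stage]
        if blk.get("estimable"):
            print(f"stage {stage:<3} HR={blk['cox']['hr']:.2f}, "
                  f"5y-DFS diff={blk['dfs_diff_at_horizon']:.0%} (n={blk['n']})")
    print(f"training AUC={cls['auc']:.2f} "
          f"sens={cls['sensitivity']:.2f} spec={cls['specificity']:.2f}")

    scored = oob_scores[oob_scores["n_votes"] > 0].merge(outcomes, on="sample_id")
    plot_km(t_all, "Training DFS by predicted risk", "scratch/km_training.png")
    if v_all.get("estimable"):
        plot_km(v_all, "Validation DFS by predicted risk", "scratch/km_validation.png")
    plot_roc(rp.roc(scored["score"], scored["class"].to_numpy()), "scratch/roc_training.png")
    print("report -> results/report.json, figures -> scratch/")


if __name__ == "__main__":
    main()
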