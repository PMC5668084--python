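"""Survival-based evaluation of risk calls against disease-free survival.

DFS is the time from surgery to recurrence or death, censored at last
follow-up. Risk groups come from the ensemble's score calls; performance is
summarized by Kaplan-Meier curves, the 5-year DFS difference, the two-group
log-rank test, the univariate Cox hazard ratio (high vs low risk) with a
Wald CI, and ROC/AUC with a DeLong CI. Medium-risk (low-confidence) calls
are reported but never excluded from any hazard-ratio computation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import CLASS_RECURRENT

logger = logging.getLogger(__name__)

HORIZON_5Y = 60.0


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate: steps only at event times, S(0) = 1."""

    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood
    n: int
    max_time: float

    def survival_at(self, t: float) -> float:
        """S(t): value at the largest event time <= t (1.0 before any event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Ties are handled conventionally: deaths at a time precede censorings at
    the same time, i.e. censored-at-t subjects remain in the risk set at t.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("km_estimate requires at least one record")
    if (time < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    surv, var_terms = [], []
    s, g = 1.0, 0.0
    n_risk, n_ev = [], []
    for t in uniq:
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        if at_risk > d:
            g += d / (at_risk * (at_risk - d))
        else:
            g = np.inf
        surv.append(s)
        var_terms.append(s * s * g if np.isfinite(g) else 0.0)
        n_risk.append(at_risk)
        n_ev.append(d)
    return KMCurve(
        event_times=uniq,
        n_risk=np.array(n_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
        survival=np.array(surv),
        variance=np.array(var_terms),
        n=len(time),
        max_time=float(time.max()),
    )


def dfs_at(curve: KMCurve, horizon: float = HORIZON_5Y) -> float:
    """Survival proportion at the horizon (60 months = 5-year DFS)."""
    if horizon > curve.max_time:
        logger.warning("horizon %.1f exceeds maximum follow-up %.1f", horizon, curve.max_time)
    return curve.survival_at(horizon)


# ------------------------------------------------------------------- log-rank

@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_events: int


def logrank(time, event, group) -> LogRankResult:
    """Two-group log-rank test (observed minus expected over shared event times)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group).astype(bool)
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    n_events = int(event.sum())
    if n_events == 0:
        warnings.warn("log-rank undefined with zero events", stacklevel=2)
        return LogRankResult(float("nan"), float("nan"), 0)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & group).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        stat = 0.0 if abs(o_minus_e) < 1e-12 else float("inf")
    else:
        stat = o_minus_e ** 2 / var
    return LogRankResult(float(stat), float(stats.chi2.sf(stat, df=1)), n_events)


# ------------------------------------------------------------- univariate Cox

@dataclass
class CoxFit:
    """Single binary covariate Cox fit (high- vs low-risk group)."""

    beta: float
    hr: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float  # likelihood-ratio test
    n: int
    n_events: int
    infinite: bool = False
    converged: bool = True
    ties: str = "breslow"


def _cox_quantities(time, event, group):
    """Per-event-time (d, d1, n1, n0) for the binary-covariate partial likelihood."""
    out = []
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        ev_here = (time == t) & (event == 1)
        out.append((
            int(ev_here.sum()),
            int((ev_here & group).sum()),
            int((at_risk & group).sum()),
            int((at_risk & ~group).sum()),
        ))
    return out


def cox_partial_loglik(beta: float, time, event, group, ties: str = "breslow") -> float:
    """Log partial likelihood at beta (Breslow or Efron tie handling)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group).astype(bool)
    eb = np.exp(beta)
    ll = 0.0
    for d, d1, n1, n0 in _cox_quantities(time, event, group):
        ll += d1 * beta
        if ties == "breslow":
            ll -= d * np.log(n0 + n1 * eb)
        elif ties == "efron":
            for j in range(d):
                ll -= np.log((n0 - j / d * (d - d1)) + (n1 - j / d * d1) * eb)
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return float(ll)


def cox_univariate(time, event, group, ties: str = "breslow",
                   tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Maximize the Cox partial likelihood for one binary covariate.

    Newton-Raphson from beta = 0; Wald CI exp(beta +/- 1.96 SE); p-value from
    the likelihood-ratio statistic. A monotone likelihood (all events in one
    group) is reported via the ``infinite`` flag rather than a number.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group).astype(bool)
    n = len(time)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("Cox fit requires at least one event")
    if group.all() or not group.any():
        raise ValueError("group indicator is constant")
    ev1 = int(event[group].sum())
    if ev1 == 0 or ev1 == n_events:
        return CoxFit(beta=np.inf if ev1 else -np.inf, hr=np.inf if ev1 else 0.0,
                      se=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                      n=n, n_events=n_events, infinite=True, converged=False, ties=ties)

    quant = _cox_quantities(time, event, group)

    def score_info(beta: float):
        eb = np.exp(beta)
        u = info = 0.0
        for d, d1, n1, n0 in quant:
            if ties == "breslow":
                a, b = n1 * eb, float(n0)
                r = a + b
                u += d1 - d * a / r
                info += d * a * b / r ** 2
            else:  # efron
                for j in range(d):
                    a = (n1 - j / d * d1) * eb
                    b = n0 - j / d * (d - d1)
                    r = a + b
                    u += -a / r
                u += d1
                for j in range(d):
                    a = (n1 - j / d * d1) * eb
                    b = n0 - j / d * (d - d1)
                    info += a * b / (a + b) ** 2
        return u, info

    beta, converged = 0.0, False
    for _ in range(max_iter):
        u, info = score_info(beta)
        if info <= 0:
            break
        step = u / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 20:  # numerically monotone likelihood
            return CoxFit(beta=np.sign(beta) * np.inf,
                          hr=np.inf if beta > 0 else 0.0,
                          se=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                          n=n, n_events=n_events, infinite=True, converged=False,
                          ties=ties)
    _, info = score_info(beta)
    se = 1.0 / np.sqrt(info)
    lr = 2.0 * (cox_partial_loglik(beta, time, event, group, ties)
                - cox_partial_loglik(0.0, time, event, group, ties))
    return CoxFit(
        beta=float(beta),
        hr=float(np.exp(beta)),
        se=float(se),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(stats.chi2.sf(max(lr, 0.0), df=1)),
        n=n,
        n_events=n_events,
        infinite=False,
        converged=converged,
        ties=ties,
    )


# ------------------------------------------------------------------- ROC/AUC

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_se: float
    ci_low: float
    ci_high: float
    p_value: float  # DeLong test of AUC = 0.5
    n_pos: int
    n_neg: int


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc(scores, labels) -> ROCResult:
    """ROC over all score cutoffs; trapezoid AUC (= Mann-Whitney concordance
    with ties counted 1/2) with DeLong variance for the CI."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN (unscored samples must be dropped first)")
    pos_mask = np.asarray(labels) == CLASS_RECURRENT if np.asarray(labels).dtype.kind in "OU" \
        else np.asarray(labels).astype(bool)
    pos, neg = scores[pos_mask], scores[~pos_mask]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(pos_mask.astype(int), scores, drop_intermediate=False)
    # DeLong structural components
    r_all = _midranks(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - _midranks(pos)) / n
    v01 = 1.0 - (r_all[m:] - _midranks(neg)) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = float("nan")
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr,
        auc=auc, auc_se=se,
        ci_low=float(max(0.0, auc - 1.959963984540054 * se)),
        ci_high=float(min(1.0, auc + 1.959963984540054 * se)),
        p_value=p, n_pos=m, n_neg=n,
    )


def sens_spec(scores, labels, cutoff: float = 0.0):
    """(sensitivity, specificity) at a score cutoff.

    Sensitivity: fraction of recurrent samples with score > cutoff.
    Specificity: fraction of non-recurrent samples with score <= cutoff
    (a score exactly at the cutoff is called low-risk).
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos_mask = lab == CLASS_RECURRENT if lab.dtype.kind in "OU" else lab.astype(bool)
    if not pos_mask.any() or pos_mask.all():
        raise ValueError("both classes must be present")
    sens = float((scores[pos_mask] > cutoff).mean())
    spec = float((scores[~pos_mask] <= cutoff).mean())
    return sens, spec


# -------------------------------------------------------------- cohort report

DEFAULT_STRATA = {"all": None, "I": ("IA", "IB"), "IA": ("IA",), "IB": ("IB",)}


def _km_block(curve: KMCurve, horizon: float) -> dict:
    return {
        "event_times": curve.event_times.tolist(),
        "survival": curve.survival.tolist(),
        "n": curve.n,
        "max_time": curve.max_time,
        "dfs_at_horizon": dfs_at(curve, horizon),
        "horizon_within_followup": bool(horizon <= curve.max_time),
    }


def evaluate_cohort(scores: pd.DataFrame, outcomes: pd.DataFrame,
                    strata: dict | None = None, horizon: float = HORIZON_5Y,
                    cutoff: float = 0.0) -> dict:
    """Full evaluation of risk scores against DFS outcomes, per stage stratum.

    ``scores`` carries (sample_id, score, call); ``outcomes`` carries
    (sample_id, class, stage, dfs_months, event). Every scored patient is
    included in every HR — medium-risk calls are counted but not excluded.
    ROC and sensitivity/specificity are reported for the pooled cohort only.
    """
    strata = DEFAULT_STRATA if strata is None else strata
    merged = scores.merge(outcomes, on="sample_id", how="inner")
    merged = merged[merged["call"].isin(["high", "low"])]
    if merged.empty:
        raise ValueError("no scored samples with outcomes to evaluate")
    merged = merged.copy()
    merged["dfs_months"] = merged["dfs_months"].astype(float)
    merged["event"] = merged["event"].astype(int)

    report: dict = {"horizon_months": horizon, "cutoff": cutoff, "strata": {}}

    for name, stages in strata.items():
        sub = merged if stages is None else merged[merged["stage"].isin(stages)]
        block: dict = {"n": int(len(sub))}
        if len(sub) == 0:
            block["estimable"] = False
            block["reason"] = "empty stratum"
            report["strata"][name] = block
            continue
        high = sub[sub["call"] == "high"]
        low = sub[sub["call"] == "low"]
        block["n_high"] = int(len(high))
        block["n_low"] = int(len(low))
        block["n_events"] = int(sub["event"].sum())
        block["n_medium_risk"] = int((sub["confidence"] == "medium_risk").sum()) \
            if "confidence" in sub.columns else None
        if len(high) == 0 or len(low) == 0:
            block["estimable"] = False
            block["reason"] = "only one risk group present"
            report["strata"][name] = block
            continue
        if sub["event"].sum() == 0:
            block["estimable"] = False
            block["reason"] = "zero events"
            report["strata"][name] = block
            continue
        block["estimable"] = True
        km_high = km_estimate(high["dfs_months"], high["event"])
        km_low = km_estimate(low["dfs_months"], low["event"])
        block["km_high"] = _km_block(km_high, horizon)
        block["km_low"] = _km_block(km_low, horizon)
        block["dfs_diff_at_horizon"] = block["km_low"]["dfs_at_horizon"] - \
            block["km_high"]["dfs_at_horizon"]
        lr = logrank(sub["dfs_months"], sub["event"], sub["call"] == "high")
        block["logrank"] = {"statistic": lr.statistic, "p_value": lr.p_value}
        cox = cox_univariate(sub["dfs_months"], sub["event"], sub["call"] == "high")
        block["cox"] = {
            "hr": cox.hr, "ci_low": cox.ci_low, "ci_high": cox.ci_high,
            "p_value": cox.p_value, "beta": cox.beta, "infinite": cox.infinite,
            "n_events": cox.n_events,
        }
        report["strata"][name] = block

    have_labels = merged["class"].isin([CLASS_RECURRENT, "non_recurrent"])
    labeled = merged[have_labels]
    if labeled["class"].nunique() == 2:
        r = roc(labeled["score"], labeled["class"])
        sn, sp = sens_spec(labeled["score"], labeled["class"], cutoff)
        report["classification"] = {
            "auc": r.auc, "auc_ci_low": r.ci_low, "auc_ci_high": r.ci_high,
            "auc_p_value": r.p_value, "sensitivity": sn, "specificity": sp,
            "n_recurrent": r.n_pos, "n_non_recurrent": r.n_neg,
        }
    return report


def report_to_json(report: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)


# -------------------------------------------------------------------- plotting

def plot_km(report_block: dict, title: str, path: str) -> None:
    """Step plot of the high/low-risk KM curves from one report stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, color in (("km_low", "tab:blue"), ("km_high", "tab:red")):
        blk = report_block[key]
        t = [0.0] + blk["event_times"]
        s = [1.0] + blk["survival"]
        ax.step(t, s, where="post", color=color,
                label=f"{key[3:]} risk (n={blk['n']})")
    ax.set_xlabel("months since surgery")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(result: ROCResult, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(result.fpr, result.tpr, color="tab:red",
            label=f"AUC = {result.auc:.2f} ({result.ci_low:.2f}-{result.ci_high:.2f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
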