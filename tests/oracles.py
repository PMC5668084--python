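"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, two-pass formulas)
and shares no code with the package under test.
"""

import math

import numpy as np


def naive_pearson(x, y):
    """Two-pass Pearson correlation with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / math.sqrt(sxx * syy)


def naive_welch(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    return (ma - mb) / math.sqrt(va / na + vb / nb)


def naive_nn_vote(train, labels, query, k=1):
    """Exhaustive correlation-distance k-NN vote; ties by lowest index."""
    dists = [1.0 - naive_pearson(train[:, j], query) for j in range(train.shape[1])]
    order = sorted(range(len(dists)), key=lambda j: (dists[j], j))
    tally = sum(labels[j] for j in order[:k])
    return 1 if tally > 0 else -1


def naive_auc(scores, positive):
    """Pairwise Mann-Whitney concordance, ties counted 1/2."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def naive_cox_loglik(beta, time, event, group):
    """Breslow partial log-likelihood for one binary covariate, all loops."""
    n = len(time)
    ll = 0.0
    for i in range(n):
        if not event[i]:
            continue
        risk = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                risk += math.exp(beta * group[j])
        ll += beta * group[i] - math.log(risk)
    return ll


def grid_cox_beta(time, event, group, lo=-5.0, hi=5.0):
    """Grid-search maximizer of the naive partial likelihood, ~1e-5 grid."""
    grid = np.linspace(lo, hi, 2001)
    lls = [naive_cox_loglik(b, time, event, group) for b in grid]
    best = grid[int(np.argmax(lls))]
    fine = np.linspace(best - 0.01, best + 0.01, 2001)
    lls = [naive_cox_loglik(b, time, event, group) for b in fine]
    return float(fine[int(np.argmax(lls))])


def empirical_survival(times, t):
    """Fraction of subjects with time > t (no-censoring survival function)."""
    return sum(1 for x in times if x > t) / len(times)
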