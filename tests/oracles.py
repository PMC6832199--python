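"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a different route (pair enumeration,
exhaustive scan, permutation, grid search) and must stay free of the code
paths it validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def pair_count_auc(pos, neg) -> float:
    """AUC as the tie-adjusted fraction of (positive, negative) pairs with
    positive > negative (ties credit 1/2)."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_youden(values, is_positive):
    """Exhaustive threshold scan for the high-is-positive Youden cut-point.

    Candidate thresholds follow the shared contract: midpoints between
    consecutive distinct values plus one sentinel below/above the range.
    Ties on J broken by higher sensitivity, then lower threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    uniq = np.unique(v)
    thresholds = (
        [uniq[0] - 1.0]
        + [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
        + [uniq[-1] + 1.0]
    )
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    best = None
    for t in thresholds:
        sens = int(((v > t) & y).sum()) / n_pos
        spec = int(((v <= t) & ~y).sum()) / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, j, sens, spec)
    return {"cutoff": best[1], "j": best[2], "sens": best[3], "spec": best[4]}


def exact_mw_two_tailed_p(a, b) -> float:
    """Two-tailed exact rank-sum p by full enumeration (no ties, tiny n)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2.0
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def hand_km(times, events):
    """Naive product-limit computation over the distinct event times."""
    times = list(map(float, times))
    events = list(map(bool, events))
    taus = sorted({t for t, e in zip(times, events) if e})
    surv = []
    s = 1.0
    for tau in taus:
        n = sum(1 for t in times if t >= tau)
        d = sum(1 for t, e in zip(times, events) if t == tau and e)
        s *= 1.0 - d / n
        surv.append(s)
    return taus, surv


def _logrank_chi2_matrices(times, events):
    """Precompute per-event-time risk/death indicator matrices."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    taus = np.unique(t[e])
    at_risk = (t[:, None] >= taus[None, :]).astype(float)  # (n, T)
    death = ((t[:, None] == taus[None, :]) & e[:, None]).astype(float)
    return at_risk, death


def permutation_logrank_p(times, events, labels, n_perm, seed):
    """Monte-Carlo permutation p for the 2-group log-rank chi-square.

    Recomputes the same statistic (hypergeometric-variance chi-square) for
    ``n_perm`` random relabelings, vectorized over permutations.
    """
    g = np.asarray(labels)
    groups = np.unique(g)
    assert groups.size == 2
    ind = (g == groups[0]).astype(float)

    at_risk, death = _logrank_chi2_matrices(times, events)
    n_tot = at_risk.sum(axis=0)
    d_tot = death.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)

    def chi2_for(label_matrix):
        n1 = label_matrix @ at_risk  # (B, T)
        o1 = (label_matrix @ death).sum(axis=1)
        frac = n1 / n_tot
        e1 = (d_tot * frac).sum(axis=1)
        v = (mult * frac * (1.0 - frac)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(v > 0, (o1 - e1) ** 2 / v, 0.0)
        return chi2

    obs = float(chi2_for(ind[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, ind.size)), axis=1)
    label_matrix = ind[perms]
    stats = chi2_for(label_matrix)
    return obs, float(np.mean(stats >= obs - 1e-12))


def grid_search_cox_beta(times, events, x, lo=-5.0, hi=5.0, step=1e-4):
    """Argmax of the Breslow partial log-likelihood over a fixed grid."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    order = np.argsort(-t, kind="mergesort")  # descending time
    ts, es, xs = t[order], e[order], x[order]
    grid = np.arange(lo, hi + step / 2, step)

    expo = np.exp(np.outer(grid, xs))  # (B, n)
    cums = np.cumsum(expo, axis=1)
    # risk-set sum for each subject's time = cumulative sum through the last
    # subject sharing that time (ties included)
    last_idx = np.empty(ts.size, dtype=int)
    i = 0
    while i < ts.size:
        j = i
        while j + 1 < ts.size and ts[j + 1] == ts[i]:
            j += 1
        last_idx[i : j + 1] = j
        i = j + 1
    ll = np.zeros(grid.size)
    for i in range(ts.size):
        if es[i]:
            ll += grid * xs[i] - np.log(cums[:, last_idx[i]])
    return float(grid[int(np.argmax(ll))])


def midrank_oracle(values):
    """Direct midrank computation by scanning sorted positions."""
    v = list(map(float, values))
    sorted_v = sorted(v)
    ranks = []
    for x in v:
        lo = sorted_v.index(x) + 1
        hi = lo + sorted_v.count(x) - 1
        ranks.append((lo + hi) / 2.0)
    return ranks
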