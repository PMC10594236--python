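"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written in the most direct form available
(pairwise enumeration, per-bin loops, explicit matrix algebra) and shares no
code with the library paths it checks.
"""

from itertools import combinations

import numpy as np


def concordance_auc(scores, labels):
    """AUC as the Mann-Whitney pair-concordance probability: over every
    (positive, negative) pair, count wins + half-ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def rank_sum_p_exhaustive(b, a):
    """Exact one-sided rank-sum p-value (alternative: b smaller) by full
    enumeration of all assignments of the pooled sample into the two groups.
    Only feasible for tiny n."""
    pooled = np.concatenate([b, a])
    ranks = _rank(pooled)
    nb = len(b)
    observed = ranks[:nb].sum()
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), nb):
        total += 1
        if ranks[list(idx)].sum() <= observed:
            count += 1
    return count / total


def _rank(x):
    """Mid-ranks (1-based, ties averaged)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def label_segments_bruteforce(vel, dist, target, n_window, half_width):
    """Per-bin loop re-implementation of the segment labeler for one finger
    group.  Returns dicts keyed by end bin."""
    n = len(vel)
    out = {}
    for k in range(n_window - 1, n):
        w = range(k - n_window + 1, k + 1)
        vs = [vel[i] for i in w]
        ds = [dist[i] for i in w]
        if all(v > 0 for v in vs):
            mt = "flexion"
        elif all(v < 0 for v in vs):
            mt = "extension"
        else:
            mt = "inconsistent"
        switch = any(target[i] != target[k] for i in w)
        if switch:
            direction = None
        elif all(v * d > 0 for v, d in zip(vs, ds)):
            direction = "toward"
        elif all(v * d < 0 for v, d in zip(vs, ds)):
            direction = "away"
        else:
            direction = None
        loc = "inside" if abs(dist[k]) <= half_width else "outside"
        out[k] = (mt, direction, loc)
    return out


def kf_step_by_hand(A, W, H, Q, x, P, y):
    """Textbook predict/update written with explicit inverses."""
    xp = A @ x
    Pp = A @ P @ A.T + W
    S = H @ Pp @ H.T + Q
    K = Pp @ H.T @ np.linalg.inv(S)
    xn = xp + K @ (y - H @ xp)
    Pn = (np.eye(len(x)) - K @ H) @ Pp
    return xn, Pn


def ols_r2_by_channel(X, Y):
    """R^2 per column of Y from the normal equations (with intercept)."""
    X1 = np.column_stack([X, np.ones(len(X))])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ Y)
    resid = Y - X1 @ beta
    sse = (resid**2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    return 1.0 - sse / sst


def lda_direction(X, y):
    """Pooled-covariance Fisher discriminant direction."""
    X0, X1 = X[y == 0], X[y == 1]
    S = ((len(X0) - 1) * np.cov(X0.T) + (len(X1) - 1) * np.cov(X1.T)) / (len(X) - 2)
    return np.linalg.solve(S, X1.mean(axis=0) - X0.mean(axis=0))
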