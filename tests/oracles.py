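"""Slow, independent reference implementations used only to check the package.

Each oracle is deliberately naive (brute-force counting, enumeration,
plain gradient iterations) so that agreement with the fast implementation
is informative.
"""

import numpy as np


def brute_auc(scores, y):
    """AUC by explicit counting over all (positive, negative) pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_bh(pvals, q=0.05):
    """Benjamini-Hochberg rejections by the textbook step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def prox_grad_l1_logistic(X, y, lam, max_iter=200_000, tol=1e-13):
    """ISTA on (1/n) sum log-loss + lam * ||w||_1 with unpenalized intercept."""
    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    L = 0.25 * (np.linalg.norm(X, 2) ** 2) / n + 0.25
    step = 1.0 / L
    for _ in range(max_iter):
        z = X @ w + b
        mu = 1.0 / (1.0 + np.exp(-z))
        g = X.T @ (mu - y) / n
        gb = np.mean(mu - y)
        w_new = w - step * g
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        b_new = b - step * gb
        if max(np.max(np.abs(w_new - w)), abs(b_new - b)) < tol:
            return w_new, b_new
        w, b = w_new, b_new
    return w, b


def _mi_discrete(a, b):
    """Plug-in MI (nats) of two discrete vectors by explicit cell loops."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    total = 0.0
    for u in np.unique(a):
        for v in np.unique(b):
            p_uv = np.mean((a == u) & (b == v))
            if p_uv > 0:
                total += p_uv * np.log(p_uv / (np.mean(a == u) * np.mean(b == v)))
    return max(total, 0.0)


def _equal_freq_bins(x, bins=10):
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def greedy_mrmr_bruteforce(X, y, bins=10):
    """Greedy MID ranking evaluated literally: relevance minus mean redundancy,
    both as plug-in MI on equal-frequency-discretized features."""
    p = X.shape[1]
    disc = [_equal_freq_bins(X[:, j], bins) for j in range(p)]
    rel = [_mi_discrete(disc[j], y) for j in range(p)]
    order = [int(np.argmax(rel))]
    while len(order) < p:
        best, best_crit = None, -np.inf
        for j in range(p):
            if j in order:
                continue
            red = np.mean([_mi_discrete(disc[j], disc[s]) for s in order])
            crit = rel[j] - red
            if crit > best_crit:
                best, best_crit = j, crit
        order.append(best)
    return order


def sens_at_spec_scan(scores, y, spec):
    """Exhaustive scan over every candidate threshold (midpoints + sentinels)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos, neg = scores[y == 1], scores[y == 0]
    uniq = np.unique(scores)
    cands = np.concatenate(([-np.inf], uniq, (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else [], [np.inf]))
    best = None
    for t in np.sort(cands):
        if np.mean(neg < t) >= spec:
            best = (float(np.mean(pos >= t)), float(np.mean(neg < t)), float(t))
            break
    if best is None:
        best = (0.0, float(np.mean(neg < np.inf)), np.inf)
    return best
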