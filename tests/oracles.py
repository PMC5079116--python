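"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double loops, exhaustive enumeration)
and shares no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np


def brute_pearson(x, y):
    """Textbook Pearson formula over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den if den else float("nan"), n


def brute_silhouette(labels, d):
    """Double-loop silhouette; labels and d are plain sequences/arrays."""
    labels = list(labels)
    d = np.asarray(d, dtype=float)
    n = len(labels)
    clusters = sorted(set(labels))
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in clusters
            if c != labels[i]
        )
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def fisher_tail(a, b, c, d):
    """One-sided over-representation p for table [[a, b], [c, d]] by direct
    summation of hypergeometric terms."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
    return p


def ranksum_exact_p(a, b):
    """Exact two-sided rank-sum p by full enumeration (no ties)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(pooled)
    na = len(a)
    mean_w = na * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def mst_total_weight(n, weights):
    """Minimum spanning-tree weight by enumerating all spanning trees.

    ``weights`` maps frozenset({i, j}) -> weight.  Enumerates all edge
    subsets of size n-1 and keeps the cheapest connected, acyclic one.
    Feasible for n <= 7.
    """
    edges = list(weights.items())
    best = None
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        ok = True
        for pair, _ in subset:
            i, j = tuple(pair)
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if ok:
            total = sum(w for _, w in subset)
            if best is None or total < best:
                best = total
    return best


def set_partitions(n):
    """Yield every partition of range(n) as an integer label array
    (restricted-growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([labels.copy()])


def exhaustive_max_modularity(adj):
    """Maximum modularity over all partitions, plus the argmax labels."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    k = adj.sum(axis=1)
    m = adj.sum() / 2.0
    b = adj - np.outer(k, k) / (2.0 * m)
    best_q, best_labels = -np.inf, None
    for labels in set_partitions(n):
        same = labels[:, None] == labels[None, :]
        q = (b * same).sum() / (2.0 * m)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    return best_q, best_labels


def partition_modularity(adj, labels):
    adj = np.asarray(adj, dtype=float)
    labels = np.asarray(labels)
    k = adj.sum(axis=1)
    m = adj.sum() / 2.0
    b = adj - np.outer(k, k) / (2.0 * m)
    same = labels[:, None] == labels[None, :]
    return (b * same).sum() / (2.0 * m)
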