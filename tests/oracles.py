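"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration, textbook recurrences) and shares no code with the
implementation it checks.
"""

from itertools import combinations

import numpy as np


def hotspot_oracle(sites, length, half_window=7, min_neighbors=5):
    """All-windows scan + interval merge, O(n^2) per enzyme.

    Returns a list of (start, end) merged hotspot intervals.
    """
    records = sorted({(s.position, s.ptm_type) for s in sites})
    qualifying = []
    for pos, ptm in records:
        n_in = sum(1 for q, t in records if abs(q - pos) <= half_window)
        if n_in - 1 >= min_neighbors:  # exclude the central record
            qualifying.append((max(1, pos - half_window), min(length, pos + half_window)))
    merged = []
    for start, end in sorted(qualifying):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def crosstalk_oracle(sites):
    """Positions whose per-position type tally has cardinality >= 2."""
    tally = {}
    for s in sites:
        tally.setdefault(s.position, set()).add(s.ptm_type)
    return sorted(p for p, types in tally.items() if len(types) >= 2)


def midrank(values):
    """Midranks computed from first principles."""
    values = list(values)
    ranks = []
    for v in values:
        below = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(below + (equal + 1) / 2)
    return np.array(ranks, dtype=float)


def spearman_oracle(x, y):
    """Rank-then-Pearson with midrank ties."""
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def u_by_pairs(a, b):
    """U for group a by direct pairwise comparison."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by exhaustive enumeration of all
    group assignments of the pooled sample, with the symmetric
    |U - n_a n_b / 2| extremeness definition."""
    pooled = list(a) + list(b)
    n_a = len(a)
    mu = n_a * (len(pooled) - n_a) / 2
    u_obs = u_by_pairs(a, b)
    extreme = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_by_pairs(ga, gb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def ward_oracle_labels(X, k):
    """Naive O(n^3) Ward agglomeration via the Lance-Williams update.

    Returns flat cluster labels after merging down to k clusters.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    # Ward merge cost between clusters A, B with centroids cA, cB:
    # |A||B|/(|A|+|B|) * ||cA - cB||^2  (for singletons: half the
    # squared Euclidean distance)
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = 0.5 * float(((X[i] - X[j]) ** 2).sum())
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(clusters) > k:
        (a, b), _ = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters.pop(a) + clusters.pop(b)
        for key in [key for key in d2 if a in key or b in key]:
            d2.pop(key)
        new = next_id
        next_id += 1
        # direct recomputation of the Ward cost to every other cluster
        for c, members in clusters.items():
            ca = X[merged].mean(axis=0)
            cb = X[members].mean(axis=0)
            nm, nc = len(merged), len(members)
            dist = (nm * nc) / (nm + nc) * float(((ca - cb) ** 2).sum())
            d2[(min(new, c), max(new, c))] = dist
        clusters[new] = merged
        sizes[new] = len(merged)
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(clusters.values(), key=min)):
        labels[members] = lab
    return labels
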