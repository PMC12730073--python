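"""Independent brute-force oracles used to validate the library paths.

Each oracle is written from the definitional formula (explicit sums, pair
enumeration, ECDF sweeps, naive O(n^3) agglomeration) and never calls into
the package it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# --------------------------------------------------------------------------
# two-way ANOVA ICC via explicit sums of squares


def icc_a1_sums_of_squares(Y: np.ndarray) -> float:
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    grand = Y.sum() / (n * k)
    ssr = sum(k * (Y[i].sum() / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (Y[:, j].sum() / n - grand) ** 2 for j in range(k))
    sst = sum((Y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# --------------------------------------------------------------------------
# naive pairwise feature-feature distances (double loop over columns)


def naive_feature_distances(X: np.ndarray, metric: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    d = np.zeros((p, p))
    for j in range(p):
        for k in range(p):
            x, y = X[:, j], X[:, k]
            if metric == "euclidean":
                d[j, k] = np.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))
            elif metric == "manhattan":
                d[j, k] = sum(abs(xi - yi) for xi, yi in zip(x, y))
            elif metric == "cosine":
                num = sum(xi * yi for xi, yi in zip(x, y))
                den = np.sqrt(sum(xi**2 for xi in x)) * np.sqrt(
                    sum(yi**2 for yi in y)
                )
                d[j, k] = 1.0 - num / den
            else:
                raise ValueError(metric)
    return d


# --------------------------------------------------------------------------
# exhaustive pair-counting adjusted Rand index


def ari_pair_counting(la, lb) -> float:
    la, lb = list(la), list(lb)
    n = len(la)
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(n), 2):
        same_a = la[i] == la[j]
        same_b = lb[i] == lb[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    total = n * (n - 1) / 2
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = ((n11 + n10) + (n11 + n01)) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def all_set_partitions(items: list):
    """Every partition of ``items`` as a list of blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def labels_from_blocks(items: list, blocks: list) -> list:
    label = {}
    for c, block in enumerate(blocks):
        for item in block:
            label[item] = c
    return [label[i] for i in items]


# --------------------------------------------------------------------------
# two-sample KS via an exhaustive ECDF sweep over all breakpoints


def ks_ecdf_sweep(a, b) -> float:
    a, b = list(a), list(b)
    best = 0.0
    for t in sorted(set(a) | set(b)):
        fa = sum(x <= t for x in a) / len(a)
        fb = sum(x <= t for x in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


# --------------------------------------------------------------------------
# naive O(n^3) agglomerative clustering
#
# single/complete/average use their definitional formulas over the original
# matrix; ward/centroid use the standard recurrence on squared distances,
# evaluated freshly over all cluster pairs at every step.


def naive_agglomerate(D: np.ndarray, linkage: str):
    """Return the merge sequence [(set_i, set_j, height), ...]."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    # squared inter-cluster distances for the recurrence-based linkages
    sq = {
        (frozenset([i]), frozenset([j])): D[i, j] ** 2
        for i in range(n)
        for j in range(n)
        if i != j
    }
    merges = []

    def dist(ci: frozenset, cj: frozenset) -> float:
        pairs = [(a, b) for a in ci for b in cj]
        if linkage == "single":
            return min(D[a, b] for a, b in pairs)
        if linkage == "complete":
            return max(D[a, b] for a, b in pairs)
        if linkage == "average":
            return sum(D[a, b] for a, b in pairs) / len(pairs)
        if linkage in ("ward.D2", "centroid"):
            return np.sqrt(sq[(ci, cj)])
        raise ValueError(linkage)

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        ci, cj = clusters[x], clusters[y]
        merged = ci | cj
        merges.append((ci, cj, d))
        remaining = [c for idx, c in enumerate(clusters) if idx not in (x, y)]
        for ck in remaining:
            ni, nj, nk = len(ci), len(cj), len(ck)
            dik, djk, dij = sq[(ci, ck)], sq[(cj, ck)], sq[(ci, cj)]
            if linkage == "centroid":
                new = (ni * dik + nj * djk) / (ni + nj) - (
                    ni * nj * dij
                ) / (ni + nj) ** 2
            else:  # ward.D2
                new = (
                    (ni + nk) * dik + (nj + nk) * djk - nk * dij
                ) / (ni + nj + nk)
            sq[(merged, ck)] = sq[(ck, merged)] = new
        clusters = remaining + [merged]
    return merges


def merge_sets_from_scipy(Z: np.ndarray):
    """Convert a scipy linkage matrix to the same merge-sequence format."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step in range(n - 1):
        i, j = int(Z[step, 0]), int(Z[step, 1])
        merges.append((members[i], members[j], float(Z[step, 2])))
        members[n + step] = members[i] | members[j]
    return merges
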