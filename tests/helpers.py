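"""Independent oracles used by the tests: deliberately naive implementations
that share no code with the package."""

from __future__ import annotations

import math

import numpy as np


def naive_upgma(dissimilarity: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) average-linkage agglomeration on a dense matrix.

    Returns the merge list as (members_a, members_b, height) with the
    average inter-cluster dissimilarity as the height.  Ties are broken by
    the smallest pair of cluster indices, matching deterministic UPGMA.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
                height = float(np.mean([d[i, j] for i, j in pairs]))
                if best is None or height < best[0] - 1e-15:
                    best = (height, a, b)
        height, a, b = best
        merges.append((clusters[a], clusters[b], height))
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        next_id += 1
    return merges


def hypergeom_tail_enum(k: int, n_universe: int, n_set: int, n_draw: int) -> float:
    """P(X >= k) for a hypergeometric variable by exhaustive summation."""
    total = math.comb(n_universe, n_draw)
    acc = 0
    for x in range(k, min(n_set, n_draw) + 1):
        if n_draw - x > n_universe - n_set:
            continue
        acc += math.comb(n_set, x) * math.comb(n_universe - n_set, n_draw - x)
    return acc / total


def binom_tail_sum(k: int, n: int, p: float) -> float:
    """P(X >= k) for a binomial variable by direct summation of the pmf."""
    return sum(
        math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1)
    )


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Correlation and its two-sided p via scipy's pearsonr (independent path)."""
    from scipy.stats import pearsonr

    r, p = pearsonr(x, y)
    return float(r), float(p)
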