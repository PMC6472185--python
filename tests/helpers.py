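"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in the most literal way possible (double loops,
explicit formulas) and never calls the code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def genorm_m_bruteforce(values: np.ndarray, names: list[str]) -> dict[str, float]:
    """geNorm M by the definition: for each gene, the mean over all other
    genes of the sample SD of the pairwise log2 ratio across samples."""
    n = len(names)
    out = {}
    for j in range(n):
        sds = []
        for k in range(n):
            if k == j:
                continue
            ratios = [math.log2(values[j, s] / values[k, s]) for s in range(values.shape[1])]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            sds.append(math.sqrt(var))
        out[names[j]] = sum(sds) / len(sds)
    return out


def select_housekeepers_bruteforce(
    values: np.ndarray, names: list[str], n_keep: int
) -> list[str]:
    """Literal re-implementation of the iterative removal loop: drop the
    highest-M gene (lexicographically last among ties) and recompute."""
    current = list(names)
    mat = values.copy()
    while len(current) > n_keep:
        m = genorm_m_bruteforce(mat, current)
        worst = max(current, key=lambda g: (m[g], g))
        idx = current.index(worst)
        current.pop(idx)
        mat = np.delete(mat, idx, axis=0)
    return current


def background_threshold_bruteforce(counts) -> float:
    """geomean (zeros -> 1) + 2 * sample SD of the raw counts."""
    counts = list(counts)
    floored = [c if c > 0 else 1 for c in counts]
    geomean = math.exp(sum(math.log(c) for c in floored) / len(floored))
    mean = sum(counts) / len(counts)
    var = sum((c - mean) ** 2 for c in counts) / (len(counts) - 1)
    return geomean + 2.0 * math.sqrt(var)


def naive_average_linkage(points: np.ndarray) -> list[tuple[frozenset, float]]:
    """O(n^3) UPGMA agglomeration on Euclidean distances.

    Returns the merge sequence as (merged leaf set, merge height) pairs.
    Ties are broken by the smallest member index of the first cluster.
    """
    n = points.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            dist = float(
                np.mean(
                    [
                        np.linalg.norm(points[i] - points[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
            )
            key = (dist, min(clusters[a]), min(clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        (dist, _, _), a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((merged, dist))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def scipy_merge_sequence(linkage_matrix: np.ndarray, n: int) -> list[tuple[frozenset, float]]:
    """Convert a SciPy linkage matrix to the same (leaf set, height) form."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, height, _) in enumerate(linkage_matrix):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        merges.append((merged, float(height)))
    return merges
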