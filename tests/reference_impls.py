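"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np

NOISE = -1


def reference_dbscan(points: np.ndarray, eps: float, min_pts: int) -> list[int]:
    """Exhaustive O(n^2) density clustering.

    Core point: >= min_pts neighbors within eps (Euclidean, inclusive,
    self-counting).  Clusters are density-connected components grown
    from core points; border points join the first core that reaches
    them; everything else is noise.
    """
    n = len(points)
    if n == 0:
        return []
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps).tolist() for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbors]
    labels = [NOISE] * n
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == NOISE:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    return labels


def partition_of(labels) -> tuple[frozenset, set]:
    """(set of clusters as index-sets, noise index-set) — id-invariant."""
    clusters: dict[int, set] = {}
    noise = set()
    for i, lab in enumerate(labels):
        if lab == NOISE:
            noise.add(i)
        else:
            clusters.setdefault(lab, set()).add(i)
    return frozenset(frozenset(c) for c in clusters.values()), noise


def grid_overlap_pct(s1: float, e1: float, s2: float, e2: float, dan: float, step: float = 60.0) -> float:
    """Count minute-grid points covered by both intervals, as % of dan."""
    lo = min(s1, s2)
    hi = max(e1, e2)
    grid = np.arange(lo, hi, step)
    both = ((grid >= s1) & (grid < e1) & (grid >= s2) & (grid < e2)).sum()
    return both * step * 100.0 / dan
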