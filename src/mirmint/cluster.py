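"""Agglomerative hierarchical clustering, complete linkage, Euclidean distance.

This is the clustering behind the DE heat maps: items (features or
samples) are merged bottom-up, the distance between clusters being the
maximum pairwise Euclidean distance (complete linkage, which guarantees
monotone merge heights).  Tie-breaks are deterministic: among equally
distant pairs the one with the smallest (index_a, index_b) cluster-id
pair merges first; leaf order is the recursive left-first traversal of
the merge tree.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    """Merge history in the usual linkage convention.

    ``merges[i] = (a, b, height)`` joins clusters a and b (original items
    are 0..n-1, the cluster formed at step i gets id n+i) at the given
    complete-linkage Euclidean height.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    labels: list[str]

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a for a, b in zip(heights, heights[1:])):
            raise ValueError("complete-linkage merge heights must be non-decreasing")

    @property
    def leaf_order(self) -> list[int]:
        """Left-first recursive traversal of the merge tree."""
        n = self.n_leaves
        if n == 1:
            return [0]

        def walk(c: int) -> list[int]:
            if c < n:
                return [c]
            a, b, _ = self.merges[c - n]
            return walk(a) + walk(b)

        return walk(n + len(self.merges) - 1)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_linkage(self) -> np.ndarray:
        """(n-1) x 4 linkage matrix (a, b, height, cluster size)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((len(self.merges), 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            out[i] = (a, b, h, sizes[n + i])
        return out


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "features") -> Dendrogram:
    """Complete-linkage Euclidean clustering of rows ("features") or
    columns ("samples") of a matrix.

    Duplicate items (zero distances) are permitted.
    """
    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    df = matrix if axis == "features" else matrix.T
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    labels = [str(i) for i in df.index]

    D = squareform(pdist(X, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    ids = list(range(n))  # position -> current cluster id
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        m = D.shape[0]
        best = float(D.min())
        cand = np.argwhere(D == best)
        cand = cand[cand[:, 0] < cand[:, 1]]
        # tie-break: smallest (cluster id, cluster id) pair
        bi, bj = min(
            (tuple(c) for c in cand),
            key=lambda c: tuple(sorted((ids[c[0]], ids[c[1]]))),
        )
        a, b = sorted((ids[bi], ids[bj]))
        merges.append((a, b, float(best)))
        # Lance-Williams complete linkage: new row is the elementwise max
        new_row = np.maximum(D[bi], D[bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = np.inf
        D = D2
        ids = [ids[k] for k in keep] + [n + step]
    return Dendrogram(merges=merges, n_leaves=n, labels=labels)
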