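"""Hierarchical clustering of samples on a DE feature subset.

Samples are compared by 1 - Pearson correlation between their expression
profiles (invariant to per-sample affine rescaling) and merged by average
linkage; the dendrogram is cut into k flat groups.  Sample columns are
processed in lexicographic order so ties in the linkage break
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix


@dataclass
class Dendrogram:
    merges: np.ndarray          # scipy linkage matrix, (n-1) x 4
    leaf_order: list[str]       # lexicographically sorted sample ids
    metric: str = "1 - pearson"
    linkage: str = "average"

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def render(self) -> str:
        """Plain-text merge history: one line per merge."""
        n = len(self.leaf_order)
        names = {i: self.leaf_order[i] for i in range(n)}
        lines = []
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = names.get(a, f"cluster{a}")
            lb = names.get(b, f"cluster{b}")
            names[n + k] = f"cluster{n + k}"
            lines.append(f"merge {n + k}: {la} + {lb} @ {h:.4f}")
        return "\n".join(lines)


def correlation_distance(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Condensed 1 - Pearson distance between sample profiles."""
    sample_ids = sorted(m.sample_ids)
    X = m.values[sample_ids].to_numpy(dtype=float).T  # samples x features
    sd = X.std(axis=1)
    for sid, s in zip(sample_ids, sd):
        if s == 0:
            raise ValueError(f"sample {sid!r} has a constant profile; correlation undefined")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)  # symmetrise away rounding noise
    return squareform(D, checks=False), sample_ids


def hierarchical_cluster(
    m: ExpressionMatrix, feature_subset: Sequence[str] | None = None, k: int = 2
) -> tuple[Dendrogram, pd.Series]:
    """Cluster samples on *feature_subset* and cut into *k* flat groups.

    Returns the dendrogram and a Series of 1-based group labels indexed
    by sample id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = m if feature_subset is None else m.subset_features(feature_subset)
    dist, sample_ids = correlation_distance(sub)
    Z = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # canonical renumbering: groups numbered by first-seen sample order
    remap: dict[int, int] = {}
    canon = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        canon.append(remap[lab])
    dend = Dendrogram(Z, sample_ids)
    return dend, pd.Series(canon, index=sample_ids, name="group")


def rand_index(a: Sequence, b: Sequence) -> float:
    """Plain Rand index between two flat partitions of the same items."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same items")
    n = len(a)
    if n < 2:
        return 1.0
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree / comb(n, 2))


def groups_to_tsv(groups: pd.Series, path: str | Path) -> None:
    out = groups.to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
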