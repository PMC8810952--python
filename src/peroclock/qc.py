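"""Array QC: interarray-correlation clustering and technical-outlier flagging.

The procedure: compute 1 minus the pairwise interarray Pearson correlation
as a dissimilarity, build an average-linkage (UPGMA) dendrogram, cut its
branches at a fixed height (0.03 by default), and flag samples that end up
in undersized clusters or that fail to correlate with the rest of their own
(tissue, species) group.  Flagging never removes anything — removal is an
explicit, separate call so the decision is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datamodel import BetaMatrix, MethylationDataset

__all__ = [
    "Dendrogram",
    "interarray_dissimilarity",
    "average_linkage_cluster",
    "cut_tree",
    "flag_outliers",
    "qc_report",
]


@dataclass
class Dendrogram:
    """UPGMA merge tree in scipy linkage-matrix form plus leaf ids.

    ``merges`` has one row per merge: (node_i, node_j, height, size); nodes
    0..n-1 are leaves in ``leaf_ids`` order, node n+k is the cluster formed
    by merge k.  Heights are non-decreasing.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n_leaves - 1 rows")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        label = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            label[n + k] = f"({label[a]}:{la:.6g},{label[b]}:{lb:.6g})"
            height[n + k] = h
        return label[n + self.n_leaves - 2] + ";"


def interarray_dissimilarity(
    data: MethylationDataset | BetaMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """1 - pairwise interarray Pearson correlation over pairwise-complete CpGs.

    Returns (symmetric dissimilarity DataFrame with zero diagonal, ids of
    excluded zero-variance samples).  Zero-variance samples, for which the
    correlation is undefined, are excluded with a warning.
    """
    beta = data.beta if isinstance(data, MethylationDataset) else data
    frame = beta.to_frame()
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    variances = frame.var(axis=0, skipna=True)
    degenerate = list(frame.columns[(variances == 0) | variances.isna()])
    if degenerate:
        warnings.warn(
            f"excluding {len(degenerate)} zero-variance sample(s) from the "
            f"dissimilarity matrix: {degenerate[:5]}",
            stacklevel=2,
        )
        frame = frame.drop(columns=degenerate)
        if frame.shape[1] < 2:
            raise ValueError("fewer than 2 samples with variance remain")
    corr = frame.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        raise ValueError("undefined pairwise correlation (no overlapping CpGs?)")
    diss = 1.0 - corr
    np.fill_diagonal(diss.values, 0.0)
    return diss, degenerate


def average_linkage_cluster(dissimilarity: pd.DataFrame | np.ndarray) -> Dendrogram:
    """UPGMA dendrogram of a symmetric dissimilarity matrix (deterministic)."""
    if isinstance(dissimilarity, pd.DataFrame):
        leaf_ids = [str(c) for c in dissimilarity.columns]
        matrix = dissimilarity.to_numpy(dtype=float)
    else:
        matrix = np.asarray(dissimilarity, dtype=float)
        leaf_ids = [str(i) for i in range(matrix.shape[0])]
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    condensed = squareform(matrix, checks=False)
    merges = linkage(condensed, method="average")
    return Dendrogram(merges=merges, leaf_ids=leaf_ids)


def cut_tree(dendrogram: Dendrogram, height: float) -> pd.Series:
    """Cluster labels from merges strictly below ``height``.

    At height 0 every leaf is its own cluster; above the last merge there is
    one cluster.  Labels are integers ordered by first occurrence.
    """
    if height < 0:
        raise ValueError("height must be >= 0")
    n = dendrogram.n_leaves
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k, (a, b, h, _) in enumerate(dendrogram.merges):
        if h < height:
            ra, rb = find(int(a)), find(int(b))
            parent[ra] = parent[rb] = n + k
    roots = [find(i) for i in range(n)]
    order: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in order:
            order[r] = len(order)
        labels.append(order[r])
    return pd.Series(labels, index=dendrogram.leaf_ids, name="cluster")


def cut_tree_k(dendrogram: Dendrogram, n_clusters: int) -> pd.Series:
    """Cluster labels at the cut producing exactly ``n_clusters`` clusters
    (i.e. undoing the last ``n_clusters`` - 1 merges)."""
    if not 1 <= n_clusters <= dendrogram.n_leaves:
        raise ValueError("n_clusters must be in [1, n_leaves]")
    if n_clusters == dendrogram.n_leaves:
        return cut_tree(dendrogram, 0.0)
    heights = dendrogram.merges[:, 2]
    threshold = heights[len(heights) - n_clusters + 1]
    labels = cut_tree(dendrogram, threshold)
    if labels.nunique() != n_clusters:  # ties at the threshold height
        from scipy.cluster.hierarchy import fcluster

        raw = fcluster(dendrogram.merges, t=n_clusters, criterion="maxclust")
        labels = pd.Series(raw, index=dendrogram.leaf_ids, name="cluster")
    return labels


def flag_outliers(
    dataset: MethylationDataset,
    height: float = 0.03,
    min_cluster_size: int = 2,
    group_cor_floor: float | None = 0.5,
    group_keys: tuple[str, ...] = ("tissue", "species"),
) -> list[str]:
    """Flag putative technical outliers; returns ids only, removes nothing.

    A sample is flagged if (a) it lands in a cluster smaller than
    ``min_cluster_size`` when the dendrogram is cut at ``height``, or (b) its
    mean Pearson correlation with the other members of its own annotation
    group (default (tissue, species)) falls below ``group_cor_floor``
    (disable with None).  Samples without group companions skip check (b).
    """
    diss, degenerate = interarray_dissimilarity(dataset)
    flagged: set[str] = set(degenerate)
    dendro = average_linkage_cluster(diss)
    labels = cut_tree(dendro, height)
    sizes = labels.value_counts()
    for sid, cluster in labels.items():
        if sizes[cluster] < min_cluster_size:
            flagged.add(str(sid))
    if group_cor_floor is not None:
        corr = 1.0 - diss
        groups: dict[tuple, list[str]] = {}
        for s in dataset.samples:
            key = tuple(getattr(s, k) for k in group_keys)
            groups.setdefault(key, []).append(s.sample_id)
        for members in groups.values():
            members = [m for m in members if m in corr.index]
            if len(members) < 2:
                continue
            for sid in members:
                others = [m for m in members if m != sid]
                if corr.loc[sid, others].mean() < group_cor_floor:
                    flagged.add(sid)
    return sorted(flagged)


def qc_report(
    dataset: MethylationDataset,
    height: float = 0.03,
    min_cluster_size: int = 2,
    group_cor_floor: float | None = 0.5,
    group_keys: tuple[str, ...] = ("tissue", "species"),
) -> dict:
    """Full QC summary: clusters at the cut, flagged ids, per-sample mean
    group correlation, and the dendrogram in Newick form."""
    diss, degenerate = interarray_dissimilarity(dataset)
    dendro = average_linkage_cluster(diss)
    labels = cut_tree(dendro, height)
    corr = 1.0 - diss
    group_cor: dict[str, float | None] = {}
    groups: dict[tuple, list[str]] = {}
    for s in dataset.samples:
        key = tuple(getattr(s, k) for k in group_keys)
        groups.setdefault(key, []).append(s.sample_id)
    for members in groups.values():
        present = [m for m in members if m in corr.index]
        for sid in present:
            others = [m for m in present if m != sid]
            group_cor[sid] = float(corr.loc[sid, others].mean()) if others else None
    flagged = flag_outliers(dataset, height, min_cluster_size, group_cor_floor, group_keys)
    clusters: dict[int, list[str]] = {}
    for sid, lab in labels.items():
        clusters.setdefault(int(lab), []).append(str(sid))
    return {
        "height": height,
        "min_cluster_size": min_cluster_size,
        "group_cor_floor": group_cor_floor,
        "n_samples": dataset.n_samples,
        "clusters": {str(k): v for k, v in sorted(clusters.items())},
        "flagged": flagged,
        "excluded_zero_variance": degenerate,
        "mean_group_correlation": group_cor,
        "newick": dendro.to_newick(),
    }
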