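"""Ward.D2 hierarchical clustering of drug similarity matrices.

Similarity is converted to distance as d = 1 - s, the agglomerative tree
is built under the Ward criterion in its D2 convention (the objective
squares the input distances; reported merge heights stay on the distance
scale, matching R's ``hclust(..., method = "ward.D2")``), and the number
of clusters is chosen by the relative-loss-of-inertia rule: pick the k for
which merging from k to k-1 clusters traverses the largest height relative
to the preceding merge. Cutting the tree and cophenetic validation are
thin wrappers over scipy's hierarchy toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ClusterTree",
    "cophenetic_correlation",
    "cut_tree",
    "ordered_matrix",
    "select_k_by_inertia",
    "to_distance",
    "to_newick",
    "ward_cluster",
]


@dataclass(frozen=True)
class ClusterTree:
    """Leaf ids plus a scipy linkage matrix (merge pairs and heights)."""

    ids: tuple[str, ...]
    linkage: np.ndarray
    linkage_name: str = "ward_d2"

    def __post_init__(self):
        n = len(self.ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 merges for n leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]


def _check_square(df: pd.DataFrame, what: str) -> None:
    if list(df.index) != list(df.columns):
        raise ValueError(f"{what} must have identical row and column ids")
    v = df.to_numpy(dtype=float)
    if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
        raise ValueError(f"{what} must be symmetric")


def to_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """Elementwise d = 1 - s with the diagonal forced to zero."""
    _check_square(similarity, "similarity matrix")
    v = similarity.to_numpy(dtype=float)
    if np.nanmin(v) < -1e-10 or np.nanmax(v) > 1 + 1e-10:
        raise ValueError("similarity values must lie in [0, 1]")
    d = 1.0 - v
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=similarity.index, columns=similarity.columns)


def ward_cluster(distance: pd.DataFrame, linkage_name: str = "ward_d2") -> ClusterTree:
    """Agglomerate a distance matrix under Ward.D2 (or average linkage)."""
    _check_square(distance, "distance matrix")
    v = distance.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("distance matrix contains NaN")
    if len(distance) < 2:
        raise ValueError("need at least 2 items to cluster")
    method = {"ward_d2": "ward", "average": "average"}[linkage_name]
    condensed = squareform(v, checks=False)
    z = hierarchy.linkage(condensed, method=method)
    return ClusterTree(ids=tuple(distance.index), linkage=z, linkage_name=linkage_name)


def _merge_height(tree: ClusterTree, k: int) -> float:
    """Height of the merge that reduces k+1 clusters to k."""
    n = tree.n_leaves
    return float(tree.linkage[n - k - 1, 2])


def select_k_by_inertia(tree: ClusterTree, k_min: int = 2,
                        k_max: int | None = None) -> int:
    """Cluster count with the highest relative loss of inertia.

    For each candidate k, the criterion compares the merge height
    traversed when collapsing k clusters into k-1 with the height of the
    previous merge (k+1 into k); the k maximizing that ratio marks the
    strongest break in the tree. A positive height over a zero height
    counts as an infinite ratio, zero over zero as no evidence; ties take
    the smallest k. A degenerate tree (all heights equal) returns
    ``k_min`` with a warning.
    """
    n = tree.n_leaves
    if k_max is None:
        k_max = n - 1
    if n == 2:
        return 2
    if not 2 <= k_min < k_max <= n - 1:
        raise ValueError("need 2 <= k_min < k_max <= n-1")
    heights = tree.linkage[:, 2]
    if np.allclose(heights, heights[0]):
        warnings.warn("degenerate tree: all merge heights equal; returning k_min",
                      stacklevel=2)
        return k_min
    best_k, best_ratio = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        num = _merge_height(tree, k - 1)   # merge k -> k-1
        den = _merge_height(tree, k)       # merge k+1 -> k
        if den > 0:
            ratio = num / den
        else:
            ratio = np.inf if num > 0 else 0.0
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Partition into exactly k clusters, labels 1..k by first appearance."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels.append(relabel[lab])
    return pd.Series(labels, index=list(tree.ids), name="cluster")


def cophenetic_correlation(tree: ClusterTree, distance: pd.DataFrame) -> float:
    """Pearson correlation between original and tree-implied distances."""
    if tree.n_leaves < 3:
        raise ValueError("cophenetic correlation needs at least 3 leaves")
    if list(distance.index) != list(tree.ids):
        raise ValueError("distance ids do not match tree leaf ids")
    _check_square(distance, "distance matrix")
    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    c, _ = hierarchy.cophenet(tree.linkage, condensed)
    return float(c)


def to_newick(tree: ClusterTree) -> str:
    """Newick text; a child branch length is its parent height minus its own."""
    z = tree.linkage
    n = tree.n_leaves

    def height(node: int) -> float:
        return 0.0 if node < n else float(z[node - n, 2])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height(node)
        if node < n:
            return f"{tree.ids[node]}:{length:g}"
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{length:g}"

    root = 2 * n - 2
    h = height(root)
    left, right = int(z[root - n, 0]), int(z[root - n, 1])
    return f"({render(left, h)},{render(right, h)});"


def ordered_matrix(similarity: pd.DataFrame, tree: ClusterTree) -> pd.DataFrame:
    """Similarity matrix re-ordered by dendrogram leaf order."""
    order = tree.leaf_order()
    return similarity.loc[order, order]


def write_newick(tree: ClusterTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def write_partition(partition: pd.Series, path) -> None:
    partition.rename_axis("drug_id").to_frame().to_csv(path, sep="\t")


def plot_heatmap(similarity: pd.DataFrame, tree: ClusterTree, path) -> None:
    """Optional clustered-heatmap PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    om = ordered_matrix(similarity, tree)
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(om.to_numpy(), cmap="Reds", vmin=0, vmax=1)
    ax.set_xticks(range(len(om)), om.columns, rotation=90, fontsize=4)
    ax.set_yticks(range(len(om)), om.index, fontsize=4)
    fig.colorbar(im, ax=ax, label=similarity.attrs.get("index_name", "similarity"))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
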