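"""Two-way Ward hierarchical clustering of the lnROR signal matrix.

Agglomerative clustering with Ward's minimum-variance criterion: at each step
the pair of clusters whose merger least increases the total within-cluster sum
of squares is joined.  The implementation runs the Lance–Williams recurrence on
squared Euclidean distances,

    d2(k, i+j) = ((n_i + n_k) d2(i,k) + (n_j + n_k) d2(j,k) - n_k d2(i,j))
                 / (n_i + n_j + n_k),

so the dissimilarity carried for a pair equals twice the sum-of-squares
increase its merger would cost.  Merge heights are reported as the square root
of that dissimilarity (for two singletons: their Euclidean distance), the
height convention of common statistical software; the raw squared value is
available behind ``height_convention="squared"``.  Ties are broken by the
smallest (left, right) node-index pair, making results independent of
floating-point dictionary order.  Drugs are clustered using events as
features, events using drugs as features, and the matrix is reordered by both
dendrogram leaf orders for heatmap display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_matrix import SignalMatrix

__all__ = ["LinkageTree", "ClusterAssignment", "TwoWayClustering",
           "ward_linkage", "cut_tree", "two_way_cluster", "to_newick",
           "write_linkage_tsv", "write_clusters_tsv", "write_heatmap"]

HEIGHT_CONVENTIONS = ("d2", "squared")


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history over one axis.

    Leaves are numbered 0..n_leaves-1 in input order; the cluster created by
    merge ``m`` (0-based) has node index ``n_leaves + m``.  Each merge is
    (left, right, height, size) with left < right.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]
    leaf_labels: tuple[str, ...]
    height_convention: str = "d2"

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a binary merge history over n leaves has n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


@dataclass(frozen=True)
class ClusterAssignment:
    """A cut of a linkage tree into k labeled clusters."""

    k: int
    labels: dict[str, int]          # leaf label -> cluster id (1-based)
    leaf_order: tuple[str, ...]     # dendrogram display order

    def label_vector(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = order if order is not None else self.leaf_order
        return np.array([self.labels[name] for name in order])


def ward_linkage(matrix: np.ndarray, labels: Sequence[str] | None = None,
                 height_convention: str = "d2") -> LinkageTree:
    """Ward's-method linkage over the rows of ``matrix``."""
    if height_convention not in HEIGHT_CONVENTIONS:
        raise ValueError(f"height_convention must be one of {HEIGHT_CONVENTIONS}")
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("ward_linkage needs at least 2 rows to cluster")
    if not np.all(np.isfinite(X)):
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite feature value at row {i}, column {j}")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = tuple(str(s) for s in labels)
    if len(labels) != n:
        raise ValueError("labels length does not match number of rows")

    total = 2 * n - 1
    # d2[i, j]: current Lance-Williams dissimilarity between active nodes.
    d2 = np.full((total, total), np.inf)
    sq = (X ** 2).sum(axis=1)
    base = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    np.fill_diagonal(base, np.inf)
    d2[:n, :n] = np.maximum(base, 0.0)
    np.fill_diagonal(d2[:n, :n], np.inf)
    size = np.zeros(total, dtype=np.int64)
    size[:n] = 1
    active = list(range(n))

    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        # smallest dissimilarity; ties -> smallest (i, j) index pair.
        # ``active`` stays ascending: survivors keep order, new nodes get the
        # largest index so far.
        idx = np.array(active)
        sub = d2[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        pos = int(np.flatnonzero(vals == vals.min())[0])
        dist = float(vals[pos])
        i, j = int(idx[iu[0][pos]]), int(idx[iu[1][pos]])
        new = n + step
        ni, nj = size[i], size[j]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            d2[new, k] = d2[k, new] = (
                (ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * dist
            ) / (ni + nj + nk)
        size[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
        height = math.sqrt(max(dist, 0.0)) if height_convention == "d2" else dist
        merges.append((i, j, float(height), int(ni + nj)))

    return LinkageTree(n_leaves=n, merges=tuple(merges), leaf_labels=labels,
                       height_convention=height_convention)


def _leaf_order_indices(tree: LinkageTree) -> list[int]:
    # depth-first from the root, lower-index child first
    children = {tree.n_leaves + m: (mg[0], mg[1]) for m, mg in enumerate(tree.merges)}
    order: list[int] = []
    stack = [tree.n_leaves + len(tree.merges) - 1]
    while stack:
        node = stack.pop()
        if node < tree.n_leaves:
            order.append(node)
        else:
            left, right = children[node]
            stack.append(right)
            stack.append(left)
    return order


def cut_tree(tree: LinkageTree, k: int) -> ClusterAssignment:
    """Cut the merge sequence after n_leaves - k merges into k clusters.

    Cluster ids are 1-based, numbered by first appearance in the dendrogram
    leaf order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}; got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):
        left, right, _, _ = tree.merges[m]
        new = n + m
        parent[find(left)] = new
        parent[find(right)] = new

    order = _leaf_order_indices(tree)
    cluster_of_root: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in order:
        root = find(leaf)
        if root not in cluster_of_root:
            cluster_of_root[root] = len(cluster_of_root) + 1
        labels[tree.leaf_labels[leaf]] = cluster_of_root[root]
    return ClusterAssignment(k=k, labels=labels,
                             leaf_order=tuple(tree.leaf_labels[i] for i in order))


@dataclass(frozen=True)
class TwoWayClustering:
    """Row (drug) and column (event) trees, cuts, and the reordered grid."""

    drug_tree: LinkageTree
    drug_clusters: ClusterAssignment
    event_tree: LinkageTree
    event_clusters: ClusterAssignment
    reordered: "object"  # pandas DataFrame: drugs x events in dendrogram order


def two_way_cluster(matrix: SignalMatrix, k_drugs: int = 5, k_events: int = 7,
                    standardize: bool = False,
                    height_convention: str = "d2") -> TwoWayClustering:
    """Cluster drugs (features = events) and events (features = drugs).

    ``standardize`` optionally z-scores each event column before clustering
    (off by default: lnROR values share a scale already).
    """
    X = matrix.lnror.astype(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if len(matrix.drugs) < 2 or len(matrix.events) < 2:
        raise ValueError("two-way clustering needs at least 2 drugs and 2 events")
    drug_tree = ward_linkage(X, labels=matrix.drugs, height_convention=height_convention)
    event_tree = ward_linkage(X.T, labels=matrix.events, height_convention=height_convention)
    drug_cut = cut_tree(drug_tree, k_drugs)
    event_cut = cut_tree(event_tree, k_events)

    import pandas as pd
    frame = pd.DataFrame(matrix.lnror, index=list(matrix.drugs), columns=list(matrix.events))
    reordered = frame.loc[list(drug_cut.leaf_order), list(event_cut.leaf_order)]
    return TwoWayClustering(drug_tree=drug_tree, drug_clusters=drug_cut,
                            event_tree=event_tree, event_clusters=event_cut,
                            reordered=reordered)


def to_newick(tree: LinkageTree) -> str:
    """Newick serialization with branch lengths from merge heights (leaves at
    height 0)."""
    heights = {i: 0.0 for i in range(tree.n_leaves)}
    children = {}
    for m, (left, right, h, _) in enumerate(tree.merges):
        node = tree.n_leaves + m
        heights[node] = h
        children[node] = (left, right)

    def esc(label: str) -> str:
        if any(ch in label for ch in " ():,;'\t"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - heights[node], 0.0)
        if node < tree.n_leaves:
            return f"{esc(tree.leaf_labels[node])}:{bl:.10g}"
        left, right = children[node]
        h = heights[node]
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = tree.n_leaves + len(tree.merges) - 1
    left, right = children[root]
    h = heights[root]
    return f"({render(left, h)},{render(right, h)});"


def write_linkage_tsv(tree: LinkageTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("left\tright\theight\tsize\n")
        for left, right, h, size in tree.merges:
            fh.write(f"{left}\t{right}\t{h:.12g}\t{size}\n")


def write_clusters_tsv(assignment: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\tcluster\n")
        for name in assignment.leaf_order:
            fh.write(f"{name}\t{assignment.labels[name]}\n")


def write_heatmap(result: TwoWayClustering, path: str | Path) -> None:
    """Render the reordered lnROR grid (red = high, blue = low)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.reordered
    vmax = float(np.abs(frame.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(6, 0.25 * frame.shape[1]), max(4, 0.35 * frame.shape[0])))
    mesh = ax.pcolormesh(frame.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(np.arange(frame.shape[1]) + 0.5)
    ax.set_xticklabels(frame.columns, rotation=90, fontsize=6)
    ax.set_yticks(np.arange(frame.shape[0]) + 0.5)
    ax.set_yticklabels(frame.index, fontsize=8)
    ax.invert_yaxis()
    fig.colorbar(mesh, ax=ax, label="lnROR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
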