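"""Hierarchical clustering of differentially expressed genes.

Mirrors the Cluster 3.0 workflow: log2-transform, median-centre each gene
row, then agglomerative clustering with *centred correlation* (Pearson) as
the similarity metric and *average linkage* (UPGMA) as the merge rule, for
both genes and samples.  Results can be written as Java TreeView
``.cdt`` / ``.gtr`` / ``.atr`` files.

The linkage is implemented directly (Lance-Williams update) so merge
tie-breaking is deterministic: among equal-distance pairs the
lexicographically smallest pair of current cluster ids merges first, and
leaf order comes from a depth-first traversal that places the child
containing the lower original index first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "preprocess",
    "centered_correlation",
    "similarity_matrix",
    "average_linkage",
    "cluster_matrix",
    "Merge",
    "Tree",
    "ClusterResult",
    "write_cdt",
]


def preprocess(values: pd.DataFrame, de_genes) -> pd.DataFrame:
    """Select DE rows, log2-transform, and centre each row at its median.

    All selected values must be strictly positive (the replacement floor
    guarantees this for post-replacement RPKM).  Applied exactly once per
    matrix: the output carries an attribute flag so a second pass raises.
    """
    if getattr(values, "_spindex_preprocessed", False):
        raise ValueError("matrix has already been preprocessed")
    sub = values.loc[list(de_genes)]
    bad = sub.le(0).any(axis=1)
    if bad.any():
        raise ValueError(
            f"non-positive abundance for gene(s) {sub.index[bad][:5].tolist()}; "
            "log2 transform undefined"
        )
    logged = np.log2(sub)
    centered = logged.sub(logged.median(axis=1), axis=0)
    centered._spindex_preprocessed = True
    return centered


def centered_correlation(x, y) -> float:
    """Pearson correlation of two vectors; 0 (with a warning) if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        warnings.warn("zero-variance vector; similarity defined as 0", stacklevel=2)
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def similarity_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise centred correlation between rows; constant rows get 0."""
    rows = np.asarray(rows, dtype=float)
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance row(s); similarity set to 0",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    unit = centered / safe[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    return sim


@dataclass(frozen=True)
class Merge:
    node: int      # id of the new internal node (n, n+1, ...)
    left: int      # child cluster id (leaf ids are 0..n-1)
    right: int
    distance: float

    @property
    def similarity(self) -> float:
        return 1.0 - self.distance


@dataclass(frozen=True)
class Tree:
    n_leaves: int
    merges: tuple[Merge, ...]

    def leaf_order(self) -> list[int]:
        """Depth-first leaf order; the child holding the lower original
        index is visited first."""
        children = {m.node: (m.left, m.right) for m in self.merges}
        min_leaf: dict[int, int] = {i: i for i in range(self.n_leaves)}
        for m in self.merges:
            min_leaf[m.node] = min(min_leaf[m.left], min_leaf[m.right])
        if not self.merges:
            return list(range(self.n_leaves))
        order: list[int] = []
        stack = [self.merges[-1].node]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
                continue
            left, right = children[node]
            first, second = (
                (left, right) if min_leaf[left] <= min_leaf[right] else (right, left)
            )
            stack.append(second)
            stack.append(first)
        return order


def average_linkage(dist: np.ndarray) -> Tree:
    """UPGMA agglomeration of a symmetric distance matrix.

    Cluster distance is the unweighted mean over all inter-cluster leaf
    pairs (maintained exactly via the Lance-Williams average update).
    Among equal-distance candidates the lexicographically smallest pair of
    current cluster ids merges first.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, rtol=0, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = dist.shape[0]
    if n == 1:
        return Tree(1, ())
    total = 2 * n - 1
    # Working matrix indexed by cluster id; rows of merged-away clusters
    # are masked with +inf, so a row-major argmin yields the smallest
    # (i, j) id pair among equal minima.
    work = np.full((total, total), np.inf)
    work[:n, :n] = dist
    np.fill_diagonal(work, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[Merge] = []
    for new in range(n, total):
        flat = np.argmin(work[:new, :new])
        i, j = divmod(int(flat), new)
        if i > j:
            i, j = j, i
        d = work[i, j]
        ids = np.nonzero(active[:new])[0]
        others = ids[(ids != i) & (ids != j)]
        work[new, others] = (
            sizes[i] * work[i, others] + sizes[j] * work[j, others]
        ) / (sizes[i] + sizes[j])
        work[others, new] = work[new, others]
        sizes[new] = sizes[i] + sizes[j]
        work[i, :] = np.inf
        work[:, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        active[i] = active[j] = False
        active[new] = True
        merges.append(Merge(node=new, left=i, right=j, distance=float(d)))
    return Tree(n, tuple(merges))


@dataclass(frozen=True)
class ClusterResult:
    matrix: pd.DataFrame       # the preprocessed matrix that was clustered
    gene_tree: Tree
    sample_tree: Tree
    gene_order: list[int]
    sample_order: list[int]

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.iloc[self.gene_order, self.sample_order]


def cluster_matrix(prepped: pd.DataFrame) -> ClusterResult:
    """Cluster genes (rows) and samples (columns) of a preprocessed matrix."""
    gene_dist = 1.0 - similarity_matrix(prepped.to_numpy())
    np.fill_diagonal(gene_dist, 0.0)
    sample_dist = 1.0 - similarity_matrix(prepped.to_numpy().T)
    np.fill_diagonal(sample_dist, 0.0)
    gene_tree = average_linkage(gene_dist)
    sample_tree = average_linkage(sample_dist)
    return ClusterResult(
        matrix=prepped,
        gene_tree=gene_tree,
        sample_tree=sample_tree,
        gene_order=gene_tree.leaf_order(),
        sample_order=sample_tree.leaf_order(),
    )


def _tree_lines(tree: Tree, leaf_tag: str) -> list[str]:
    name = {i: f"{leaf_tag}{i}X" for i in range(tree.n_leaves)}
    lines = []
    for k, m in enumerate(tree.merges):
        node = f"NODE{k + 1}X"
        lines.append(
            f"{node}\t{name.get(m.left, _node_name(m.left, tree))}\t"
            f"{name.get(m.right, _node_name(m.right, tree))}\t{m.similarity:.6f}"
        )
    return lines


def _node_name(cluster_id: int, tree: Tree) -> str:
    return f"NODE{cluster_id - tree.n_leaves + 1}X"


def write_cdt(result: ClusterResult, prefix) -> dict[str, str]:
    """Write TreeView ``<prefix>.cdt``, ``.gtr`` and ``.atr`` files.

    Returns the mapping of extension to path.  The CDT holds the
    preprocessed matrix in clustered order with GENE/ARRY node ids; the
    GTR/ATR record the merge lists with similarity scores.
    """
    prefix = str(prefix)
    paths = {"cdt": prefix + ".cdt", "gtr": prefix + ".gtr", "atr": prefix + ".atr"}
    mat = result.matrix
    genes = list(mat.index)
    samples = list(mat.columns)
    with open(paths["gtr"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(_tree_lines(result.gene_tree, "GENE")) + "\n")
    with open(paths["atr"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(_tree_lines(result.sample_tree, "ARRY")) + "\n")
    with open(paths["cdt"], "w", encoding="utf-8") as fh:
        ordered_samples = [samples[j] for j in result.sample_order]
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(ordered_samples) + "\n")
        fh.write(
            "AID\t\t\t"
            + "\t".join(f"ARRY{j}X" for j in result.sample_order)
            + "\n"
        )
        fh.write("EWEIGHT\t\t\t" + "\t".join("1" for _ in ordered_samples) + "\n")
        for i in result.gene_order:
            row = mat.iloc[i, result.sample_order]
            vals = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"GENE{i}X\t{genes[i]}\t1\t{vals}\n")
    return paths
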