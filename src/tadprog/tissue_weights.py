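"""Per-tissue weights from gene-expression divergence.

The consensus TAD map treats tissues as non-independent: closely related
tissues (as judged by their transcriptomes) should not dominate the
consensus simply by being sampled more densely. Tissues are therefore
clustered on a correlation dendrogram and each leaf receives a weight that
summarizes its contribution to total expression divergence; redundant
tissues share, rather than multiply, their influence.

Weighting rule: the *equal-splits* attribution
``raw(leaf) = sum over root-to-leaf edges e of length(e) / n_leaves_below(e)``,
normalized to sum to one. It is exposed behind ``leaf_weights(method=...)``
so an alternative attribution can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "transform_counts",
    "select_variable_genes",
    "build_dendrogram",
    "leaf_weights",
    "assign_map_weights",
    "to_newick",
]


@dataclass
class TreeNode:
    """Node of a rooted tissue dendrogram. Leaves carry a tissue label."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0  # length of the edge to the parent
    height: float = 0.0  # merge height (0 for leaves)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]


def transform_counts(expr: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilize a genes x tissues count matrix.

    Applies log2(count / size_factor + 1) with median-of-ratios size
    factors: the reference is the per-gene geometric mean across tissues
    (genes expressed everywhere), and each tissue's factor is the median
    ratio to that reference. Doubling one tissue's library leaves its
    transformed profile shape invariant.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    if (expr < 0).any().any():
        raise ValueError("counts must be non-negative")
    zero_cols = expr.columns[(expr == 0).all()]
    if len(zero_cols):
        raise ValueError(f"all-zero tissue column(s): {list(zero_cols)}")
    counts = expr.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        size_factors = np.ones(expr.shape[1])
    else:
        log_ref = np.log(counts[positive]).mean(axis=1, keepdims=True)
        ratios = np.log(counts[positive]) - log_ref
        size_factors = np.exp(np.median(ratios, axis=0))
    transformed = np.log2(counts / size_factors + 1.0)
    return pd.DataFrame(transformed, index=expr.index, columns=expr.columns)


def select_variable_genes(expr: pd.DataFrame, n: int = 2000) -> pd.DataFrame:
    """Keep the ``n`` genes with the largest max |x_gt - median_t(x_g)|.

    Ties are broken by gene id; if ``n`` exceeds the gene count all genes
    are kept with a warning.
    """
    med = expr.median(axis=1)
    deviation = (expr.sub(med, axis=0)).abs().max(axis=1)
    if n > len(expr):
        logger.warning("requested %d variable genes but only %d available", n, len(expr))
        n = len(expr)
    order = pd.DataFrame({"dev": deviation, "gene": expr.index.astype(str)})
    order = order.sort_values(["dev", "gene"], ascending=[False, True], kind="mergesort")
    keep = order.index[:n]
    return expr.loc[keep]


def _average_linkage(dist: np.ndarray, labels: list[str]) -> TreeNode:
    """Deterministic UPGMA-style agglomeration.

    Average linkage on a full distance matrix; equal merge heights are
    broken lexicographically by the smallest member label of each cluster.
    Cross-checked against scipy.cluster.hierarchy.linkage in the test
    suite.
    """
    clusters: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in clusters}
    minlab = {i: lab for i, lab in enumerate(labels)}
    d = {frozenset((i, j)): dist[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    next_id = len(labels)
    while len(clusters) > 1:
        # pick the pair with minimal distance; ties by sorted member labels
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted(minlab[i] for i in kv[0]))),
        )
        (pair, h) = best
        i, j = sorted(pair, key=lambda k: minlab[k])
        a, b = clusters.pop(i), clusters.pop(j)
        a.branch_length = h / 2 - a.height
        b.branch_length = h / 2 - b.height
        node = TreeNode(children=[a, b], height=h / 2)
        clusters[next_id] = node
        new_size = sizes[i] + sizes[j]
        for k in list(clusters):
            if k == next_id:
                continue
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / new_size
        del d[pair]
        sizes[next_id] = new_size
        minlab[next_id] = min(minlab[i], minlab[j])
        del sizes[i], sizes[j], minlab[i], minlab[j]
        next_id += 1
    return clusters.popitem()[1]


def build_dendrogram(expr: pd.DataFrame) -> TreeNode:
    """Cluster tissues with distance 1 - Pearson r and average linkage.

    Branch lengths derive from merge heights (ultrametric: each leaf sits
    at depth height/2 below its first merge). A constant expression profile
    has undefined correlation and raises, naming the tissue.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    values = expr.to_numpy(dtype=float)
    stds = values.std(axis=0)
    for tissue, s in zip(expr.columns, stds):
        if s == 0:
            raise ValueError(f"constant expression profile for tissue {tissue!r}: "
                             "correlation undefined")
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return _average_linkage(dist, [str(c) for c in expr.columns])


def _equal_splits_raw(tree: TreeNode) -> dict[str, float]:
    raw: dict[str, float] = {}

    def walk(node: TreeNode, acc: float):
        if node.is_leaf:
            raw[node.label] = acc
            return
        for child in node.children:
            n_below = len(child.leaves())
            walk(child, acc + child.branch_length / n_below)

    walk(tree, 0.0)
    return raw


def leaf_weights(tree: TreeNode, method: str = "equal_splits") -> pd.Series:
    """Per-tissue weights >= 0 summing to 1 from the dendrogram.

    ``equal_splits``: each edge's length is shared equally among the leaves
    below it; a leaf's raw score is the sum of its shares along the
    root-to-leaf path. Degenerate trees with zero total branch length give
    uniform weights.
    """
    if method != "equal_splits":
        raise ValueError(f"unknown leaf-weight method {method!r}")
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    if len(labels) == 1:
        return pd.Series({labels[0]: 1.0})
    raw = _equal_splits_raw(tree)
    total = sum(raw.values())
    if total <= 0:
        weights = {lab: 1.0 / len(labels) for lab in labels}
    else:
        weights = {lab: raw[lab] / total for lab in labels}
    return pd.Series(weights).sort_index()


def assign_map_weights(weights: pd.Series, maps) -> pd.Series:
    """Split tissue weights across that tissue's TAD maps and renormalize.

    A tissue represented by m maps contributes weight/m to each map
    (e.g. two maps for one cell line each receive half the weight); the
    resulting per-map weights are renormalized to sum to 1.
    """
    counts: dict[str, int] = {}
    for m in maps:
        counts[m.sample_id] = counts.get(m.sample_id, 0) + 1
    missing = [s for s in counts if s not in weights.index]
    if missing:
        raise ValueError(f"no tissue weight for map sample(s): {missing}")
    out = {}
    for idx, m in enumerate(maps):
        out[idx] = weights[m.sample_id] / counts[m.sample_id]
    s = pd.Series(out, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("all map weights are zero")
    return s / total


def to_newick(tree: TreeNode) -> str:
    """Serialize the dendrogram in Newick format."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{node.branch_length:g}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{node.branch_length:g}"

    return fmt(tree) + ";"
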