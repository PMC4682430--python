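"""Hierarchical-clustering helpers shared by the array and SNP modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform


def pearson_distance(values: pd.DataFrame) -> np.ndarray:
    """Full 1 - Pearson r distance matrix over the rows of ``values``."""
    r = np.corrcoef(values.to_numpy(dtype=float))
    r = np.clip(np.atleast_2d(r), -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(distance: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree from a square distance matrix."""
    condensed = squareform(np.maximum(distance, 0.0), checks=False)
    return linkage(condensed, method="average")


def leaf_order(merge_tree: np.ndarray, labels: list[str]) -> list[str]:
    return [labels[i] for i in leaves_list(merge_tree)]


def to_newick(merge_tree: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    root = to_tree(merge_tree)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"
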