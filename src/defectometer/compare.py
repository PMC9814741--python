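"""Whole-system classification from the d_SOAP matrix.

Single-linkage agglomerative clustering of the simulation-average
fingerprint distances yields a dendrogram whose leaf order is used to
reshuffle the distance matrix into contiguous blocks; per-reference distance
rankings list the neighbours of one system from most to least similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import squareform

from .metric import DistanceMatrix

__all__ = ["LinkageTree", "single_linkage", "dendrogram_order",
           "rank_by_distance", "to_newick"]


@dataclass
class LinkageTree:
    """Single-linkage merge records (scipy format) plus leaf labels."""

    merges: np.ndarray  # (S-1, 4): left, right, height, size
    leaf_labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cophenetic(self) -> np.ndarray:
        return squareform(cophenet(self.merges))


def single_linkage(dm: DistanceMatrix) -> LinkageTree:
    """Agglomerative single-linkage tree of the system distance matrix.

    scipy's implementation merges the closest pair first and breaks ties by
    the order of the condensed matrix, i.e. by smallest leaf index.
    """
    S = dm.d.shape[0]
    if S < 2:
        raise ValueError("need at least two systems")
    if not np.allclose(dm.d, dm.d.T) or np.any(np.diag(dm.d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    merges = linkage(squareform(dm.d, checks=False), method="single")
    return LinkageTree(merges=merges, leaf_labels=list(dm.labels))


def dendrogram_order(tree: LinkageTree) -> list:
    """Left-to-right leaf order; merged groups occupy contiguous blocks."""
    return [tree.leaf_labels[i] for i in leaves_list(tree.merges)]


def reorder_matrix(dm: DistanceMatrix, tree: LinkageTree) -> DistanceMatrix:
    """The distance matrix permuted into dendrogram leaf order."""
    order = leaves_list(tree.merges)
    return DistanceMatrix(d=dm.d[np.ix_(order, order)],
                          labels=[dm.labels[i] for i in order], params=dm.params)


def rank_by_distance(dm: DistanceMatrix, reference: str):
    """All other systems sorted by ascending d_SOAP to ``reference``.

    Ties keep the label order of the matrix.  Returns a list of
    (label, distance) pairs excluding the reference itself.
    """
    labels = list(dm.labels)
    if reference not in labels:
        raise KeyError(f"unknown reference system {reference!r}")
    r = labels.index(reference)
    others = [(lab, float(dm.d[r, i])) for i, lab in enumerate(labels) if i != r]
    return sorted(others, key=lambda t: t[1])


def to_newick(tree: LinkageTree) -> str:
    """Newick string with branch lengths equal to merge-height increments."""
    S = tree.n_leaves
    heights = {i: 0.0 for i in range(S)}
    reprs = {i: _escape(tree.leaf_labels[i]) for i in range(S)}
    for k, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        node = S + k
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        reprs[node] = f"({reprs[a]}:{la:.6g},{reprs[b]}:{lb:.6g})"
        heights[node] = h
    return reprs[S + tree.merges.shape[0] - 1] + ";"


def _escape(label: str) -> str:
    label = str(label)
    return label.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "_").replace(":", "_").replace(";", "_")
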