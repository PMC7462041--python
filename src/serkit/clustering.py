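"""Agglomerative clustering of sequences by SER dissimilarity.

A :class:`~serkit.compare.DissimilarityMatrix` is condensed and fed to
scipy's hierarchical clustering (default: average linkage / UPGMA, the
conventional choice for similarity trees).  To make the tree deterministic
under permutation of the input, ids are sorted lexicographically before
linkage — scipy breaks ties by index order, so a fixed id order fixes the
tie-break.

Merge heights are the linkage distances (D units).  For export the
ultrametric convention height = merge distance / 2 is used, so the
cophenetic distance between two leaves along the tree equals the linkage
distance at their join.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .compare import DissimilarityMatrix
from .errors import ValidationError

__all__ = ["Dendrogram", "linkage_tree", "to_newick"]

_LINKAGE_METHODS = ("average", "single", "complete")

# a Newick label that needs no quoting
_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.|\-]+$")


@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary tree over sequence ids.

    ``ids`` are in the (lexicographic) order used for linkage; ``linkage``
    is the scipy linkage matrix over those ids; ``method`` records the
    linkage criterion.
    """

    ids: tuple[str, ...]
    linkage: np.ndarray
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def merge_table(self) -> pd.DataFrame:
        """Merge sequence as a DataFrame (children, height, cluster size)."""
        return pd.DataFrame(
            self.linkage,
            columns=["child_a", "child_b", "height", "n_members"],
        ).astype({"child_a": int, "child_b": int, "n_members": int})

    def cophenetic(self) -> pd.DataFrame:
        """Cophenetic distances between leaves (merge-height units)."""
        condensed = sch.cophenet(self.linkage)
        return pd.DataFrame(squareform(condensed), index=list(self.ids), columns=list(self.ids))


def linkage_tree(d: DissimilarityMatrix, method: str = "average") -> Dendrogram:
    """Cluster a dissimilarity matrix into a dendrogram.

    Ids are sorted lexicographically before linkage so the merge sequence
    is independent of input order (deterministic tie-breaking).
    """
    if method not in _LINKAGE_METHODS:
        raise ValidationError(f"method must be one of {_LINKAGE_METHODS}, got {method!r}")
    if len(d.ids) < 2:
        raise ValidationError("clustering needs at least 2 items")
    order = np.argsort(np.asarray(d.ids, dtype=object))
    ids = tuple(d.ids[i] for i in order)
    values = d.values[np.ix_(order, order)]
    z = sch.linkage(squareform(values, checks=False), method=method)
    return Dendrogram(ids=ids, linkage=z, method=method)


def _format_label(name: str) -> str:
    if _PLAIN_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(tree: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths.

    Node heights are merge distance / 2 (leaves at height 0); a branch
    length is the height difference between a node and its parent.  Labels
    that are not plain alphanumerics are quoted.
    """
    n = tree.n_leaves
    heights = np.concatenate([np.zeros(n), tree.linkage[:, 2] / 2.0])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{_format_label(tree.ids[node])}:{length:.10g}"
        a, b = int(tree.linkage[node - n, 0]), int(tree.linkage[node - n, 1])
        inner = ",".join(render(c, heights[node]) for c in (a, b))
        return f"({inner}):{length:.10g}"

    root = n + len(tree.linkage) - 1
    a, b = int(tree.linkage[-1, 0]), int(tree.linkage[-1, 1])
    inner = ",".join(render(c, heights[root]) for c in (a, b))
    return f"({inner});"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
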