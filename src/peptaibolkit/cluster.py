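"""Hierarchical clustering of strain production profiles.

Strains (columns of a compounds x strains level matrix) are clustered by
complete linkage on Euclidean column distances — the settings of the web
tool used for the published heat map. Raw levels are used by default; unit
variance scaling is exposed as an option but off, since only linkage and
distance were reported.

Complete linkage is implemented directly (naive O(n^3); strain panels are
tiny) so that the tie rule is deterministic and invariant to input order:
candidate merges are compared by (distance, canonical pair), where the
canonical label of a cluster is its lexicographically smallest column name.
scipy's implementation serves as an independent oracle in the test suite,
not as the implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["column_distance", "complete_linkage", "MergeTree",
           "export_heatmap", "cophenetic_matrix", "top_split", "scale_columns"]


def scale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional unit-variance scaling of rows (compound levels)."""
    sd = matrix.std(axis=1, ddof=1).replace(0.0, 1.0)
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def column_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between strain columns."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-numeric or non-finite values")
    dm = squareform(pdist(values.T, metric="euclidean"))
    return pd.DataFrame(dm, index=matrix.columns, columns=matrix.columns)


@dataclass
class _Node:
    label: str                    # canonical (smallest member column name)
    members: list[str]
    height: float = 0.0
    children: tuple = ()          # () for leaves, (left, right) otherwise


@dataclass
class MergeTree:
    """Rooted binary merge tree with heights and a JSON-able merge trace."""

    root: _Node
    merges: list[dict] = field(default_factory=list)

    @property
    def leaves(self) -> list[str]:
        out = []

        def walk(n):
            if not n.children:
                out.append(n.label)
            else:
                for c in n.children:
                    walk(c)
        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(n, parent_height):
            blen = parent_height - n.height
            if not n.children:
                return f"{n.label}:{blen:.6g}"
            inner = ",".join(fmt(c, n.height) for c in n.children)
            return f"({inner}):{blen:.6g}"
        n = self.root
        inner = ",".join(fmt(c, n.height) for c in n.children) \
            if n.children else n.label
        return f"({inner});" if n.children else f"({inner});"

    def merge_trace_json(self, **kw) -> str:
        return json.dumps(self.merges, **kw)


def complete_linkage(dist: pd.DataFrame) -> MergeTree:
    """Agglomerative complete-linkage clustering of a symmetric distance
    table; merge heights are non-decreasing by construction."""
    names = list(dist.columns)
    if len(names) < 2:
        raise ValueError("need at least two items to cluster")
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance table must be symmetric")

    # canonical processing order: sort by name so input order cannot matter
    order = sorted(range(len(names)), key=lambda i: names[i])
    names_sorted = [names[i] for i in order]
    d = d[np.ix_(order, order)]

    nodes = [_Node(nm, [nm]) for nm in names_sorted]
    dm = {(i, j): d[i, j] for i in range(len(nodes)) for j in range(i)}
    active = dict(enumerate(nodes))
    merges = []
    next_id = len(nodes)
    last_height = 0.0
    while len(active) > 1:
        (j, i), h = min(
            ((pair, dm[pair]) for pair in dm
             if pair[0] in active and pair[1] in active),
            key=lambda kv: (kv[1], active[kv[0][1]].label, active[kv[0][0]].label))
        a, b = active.pop(i), active.pop(j)
        left, right = (a, b) if a.label <= b.label else (b, a)
        h = max(h, last_height)  # guard height monotonicity on fp noise
        node = _Node(left.label, left.members + right.members, h, (left, right))
        merges.append({"left": left.label, "right": right.label,
                       "height": h, "size": len(node.members)})
        # complete linkage: distance to a merged cluster is the max
        for k in active:
            dm[(next_id, k) if next_id > k else (k, next_id)] = max(
                dm[(max(i, k), min(i, k))], dm[(max(j, k), min(j, k))])
        active[next_id] = node
        next_id += 1
        last_height = h
    return MergeTree(next(iter(active.values())), merges)


def cophenetic_matrix(tree: MergeTree) -> pd.DataFrame:
    """Cophenetic distances (merge height joining each leaf pair)."""
    leaves = tree.leaves
    cm = pd.DataFrame(0.0, index=leaves, columns=leaves)

    def walk(n):
        if not n.children:
            return
        left, right = n.children
        for a in left.members:
            for b in right.members:
                cm.loc[a, b] = cm.loc[b, a] = n.height
        walk(left)
        walk(right)
    walk(tree.root)
    return cm


def top_split(tree: MergeTree) -> tuple[set[str], set[str]]:
    """The two-cluster partition at the root."""
    left, right = tree.root.children
    return set(left.members), set(right.members)


def export_heatmap(matrix: pd.DataFrame,
                   tree: MergeTree) -> tuple[pd.DataFrame, str]:
    """Columns permuted to tree leaf order, plus the Newick serialisation."""
    if set(tree.leaves) != set(matrix.columns):
        raise ValueError("tree leaves do not match matrix columns")
    return matrix.loc[:, tree.leaves], tree.to_newick()
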