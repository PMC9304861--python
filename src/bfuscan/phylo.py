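"""Distance tree over BfuB sequences and threshold-cut clade partitioning.

The tree stage is a deliberate, declared substitution for an ML pipeline:
pairwise global-alignment p-distances feed a self-implemented neighbor
joining, because everything downstream (the fixed 0.33 branch-length cut and
the clade-by-class association) only needs a tree with branch lengths.
Clades are the leaf-containing components left after deleting every edge
whose length is >= the threshold; singleton clades are flagged orphan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cofactor_scan import DEFAULT_SCORING, AlignmentScoring, _make_aligner

DEFAULT_CLADE_THRESHOLD = 0.33


@dataclass
class TreeNode:
    name: str | None = None  # leaf label; None for internal nodes
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored with an explicit (trifurcating) root."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            stack.extend(reversed(node.children))
        return sorted(out, key=lambda n: n.name or "")

    def edges(self) -> list[tuple[TreeNode, TreeNode, float]]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                out.append((node, child, child.length))
                stack.append(child)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{node.length:.6f}"

        return fmt(self.root) + ";"


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (m < 0).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def pairwise_p_distance(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """1 - identity over aligned columns of the optimal global alignment.

    Gap columns are excluded from the denominator.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(scoring)
    alignment = next(iter(aligner.align(a, b)))
    aligned = identical = 0
    for (s1, e1), (s2, _e2) in zip(*alignment.aligned):
        n = e1 - s1
        aligned += n
        identical += sum(a[s1 + k] == b[s2 + k] for k in range(n))
    if aligned == 0:
        return 1.0
    return 1.0 - identical / aligned


def distance_matrix(
    sequences: Mapping[str, str], scoring: AlignmentScoring = DEFAULT_SCORING
) -> DistanceMatrix:
    """All-pairs alignment p-distance over ``sequences`` (id -> sequence)."""
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_p_distance(sequences[ids[i]], sequences[ids[j]], scoring)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining with deterministic tie-breaking.

    Negative estimated branch lengths are clamped to zero; Q-criterion ties
    are resolved toward the lexicographically smallest pair of cluster
    representatives (the smallest leaf id under each cluster).  The returned
    tree has a trifurcating root, the conventional unrooted NJ output.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=pid) for i, pid in enumerate(D.ids)
    }
    reps: dict[int, str] = {i: pid for i, pid in enumerate(D.ids)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.matrix[i, j])

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, li)
        child_j.length = max(0.0, lj)
        new = TreeNode(children=[child_i, child_j])
        nodes[next_id] = new
        reps[next_id] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            dk = (d(i, k) + d(j, k) - d(i, j)) / 2
            dist[(min(k, next_id), max(k, next_id))] = max(0.0, dk)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = sorted(active, key=lambda x: reps[x])
    dij, dik, djk = d(i, j), d(i, k), d(j, k)
    nodes[i].length = max(0.0, (dij + dik - djk) / 2)
    nodes[j].length = max(0.0, (dij + djk - dik) / 2)
    nodes[k].length = max(0.0, (dik + djk - dij) / 2)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Clade partitioning


@dataclass
class CladePartition:
    leaf_to_clade: dict[str, str]
    clades: dict[str, dict]  # clade id -> {"members": [...], "is_orphan": bool}
    threshold: float


def partition_clades(
    tree: PhyloTree,
    threshold: float = DEFAULT_CLADE_THRESHOLD,
    outgroup: str | None = None,
) -> CladePartition:
    """Delete edges with length >= ``threshold``; leaf components are clades.

    Clade ids are assigned deterministically by the smallest leaf id in each
    clade.  ``outgroup`` (a leaf id) is excluded from the partition.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    parent_uf: dict[int, int] = {}

    def find(x: int) -> int:
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    def union(a: int, b: int) -> None:
        parent_uf[find(a)] = find(b)

    node_ids: dict[int, TreeNode] = {}

    def reg(node: TreeNode) -> int:
        key = id(node)
        if key not in parent_uf:
            parent_uf[key] = key
            node_ids[key] = node
        return key

    for parent, child, length in tree.edges():
        pk, ck = reg(parent), reg(child)
        if length < threshold:
            union(pk, ck)
    reg(tree.root)

    groups: dict[int, list[str]] = {}
    for key, node in node_ids.items():
        if node.is_leaf and node.name != outgroup:
            groups.setdefault(find(key), []).append(node.name)

    leaf_to_clade: dict[str, str] = {}
    clades: dict[str, dict] = {}
    for members in sorted(groups.values(), key=min):
        cid = f"clade_{len(clades) + 1:03d}"
        clades[cid] = {
            "members": sorted(members),
            "is_orphan": len(members) == 1,
        }
        for leaf in members:
            leaf_to_clade[leaf] = cid
    return CladePartition(leaf_to_clade, clades, threshold)


def clade_summary(
    partition: CladePartition,
    classifications: Mapping[str, str],
    phyla: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Contingency table clade x class (plus clade x phylum when given).

    Leaves without a classification are counted as ``Unknown`` with a
    warning.  Rows are clade ids, columns class names, values counts.
    """
    rows = []
    for leaf, clade in sorted(partition.leaf_to_clade.items()):
        cls = classifications.get(leaf)
        if cls is None:
            warnings.warn(f"leaf {leaf!r} has no classification; counted as Unknown")
            cls = "Unknown"
        rows.append(
            {"clade": clade, "class": cls,
             **({"phylum": phyla.get(leaf, "unknown")} if phyla else {})}
        )
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["clade"], df["class"])
    if phyla:
        table = table.join(
            pd.crosstab(df["clade"], df["phylum"]).add_prefix("phylum:")
        )
    return table
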