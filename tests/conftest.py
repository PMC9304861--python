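"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bfuscan.io_formats import AMINO_ACIDS
from bfuscan.phylo import PhyloTree, TreeNode

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Brute-force affine-gap global alignment (Gotoh), independent of Biopython.

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a: str, b: str, open_: float = -11.0, extend: float = -1.0) -> float:
    """Optimal global alignment score; gap of length L costs open+(L-1)*extend."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend,
                          Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend,
                          X[i, j - 1] + open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Random additive trees for the NJ consistency oracle.


def random_additive_tree(
    rng: np.random.Generator, n_leaves: int
) -> tuple[PhyloTree, dict[str, dict[str, float]]]:
    """A random unrooted binary tree with positive lengths + its path metric."""
    assert n_leaves >= 3
    leaves = [f"L{i:02d}" for i in range(n_leaves)]

    def blen() -> float:
        return float(rng.uniform(0.1, 1.0))

    root = TreeNode(children=[TreeNode(name=leaf, length=blen()) for leaf in leaves[:3]])
    edges: list[tuple[TreeNode, TreeNode]] = [(root, c) for c in root.children]
    for leaf in leaves[3:]:
        parent, child = edges[rng.integers(0, len(edges))]
        u = float(rng.uniform(0.2, 0.8))
        mid = TreeNode(length=child.length * u)
        child.length *= 1 - u
        parent.children[parent.children.index(child)] = mid
        new_leaf = TreeNode(name=leaf, length=blen())
        mid.children = [child, new_leaf]
        edges.remove((parent, child))
        edges.extend([(parent, mid), (mid, child), (mid, new_leaf)])
    tree = PhyloTree(root)

    # path-length metric between leaves
    import networkx as nx

    g = nx.Graph()
    for parent, child, length in tree.edges():
        g.add_edge(id(parent), id(child), weight=length)
    names = {id(l): l.name for l in tree.leaves()}
    dist: dict[str, dict[str, float]] = {name: {} for name in leaves}
    sp = dict(nx.all_pairs_dijkstra_path_length(g))
    for ka, na in names.items():
        for kb, nb in names.items():
            dist[na][nb] = sp[ka][kb] if ka != kb else 0.0
    return tree, dist


def bipartitions(tree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of the unrooted topology."""
    all_leaves = frozenset(l.name for l in tree.leaves())

    def leafset(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        return frozenset().union(*(leafset(c) for c in node.children))

    splits = set()
    for _parent, child, _length in tree.edges():
        side = leafset(child)
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(frozenset({side, all_leaves - side}))
    return splits


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
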