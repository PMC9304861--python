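"""Distances, neighbor joining, clade cutting and the clade/class table."""

import numpy as np
import pytest

from bfuscan import phylo as ph
from conftest import bipartitions, random_additive_tree, random_protein


def test_identical_pair_distance_zero():
    assert ph.pairwise_p_distance("MKCLLA", "MKCLLA") == 0.0


def test_hand_aligned_quarter_distance():
    # AAAA vs AAAT aligns without gaps: 1 mismatch over 4 columns
    assert ph.pairwise_p_distance("AAAA", "AAAT") == pytest.approx(0.25)


def test_distance_matrix_symmetric(rng):
    seqs = {f"s{i}": random_protein(rng, 30) for i in range(8)}
    D = ph.distance_matrix(seqs)
    assert np.allclose(D.matrix, D.matrix.T)
    assert np.allclose(np.diag(D.matrix), 0)
    assert ((D.matrix >= 0) & (D.matrix <= 1)).all()


def test_distance_matrix_needs_two():
    with pytest.raises(ValueError):
        ph.distance_matrix({"a": "MK"})


def test_three_leaf_closed_form():
    D = ph.DistanceMatrix(
        ["a", "b", "c"],
        np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]),
    )
    tree = ph.nj_tree(D)
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
    assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
    assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)


def test_nj_rejects_tiny_input():
    with pytest.raises(ValueError):
        ph.nj_tree(ph.DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


def test_nj_recovers_additive_topology(rng):
    for _ in range(25):
        true_tree, dist = random_additive_tree(rng, int(rng.integers(4, 13)))
        ids = sorted(dist)
        m = np.array([[dist[a][b] for b in ids] for a in ids])
        recon = ph.nj_tree(ph.DistanceMatrix(ids, m))
        assert bipartitions(recon) == bipartitions(true_tree)


def test_nj_invariant_to_leaf_order(rng):
    _, dist = random_additive_tree(rng, 8)
    ids = sorted(dist)
    m = np.array([[dist[a][b] for b in ids] for a in ids])
    t1 = ph.nj_tree(ph.DistanceMatrix(ids, m))
    perm = list(rng.permutation(len(ids)))
    ids2 = [ids[i] for i in perm]
    m2 = m[np.ix_(perm, perm)]
    t2 = ph.nj_tree(ph.DistanceMatrix(ids2, m2))
    assert bipartitions(t1) == bipartitions(t2)


def test_all_short_edges_single_clade(rng):
    tree, _ = random_additive_tree(rng, 7)
    for _parent, child, _l in tree.edges():
        child.length = 0.01
    part = ph.partition_clades(tree, 0.33)
    assert len(part.clades) == 1
    assert not any(c["is_orphan"] for c in part.clades.values())


def test_star_tree_orphan_count():
    from bfuscan.phylo import PhyloTree, TreeNode

    n, k = 6, 2  # k long stems -> k orphans + one clade of n-k
    children = [
        TreeNode(name=f"L{i}", length=0.5 if i < k else 0.1) for i in range(n)
    ]
    part = ph.partition_clades(PhyloTree(TreeNode(children=children)), 0.33)
    orphans = [c for c in part.clades.values() if c["is_orphan"]]
    assert len(orphans) == k
    assert len(part.clades) == k + 1
    big = max(part.clades.values(), key=lambda c: len(c["members"]))
    assert len(big["members"]) == n - k


def test_partition_equals_graph_components_oracle(rng):
    import networkx as nx

    for _ in range(50):
        tree, _ = random_additive_tree(rng, int(rng.integers(4, 12)))
        threshold = float(rng.uniform(0.2, 0.9))
        part = ph.partition_clades(tree, threshold)
        g = nx.Graph()
        for parent, child, length in tree.edges():
            g.add_node(id(parent)), g.add_node(id(child))
            if length < threshold:
                g.add_edge(id(parent), id(child))
        names = {id(l): l.name for l in tree.leaves()}
        expected = set()
        for comp in nx.connected_components(g):
            leaves = frozenset(names[x] for x in comp if x in names)
            if leaves:
                expected.add(leaves)
        got = {frozenset(c["members"]) for c in part.clades.values()}
        assert got == expected


def test_threshold_monotonicity(rng):
    tree, _ = random_additive_tree(rng, 10)
    counts = [
        len(ph.partition_clades(tree, t).clades) for t in (0.1, 0.33, 0.6, 1.1)
    ]
    assert counts == sorted(counts, reverse=True)


def test_invalid_threshold():
    tree, _ = random_additive_tree(np.random.default_rng(0), 4)
    with pytest.raises(ValueError):
        ph.partition_clades(tree, 0.0)


def test_outgroup_excluded(rng):
    tree, _ = random_additive_tree(rng, 5)
    part = ph.partition_clades(tree, 0.9, outgroup="L00")
    assert "L00" not in part.leaf_to_clade


def test_clade_summary_diagonal_on_designed_cohort():
    from bfuscan.synthetic_data import generate_cohort

    coh = generate_cohort(
        ["FeFe", "Nfn", "Wor"], n_per_template=3,
        divergence=0.02, between_divergence=0.9, seed=17,
    )
    seqs, classes = {}, {}
    for g in coh.genomes:
        pid = g.truth.bfub_protein_id
        seqs[pid] = next(
            r.sequence for r in g.records if r.protein_id == pid
        )
        classes[pid] = g.truth.class_name
    tree = ph.nj_tree(ph.distance_matrix(seqs))
    part = ph.partition_clades(tree, 0.33)
    assert len(part.clades) == 3
    table = ph.clade_summary(part, classes)
    assert (table.to_numpy().sum(axis=1) == 3).all()
    assert ((table.to_numpy() > 0).sum(axis=1) == 1).all()  # one class per clade
    assert table.to_numpy().sum() == 9


def test_clade_summary_missing_classification_warns(rng):
    tree, _ = random_additive_tree(rng, 4)
    part = ph.partition_clades(tree, 2.0)
    with pytest.warns(UserWarning):
        table = ph.clade_summary(part, {})
    assert int(table["Unknown"].sum()) == 4


def test_clade_summary_empty():
    part = ph.CladePartition({}, {}, 0.33)
    assert ph.clade_summary(part, {}).empty
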