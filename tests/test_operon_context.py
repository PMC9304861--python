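"""Neighborhood extraction, the sandwich rule and signature matching."""

import pytest

from bfuscan import operon_context as oc
from bfuscan import synthetic_data as syn
from bfuscan.io_formats import GeneFeature


def _features(roles, genome="G", contig="c1"):
    feats = []
    for i, role in enumerate(roles):
        feats.append(
            GeneFeature(genome, contig, f"g{i:03d}", i * 1000, i * 1000 + 900,
                        "+", f"p{i:03d}", role)
        )
    return feats


def test_codh_sandwich():
    g = syn.generate_genome("Codh", seed=1)
    anchor = next(f for f in g.features if f.role_label == "bfuB")
    cluster = oc.extract_cluster(g.features, anchor)
    assert {f.role_label for f in cluster.sandwich} == {"codh_a", "codh_b", "codh_c"}


def test_isolated_anchor_gives_singleton_cluster():
    feats = _features(["bfuB"])
    cluster = oc.extract_cluster(feats, feats[0])
    assert cluster.members == (feats[0],)
    assert cluster.bfua is None and cluster.sandwich == ()


def test_standalone_decoy_outside_window():
    g = syn.generate_genome("Rub", seed=2, standalone_decoy="Codh")
    anchor = next(f for f in g.features if f.role_label == "bfuB")
    cluster = oc.extract_cluster(g.features, anchor, window=10)
    assert all("codh" not in f.role_label for f in cluster.members)


def test_unknown_anchor_is_error():
    with pytest.raises(ValueError, match="nope"):
        oc.extract_cluster(_features(["bfuB"]), "nope")


def test_fused_h_cluster_domain_gives_fefe():
    feats = _features(["bfuA", "bfuB", "bfuC"])
    cluster = oc.extract_cluster(feats, feats[1])
    call = oc.match_signature(cluster, bfuA_domains=["BFS_HCLUS"])
    assert call.class_name == "FeFe"
    assert call.matched_roles == ("h_cluster",)


def test_fdhfefe_outranks_fdh_and_fefe():
    feats = _features(["fdh_catalytic", "h_cluster_subunit", "bfuA", "bfuB", "bfuC"])
    cluster = oc.extract_cluster(feats, feats[3])
    call = oc.match_signature(cluster)
    assert call.class_name == "FdhFeFe"
    # without the hydrogenase subunit the same cluster is plain Fdh
    feats2 = _features(["fdh_catalytic", "bfuA", "bfuB", "bfuC"])
    call2 = oc.match_signature(oc.extract_cluster(feats2, feats2[2]))
    assert call2.class_name == "Fdh"


def test_rub_requires_adjacency_and_no_bfua():
    feats = _features(["bfuC", "bfuB", "rubrerythrin"])
    call = oc.match_signature(oc.extract_cluster(feats, feats[1]))
    assert call.class_name == "Rub"
    # a gene in between breaks the directly-downstream rule
    feats2 = _features(["bfuC", "bfuB", "hypothetical", "rubrerythrin"])
    call2 = oc.match_signature(oc.extract_cluster(feats2, feats2[1]))
    assert call2.class_name == "Unknown"
    # a bfuA in the cluster excludes the BfuA-less arrangement
    feats3 = _features(["bfuC", "bfuB", "rubrerythrin", "bfuA"])
    call3 = oc.match_signature(oc.extract_cluster(feats3, feats3[1]))
    assert call3.class_name != "Rub"


def test_no_signature_gives_unknown_with_note():
    feats = _features(["bfuB", "hypothetical"])
    call = oc.match_signature(oc.extract_cluster(feats, feats[0]))
    assert call.class_name == "Unknown"
    assert "no bfuA" in call.confidence_note


def test_tie_gives_unknown_with_tie_note():
    # two fused-domain templates with one matched role each tie in band 3
    feats = _features(["bfuA", "bfuB", "bfuC"])
    cluster = oc.extract_cluster(feats, feats[1])
    call = oc.match_signature(cluster, bfuA_domains=["BFS_HCLUS", "BFS_NFNFAD"])
    assert call.class_name == "Unknown"
    assert "tie" in call.confidence_note


@pytest.mark.parametrize("template,n_expected", [
    ("Nuo", 14), ("Bam", 8), ("Wor", 5), ("NiFe", 5), ("Rub", 3),
])
def test_holoenzyme_counts(template, n_expected):
    g = syn.generate_genome(template, seed=1)
    anchor = next(f for f in g.features if f.role_label == "bfuB")
    cluster = oc.extract_cluster(g.features, anchor)
    call = oc.match_signature(cluster)
    assert len(oc.holoenzyme_subunits(cluster, call)) == n_expected


def test_maturation_genes_excluded_from_holoenzyme():
    g = syn.generate_genome("NiFe", seed=1)
    anchor = next(f for f in g.features if f.role_label == "bfuB")
    cluster = oc.extract_cluster(g.features, anchor)
    call = oc.match_signature(cluster)
    holo = oc.holoenzyme_subunits(cluster, call)
    roles = {f.role_label for f in cluster.members if f.gene_id in holo}
    assert "hisK" not in roles and "hydD" not in roles


def test_window_enlargement_keeps_correct_call():
    g = syn.generate_genome("Wor", seed=4, standalone_decoy="Codh")
    anchor = next(f for f in g.features if f.role_label == "bfuB")
    for window in (5, 10, 15):
        cluster = oc.extract_cluster(g.features, anchor, window=window)
        assert oc.match_signature(cluster).class_name == "Wor"
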