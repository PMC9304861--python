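"""Reference-frame alignment and FeS cluster calling."""

import numpy as np
import pytest

from bfuscan import cofactor_scan as cs
from bfuscan import reference as ref
from bfuscan.classify import default_reference_frame
from bfuscan.synthetic_data import make_reference_proteins
from conftest import gotoh_score, random_protein


@pytest.fixture(scope="module")
def frame():
    return default_reference_frame()


def test_identity_alignment(frame):
    seq = frame.sequences["BfuC"]
    pmap = cs.align_to_reference(seq, seq)
    assert pmap == {i: i for i in range(len(seq))}


def test_single_deletion_shifts_map(frame):
    seq = frame.sequences["BfuC"]
    i = 30
    query = seq[:i] + seq[i + 1:]
    pmap = cs.align_to_reference(query, seq)
    assert pmap[10] == 10
    assert i not in pmap
    assert pmap[i + 1] == i
    assert pmap[len(seq) - 1] == len(query) - 1


def test_alignment_score_equals_dp_oracle(rng):
    """Biopython's affine global score must equal an independent Gotoh DP."""
    for _ in range(200):
        a = random_protein(rng, int(rng.integers(1, 13)))
        b = random_protein(rng, int(rng.integers(1, 13)))
        assert cs.alignment_score(a, b) == pytest.approx(gotoh_score(a, b))


def test_empty_sequence_rejected(frame):
    with pytest.raises(ValueError):
        cs.align_to_reference("", frame.sequences["BfuB"])


def test_unmutated_bfub_has_all_clusters(frame):
    seq = frame.sequences["BfuB"]
    calls = cs.call_clusters(
        cs.align_to_reference(seq, seq), seq, frame, "BfuB"
    )
    for cluster in ("B1", "B2", "B3", "B4", "B5"):
        assert calls[cluster].status == "present"


def test_a4_ablation_called_absent(frame):
    seq = list(frame.sequences["BfuA"])
    for pos, _ in ref.LIGANDS["BfuA"]["A4"]:
        seq[pos - 1] = "A"
    seq = "".join(seq)
    calls = cs.call_clusters(
        cs.align_to_reference(seq, frame.sequences["BfuA"]), seq, frame, "BfuA"
    )
    assert calls["A4"].status == "absent"
    assert calls["A3"].status == "present"


@pytest.mark.parametrize("k_removed,expected", [
    (0, "present"), (1, "present"), (2, "partial"), (3, "partial"), (4, "absent"),
])
def test_threshold_rule_by_enumeration(frame, k_removed, expected):
    """Removing k of 4 quartet ligands gives the status the rule dictates."""
    seq = list(frame.sequences["BfuC"])
    for pos, _ in list(ref.LIGANDS["BfuC"]["C1"])[:k_removed]:
        seq[pos - 1] = "A"
    seq = "".join(seq)
    calls = cs.call_clusters(
        cs.align_to_reference(seq, frame.sequences["BfuC"]), seq, frame, "BfuC"
    )
    assert calls["C1"].status == expected


def test_presence_monotone_under_ligand_restoration(frame):
    """Restoring an ablated ligand never demotes a cluster's status."""
    order = {"absent": 0, "partial": 1, "present": 2}
    refseq = frame.sequences["BfuC"]
    positions = [p for p, _ in ref.LIGANDS["BfuC"]["C1"]]
    prev = None
    for k in range(4, -1, -1):  # restore ligands one at a time
        seq = list(refseq)
        for pos in positions[:k]:
            seq[pos - 1] = "A"
        seq = "".join(seq)
        status = cs.call_clusters(
            cs.align_to_reference(seq, refseq), seq, frame, "BfuC"
        )["C1"].status
        if prev is not None:
            assert order[status] >= order[prev]
        prev = status


def test_unknown_subunit_is_error(frame):
    with pytest.raises(ValueError):
        cs.call_clusters({}, "MK", frame, "BfuX")


def test_b2_signature_reference_and_variants(frame):
    seq = frame.sequences["BfuB"]
    pmap = cs.align_to_reference(seq, seq)
    sig = cs.b2_signature(pmap, seq, frame)
    assert sig == cs.B2Signature(True, "C")
    thr, _ = make_reference_proteins(0, variant="thr")
    tseq = thr["BfuB"]
    tsig = cs.b2_signature(cs.align_to_reference(tseq, seq), tseq, frame)
    assert tsig == cs.B2Signature(True, "T")
    assert tsig.canonical
    hseq = seq[:524] + "A" + seq[525:]
    hsig = cs.b2_signature(cs.align_to_reference(hseq, seq), hseq, frame)
    assert not hsig.his525_present


def test_core_verdict(frame):
    seq = frame.sequences["BfuB"]
    cseq = frame.sequences["BfuC"]
    bcalls = cs.call_clusters(cs.align_to_reference(seq, seq), seq, frame, "BfuB")
    ccalls = cs.call_clusters(cs.align_to_reference(cseq, cseq), cseq, frame, "BfuC")
    sig = cs.b2_signature(cs.align_to_reference(seq, seq), seq, frame)
    assert cs.core_verdict(bcalls, ccalls, sig).bifurcating

    # Nqo-like homolog: B2-B5 gone
    nqo = list(seq)
    for cluster in ("B2", "B3", "B4", "B5"):
        for pos, _ in ref.LIGANDS["BfuB"][cluster]:
            nqo[pos - 1] = "A"
    nqo = "".join(nqo)
    pmap = cs.align_to_reference(nqo, seq)
    verdict = cs.core_verdict(
        cs.call_clusters(pmap, nqo, frame, "BfuB"),
        ccalls,
        cs.b2_signature(pmap, nqo, frame),
    )
    assert not verdict.bifurcating
    assert any("B2" in r for r in verdict.reasons)

    # C1 alone missing also breaks the core
    verdict2 = cs.core_verdict(bcalls, {}, sig)
    assert not verdict2.bifurcating
    assert verdict2.reasons == ("C1 missing",)


def test_entry_cluster_priority(frame):
    present = cs.ClusterCall("present", 1.0, ())
    absent = cs.ClusterCall("absent", 0.0, ())
    assert cs.entry_cluster({"A3": present, "A4": present}) == "A4"
    assert cs.entry_cluster({"A3": present, "A4": absent}) == "A3"
    assert cs.entry_cluster({"A3": absent, "A4": absent}) == "none"
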