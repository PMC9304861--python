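"""The Type 1-4 verdict: combining core, BfuA profile and functional call.

Decision table (total and deterministic):

  (a) core not bifurcating                          -> NonBifurcating / none
  (b) no bfuA: recognised Rub-like partner          -> T4 / direct
      no bfuA otherwise                             -> Unclassified / none
  (c) catalytic domain fused to bfuA                -> T1 / entry cluster
      (A4 when present, the A3 fallback otherwise)
  (d) extra catalytic subunits, A3 absent           -> T2 / A4
  (e) extra catalytic subunits, A3 present          -> T3 / A3
  (f) otherwise                                     -> Unclassified / none

A5 plays no part in the Type 2 test: the operative contrast between Types 2
and 3 is the presence of A3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import reference as ref
from .cofactor_scan import (
    DEFAULT_SCORING,
    AlignmentScoring,
    ClusterCallMap,
    CoreVerdict,
    ReferenceFrame,
    align_to_reference,
    b2_signature,
    call_clusters,
    core_verdict,
    entry_cluster,
)
from .domain_filter import CandidateSet, select_bfua, select_bfub, select_bfuc
from .io_formats import DomainAnnotation, GeneFeature, ProteinRecord
from .operon_context import (
    DEFAULT_WINDOW,
    FunctionalCall,
    extract_cluster,
    holoenzyme_subunits,
    match_signature,
)
from .synthetic_data import ROLE_KINDS, make_reference_proteins

TYPES = ("T1", "T2", "T3", "T4", "NonBifurcating", "Unclassified")
ENTRIES = ("A3", "A4", "direct", "none")


@dataclass(frozen=True)
class BfuTypeCall:
    type: str
    entry: str
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in TYPES:
            raise ValueError(f"unknown type {self.type!r}")
        if self.entry not in ENTRIES:
            raise ValueError(f"unknown entry {self.entry!r}")


def assign_type(
    core: CoreVerdict,
    bfuA_present: bool,
    bfuA_calls: ClusterCallMap | None,
    bfuA_has_fused_catalytic: bool,
    extra_catalytic_subunits: bool,
    call: FunctionalCall,
) -> BfuTypeCall:
    """Apply the decision table; see the module docstring for the rows."""
    if bfuA_has_fused_catalytic and call.class_name == "Rub":
        raise ValueError("contradictory input: fused catalytic domain with class Rub")
    if not core.bifurcating:
        return BfuTypeCall(
            "NonBifurcating", "none",
            ("core not bifurcating:",) + core.reasons,
        )
    if not bfuA_present:
        if call.class_name == "Rub":
            return BfuTypeCall(
                "T4", "direct",
                ("no bfuA; rubrerythrin partner feeds the core directly",),
            )
        return BfuTypeCall(
            "Unclassified", "none",
            ("no bfuA and no recognised direct-feeding partner",),
        )
    calls = bfuA_calls or {}
    a3_present = "A3" in calls and calls["A3"].status == "present"
    if bfuA_has_fused_catalytic:
        entry = entry_cluster(calls)
        return BfuTypeCall(
            "T1", entry, (f"catalytic domain fused to bfuA; entry {entry}",)
        )
    if extra_catalytic_subunits:
        if a3_present:
            return BfuTypeCall("T3", "A3", ("extra catalytic subunits; A3 present",))
        return BfuTypeCall("T2", "A4", ("extra catalytic subunits; A3 absent",))
    return BfuTypeCall(
        "Unclassified", "none", ("bfuA present but no catalytic evidence",)
    )


REPORT_COLUMNS = [
    "genome_id", "contig", "anchor_gene_id", "anchor_protein_id",
    "class", "type", "entry", "core_bifurcating", "core_reasons",
    "matched_roles", "holoenzyme_genes", "note",
]


def classification_row(
    anchor_feature,
    call: FunctionalCall,
    type_call: BfuTypeCall,
    core: CoreVerdict,
    holoenzyme: list[str],
) -> dict:
    return {
        "genome_id": anchor_feature.genome_id,
        "contig": anchor_feature.contig,
        "anchor_gene_id": anchor_feature.gene_id,
        "anchor_protein_id": anchor_feature.protein_id or "",
        "class": call.class_name,
        "type": type_call.type,
        "entry": type_call.entry,
        "core_bifurcating": core.bifurcating,
        "core_reasons": ";".join(core.reasons),
        "matched_roles": ";".join(call.matched_roles),
        "holoenzyme_genes": ";".join(holoenzyme),
        "note": call.confidence_note,
    }


def classification_table(rows: list[dict]) -> pd.DataFrame:
    """One row per bfuB anchor, ordered by (genome, contig, start order)."""
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(
        ["genome_id", "contig", "anchor_gene_id"], kind="stable"
    ).reset_index(drop=True)


def default_reference_frame() -> ReferenceFrame:
    """The packaged frame: seed-0 reference subunits + the ligand tables."""
    sequences, _ = make_reference_proteins(0)
    return ReferenceFrame(sequences=sequences)


_FUSED_ROLES = {"h_cluster", "nfn_fad", "f420_fad", "fdh_pterin"}


def classify_dataset(
    records: Sequence[ProteinRecord],
    features: Sequence[GeneFeature],
    domains: Sequence[DomainAnnotation],
    frame: ReferenceFrame | None = None,
    window: int = DEFAULT_WINDOW,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    role_vocab: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """End-to-end classification: one row per bfuB anchor in the dataset.

    Runs domain filtering, reference-frame cofactor scanning, neighborhood
    extraction, signature matching and the type decision table, joining the
    evidence into a deterministic table (see ``REPORT_COLUMNS``).
    """
    from .operon_context import DEFAULT_ROLE_VOCAB

    frame = frame or default_reference_frame()
    vocab = dict(role_vocab) if role_vocab is not None else DEFAULT_ROLE_VOCAB
    rec_by_id = {r.protein_id: r for r in records}
    doms_by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        doms_by_protein.setdefault(d.protein_id, []).append(d)

    candidates = CandidateSet(
        bfuB_ids=select_bfub(domains),
        bfuC_ids=select_bfuc(domains),
        bfuA_ids=select_bfua(domains),
    )

    def _calls(pid: str | None, subunit: str) -> ClusterCallMap:
        if pid is None or pid not in rec_by_id:
            return {}
        seq = rec_by_id[pid].sequence
        pmap = align_to_reference(seq, frame.sequences[subunit], scoring)
        return call_clusters(pmap, seq, frame, subunit)

    rows = []
    anchors = [
        f for f in features
        if f.protein_id in candidates.bfuB_ids
    ]
    for anchor in anchors:
        try:
            seq = rec_by_id[anchor.protein_id].sequence
            pmap = align_to_reference(seq, frame.sequences["BfuB"], scoring)
            bfub_calls = call_clusters(pmap, seq, frame, "BfuB")
            b2sig = b2_signature(pmap, seq, frame)
            cluster = extract_cluster(features, anchor, window, candidates, vocab)
            bfuc_calls = _calls(
                cluster.bfuc.protein_id if cluster.bfuc else None, "BfuC"
            )
            bfua_pid = cluster.bfua.protein_id if cluster.bfua else None
            bfua_calls = _calls(bfua_pid, "BfuA")
            extra_domains = [
                d.domain_id for d in doms_by_protein.get(bfua_pid or "", [])
                if d.domain_id not in ref.BFUA_DOMAINS
            ]
            call = match_signature(cluster, candidates, extra_domains, vocab)
            core = core_verdict(bfub_calls, bfuc_calls, b2sig)
            fused = any(vocab.get(d) in _FUSED_ROLES for d in extra_domains)
            extra_subunits = any(
                ROLE_KINDS.get(r) == "catalytic" for r in call.matched_roles
            )
            type_call = assign_type(
                core, cluster.bfua is not None, bfua_calls,
                fused, extra_subunits, call,
            )
            holo = (
                holoenzyme_subunits(cluster, call)
                if call.class_name != "Unknown"
                else []
            )
            rows.append(classification_row(anchor, call, type_call, core, holo))
        except Exception as exc:
            raise RuntimeError(
                f"classification failed for anchor {anchor.gene_id} "
                f"(genome {anchor.genome_id})"
            ) from exc
    return classification_table(rows)
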