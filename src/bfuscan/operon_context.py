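"""Gene-neighborhood extraction and functional signature matching.

Every BfuB anchor defines a gene cluster (±window genes on its contig,
ordered by start; strand is ignored for ordering).  Genes strictly between
bfuB and bfuA form the sandwich set — treated as holoenzyme subunits, the
strongest operon-level evidence that the catalytic cassette belongs to the
complex.  Signature templates for the thirteen functional classes are then
evaluated with a fixed priority: composite templates first, then
subunit-count-heavy ones, then single fused-domain templates, then the
BfuA-less rubrerythrin arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import reference as ref
from .domain_filter import CandidateSet
from .io_formats import GeneFeature
from .synthetic_data import ROLE_KINDS

DEFAULT_WINDOW = 10  # the largest packaged operon (14 genes) fits with margin

#: Maps free-text product labels and extra domain accessions onto controlled
#: roles.  Synthetic data emits controlled roles directly (identity); real
#: annotations can extend this map through the pipeline config.
DEFAULT_ROLE_VOCAB: dict[str, str] = {
    **{role: role for role in ROLE_KINDS},
    ref.FUSED_DOMAIN_ACCESSIONS["h_cluster"]: "h_cluster",
    ref.FUSED_DOMAIN_ACCESSIONS["nfn_fad"]: "nfn_fad",
    ref.FUSED_DOMAIN_ACCESSIONS["f420_fad"]: "f420_fad",
    ref.FUSED_DOMAIN_ACCESSIONS["fdh_pterin"]: "fdh_pterin",
}


@dataclass(frozen=True)
class GeneCluster:
    """The gene neighborhood around one bfuB anchor."""

    anchor: GeneFeature
    members: tuple[GeneFeature, ...]  # ordered by start
    bfua: GeneFeature | None
    bfuc: GeneFeature | None
    sandwich: tuple[GeneFeature, ...]  # strictly between bfuB and bfuA
    roles: Mapping[str, str]  # gene_id -> resolved controlled role


@dataclass(frozen=True)
class FunctionalCall:
    class_name: str
    matched_roles: tuple[str, ...] = ()
    holoenzyme_gene_ids: tuple[str, ...] = ()
    confidence_note: str = ""


def extract_cluster(
    features: Sequence[GeneFeature],
    anchor: GeneFeature | str,
    window: int = DEFAULT_WINDOW,
    candidates: CandidateSet | None = None,
    role_vocab: Mapping[str, str] | None = None,
) -> GeneCluster:
    """Extract the ±``window`` gene neighborhood of a bfuB anchor.

    Subunit genes are identified through ``candidates`` (protein ids from
    the domain filter) with the feature ``role_label`` as fallback; the
    nearest candidate on each side wins when several are in range.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vocab = dict(role_vocab) if role_vocab is not None else DEFAULT_ROLE_VOCAB
    if isinstance(anchor, str):
        matches = [f for f in features if f.gene_id == anchor]
        if not matches:
            raise ValueError(f"anchor gene {anchor!r} not in features")
        anchor = matches[0]
    elif anchor not in features:
        raise ValueError(f"anchor gene {anchor.gene_id!r} not in features")

    contig_genes = sorted(
        (f for f in features
         if f.contig == anchor.contig and f.genome_id == anchor.genome_id),
        key=lambda f: (f.start, f.gene_id),
    )
    idx = next(i for i, f in enumerate(contig_genes) if f.gene_id == anchor.gene_id)
    lo, hi = max(0, idx - window), min(len(contig_genes), idx + window + 1)
    members = tuple(contig_genes[lo:hi])
    anchor_pos = idx - lo

    def _is_subunit(f: GeneFeature, ids: set[str], label: str) -> bool:
        if candidates is not None and f.protein_id in ids:
            return True
        return candidates is None and f.role_label == label

    def _nearest(label: str, ids: set[str]) -> GeneFeature | None:
        best, best_d = None, None
        for j, f in enumerate(members):
            if j != anchor_pos and _is_subunit(f, ids, label):
                d = abs(j - anchor_pos)
                if best_d is None or d < best_d:
                    best, best_d = f, d
        return best

    bfua = _nearest("bfuA", candidates.bfuA_ids if candidates else set())
    bfuc = _nearest("bfuC", candidates.bfuC_ids if candidates else set())

    sandwich: tuple[GeneFeature, ...] = ()
    if bfua is not None:
        ja = members.index(bfua)
        a, b = sorted((anchor_pos, ja))
        sandwich = tuple(members[a + 1:b])

    roles = {
        f.gene_id: vocab[f.role_label]
        for f in members
        if f.role_label in vocab
    }
    return GeneCluster(anchor, members, bfua, bfuc, sandwich, roles)


# ---------------------------------------------------------------------------
# Signature templates

@dataclass(frozen=True)
class Signature:
    class_name: str
    band: int  # 1 composite > 2 subunit-heavy > 3 fused-domain > 4 Rub
    subunit_roles: frozenset[str] = frozenset()
    min_subunit_matches: int = 0
    fused_roles: frozenset[str] = frozenset()  # any-of, on the bfuA protein


SIGNATURES: tuple[Signature, ...] = (
    Signature("FdhFeFe", 1,
              frozenset({"fdh_catalytic", "h_cluster_subunit"}), 2),
    Signature("Nuo", 2, frozenset(f"nuo_{chr(97 + i)}" for i in range(11)), 6),
    Signature("Mbh", 2, frozenset(f"mbh_{chr(97 + i)}" for i in range(6)), 3),
    Signature("Bam", 2, frozenset(f"bam_{chr(97 + i)}" for i in range(5)), 3),
    Signature("Por", 2, frozenset(f"por_{chr(97 + i)}" for i in range(4)), 2),
    Signature("Codh", 2, frozenset(f"codh_{chr(97 + i)}" for i in range(3)), 2),
    Signature("NiFe", 2, frozenset({"nife_small", "nife_large"}), 2),
    Signature("Wor", 2, frozenset({"wor_small", "wor_large"}), 2),
    Signature("FeFe", 3, fused_roles=frozenset({"h_cluster"})),
    Signature("Nfn", 3, fused_roles=frozenset({"nfn_fad"})),
    Signature("F420", 3, fused_roles=frozenset({"f420_fad"})),
    Signature("Fdh", 3, frozenset({"fdh_catalytic"}), 1,
              fused_roles=frozenset({"fdh_pterin"})),
    Signature("Rub", 4, frozenset({"rubrerythrin"}), 1),
)


def _match_one(
    sig: Signature,
    cluster: GeneCluster,
    bfuA_roles: set[str],
) -> tuple[str, ...] | None:
    """Matched roles when the signature applies, else None."""
    member_roles = set(cluster.roles.values())
    matched: set[str] = set()
    if sig.class_name == "Rub":
        if cluster.bfua is not None:
            return None
        # rubrerythrin must be the gene directly downstream of bfuB
        anchor_pos = cluster.members.index(cluster.anchor)
        if anchor_pos + 1 >= len(cluster.members):
            return None
        neighbor = cluster.members[anchor_pos + 1]
        if cluster.roles.get(neighbor.gene_id) != "rubrerythrin":
            return None
        return ("rubrerythrin",)
    sub_matched = sig.subunit_roles & member_roles
    fused_matched = sig.fused_roles & bfuA_roles
    if sig.subunit_roles and len(sub_matched) >= sig.min_subunit_matches > 0:
        matched |= sub_matched
    if fused_matched:
        matched |= fused_matched
    if not matched:
        return None
    if sig.band == 1 and len(sub_matched) < sig.min_subunit_matches:
        return None
    return tuple(sorted(matched))


def match_signature(
    cluster: GeneCluster,
    candidate_sets: CandidateSet | None = None,
    bfuA_domains: Iterable[str] = (),
    role_vocab: Mapping[str, str] | None = None,
) -> FunctionalCall:
    """Evaluate all signature templates and return the best match.

    ``bfuA_domains`` are the extra domain accessions on the cluster's bfuA
    protein (beyond the two family-defining ones); they resolve to fused
    catalytic roles through the role vocabulary.  Priority: lower band wins;
    within a band more matched roles wins; residual ties give ``Unknown``
    with a tie note rather than a silent pick.
    """
    vocab = dict(role_vocab) if role_vocab is not None else DEFAULT_ROLE_VOCAB
    bfuA_roles = {vocab[d] for d in bfuA_domains if d in vocab}
    hits: list[tuple[int, int, str, tuple[str, ...]]] = []
    for sig in SIGNATURES:
        matched = _match_one(sig, cluster, bfuA_roles)
        if matched is not None:
            hits.append((sig.band, -len(matched), sig.class_name, matched))
    note = ""
    if cluster.bfua is None:
        note = "no bfuA in window (a homolog may be encoded elsewhere)"
    if not hits:
        return FunctionalCall("Unknown", confidence_note=note or "no signature matched")
    hits.sort()
    if len(hits) > 1 and hits[0][:2] == hits[1][:2]:
        tied = sorted({h[2] for h in hits if h[:2] == hits[0][:2]})
        return FunctionalCall(
            "Unknown",
            confidence_note=f"tie between templates {','.join(tied)}",
        )
    _, _, class_name, matched = hits[0]
    return FunctionalCall(class_name, matched_roles=matched, confidence_note=note)


def holoenzyme_subunits(cluster: GeneCluster, call: FunctionalCall) -> list[str]:
    """Gene ids of the holoenzyme: BfuABC plus matched catalytic/partner genes.

    Maturation and regulatory genes in the neighborhood are excluded even
    when they sit inside the operon.
    """
    if call.class_name == "Unknown":
        raise ValueError("cannot list holoenzyme subunits for an Unknown call")
    matched = set(call.matched_roles)
    gene_ids = []
    core_ids = {cluster.anchor.gene_id}
    for sub in (cluster.bfua, cluster.bfuc):
        if sub is not None:
            core_ids.add(sub.gene_id)
    for f in cluster.members:
        role = cluster.roles.get(f.gene_id, "")
        kind = ROLE_KINDS.get(role, "")
        if f.gene_id in core_ids or (
            role in matched and kind in {"catalytic", "partner"}
        ):
            gene_ids.append(f.gene_id)
    return gene_ids
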