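"""FeS cofactor calling against the *A. mobile* reference frame.

Each candidate subunit is globally aligned to its reference sequence; ligand
positions are read through the resulting position map and every cluster is
called present / partial / absent by the fraction of its ligand positions
carrying an allowed residue.  The bifurcating-core verdict requires the
B2-B5 clusters, C1 and the B2 histidine — the conserved signature that
separates true bifurcating cores from Nqo-like non-bifurcating homologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from . import reference as ref

PRESENCE_THRESHOLD = 0.75  # tolerate one mismapped ligand in a quartet
CORE_CLUSTERS = ("B2", "B3", "B4", "B5", "C1")


@dataclass(frozen=True)
class AlignmentScoring:
    """Fixed global-alignment scoring, recorded in output provenance."""

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def describe(self) -> str:
        return f"{self.matrix},open={self.gap_open},extend={self.gap_extend}"


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class ReferenceFrame:
    """Reference sequences plus ligand/FMN-site position tables.

    ``ligands`` maps subunit -> cluster -> [(1-based reference position,
    allowed residue set)].  The packaged defaults cover A1-A5, B1-B5 and C1;
    only B2 and the FMN site carry experimentally assigned residues, the
    rest are synthetic defaults that a user can override.
    """

    sequences: dict[str, str]
    ligands: dict[str, dict[str, list[tuple[int, frozenset[str]]]]] = field(
        default_factory=lambda: ref.LIGANDS
    )
    fmn_site: dict[int, str] = field(default_factory=lambda: ref.FMN_SITE)
    b2_positions: dict[int, frozenset[str]] = field(
        default_factory=lambda: ref.B2_POSITIONS
    )

    def __post_init__(self) -> None:
        for subunit, clusters in self.ligands.items():
            for name, positions in clusters.items():
                pos = [p for p, _ in positions]
                if pos != sorted(set(pos)):
                    raise ValueError(
                        f"{subunit}/{name}: ligand positions must be strictly increasing"
                    )


@dataclass(frozen=True)
class ClusterCall:
    status: str  # present | partial | absent
    fraction: float
    evidence: tuple[tuple[int, str, bool], ...]  # (ref position, residue, allowed)


ClusterCallMap = dict[str, ClusterCall]


@dataclass(frozen=True)
class B2Signature:
    his525_present: bool
    feA476_residue: str

    @property
    def canonical(self) -> bool:
        return self.feA476_residue in {"C", "T"}


@dataclass(frozen=True)
class CoreVerdict:
    bifurcating: bool
    reasons: tuple[str, ...] = ()


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_to_reference(
    query: str, reference_seq: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> dict[int, int]:
    """Globally align ``query`` to ``reference_seq``.

    Returns the position map {0-based reference index -> 0-based query index}
    over aligned (non-gap) columns.  Scoring is fixed affine-gap global
    alignment; ties are resolved by the aligner's deterministic enumeration
    order (first optimal alignment).
    """
    if not query or not reference_seq:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(scoring)
    alignment = next(iter(aligner.align(reference_seq, query)))
    pmap: dict[int, int] = {}
    for (rs, re_), (qs, qe) in zip(*alignment.aligned):
        for k in range(re_ - rs):
            pmap[rs + k] = qs + k
    return pmap


def alignment_score(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Optimal global alignment score under the fixed scoring."""
    return float(_make_aligner(scoring).score(a, b))


def call_clusters(
    position_map: dict[int, int],
    query: str,
    frame: ReferenceFrame,
    subunit: str,
) -> ClusterCallMap:
    """Call every cluster of ``subunit`` from mapped ligand residues.

    A cluster is ``present`` when >= 75% of its ligand positions map to an
    allowed residue, ``absent`` when none do, ``partial`` otherwise.
    """
    if subunit not in frame.ligands:
        raise ValueError(f"no reference for subunit {subunit!r}")
    calls: ClusterCallMap = {}
    for cluster, positions in frame.ligands[subunit].items():
        evidence = []
        n_ok = 0
        for pos1, allowed in positions:
            qidx = position_map.get(pos1 - 1)
            residue = query[qidx] if qidx is not None else "-"
            ok = residue in allowed
            n_ok += ok
            evidence.append((pos1, residue, ok))
        fraction = n_ok / len(positions)
        if fraction >= PRESENCE_THRESHOLD:
            status = "present"
        elif n_ok == 0:
            status = "absent"
        else:
            status = "partial"
        calls[cluster] = ClusterCall(status, fraction, tuple(evidence))
    return calls


def b2_signature(
    position_map: dict[int, int], query: str, frame: ReferenceFrame
) -> B2Signature:
    """Read the B2 histidine (525) and FeA ligand (476) of a BfuB query."""
    his_idx = position_map.get(525 - 1)
    fea_idx = position_map.get(476 - 1)
    his = query[his_idx] if his_idx is not None else "-"
    fea = query[fea_idx] if fea_idx is not None else "-"
    return B2Signature(his525_present=(his == "H"), feA476_residue=fea)


def core_verdict(
    bfuB_calls: ClusterCallMap,
    bfuC_calls: ClusterCallMap,
    b2sig: B2Signature,
) -> CoreVerdict:
    """Bifurcating iff B2-B5 and C1 are present and His525 is retained."""
    reasons = []
    for cluster in ("B2", "B3", "B4", "B5"):
        call = bfuB_calls.get(cluster)
        if call is None or call.status != "present":
            status = call.status if call else "missing"
            reasons.append(f"{cluster} {status}")
    c1 = bfuC_calls.get("C1")
    if c1 is None or c1.status != "present":
        reasons.append(f"C1 {c1.status if c1 else 'missing'}")
    if not b2sig.his525_present:
        reasons.append("His525 absent")
    return CoreVerdict(bifurcating=not reasons, reasons=tuple(reasons))


def entry_cluster(bfuA_calls: ClusterCallMap) -> str:
    """Electron entry into the core: A4 when present, else A3, else 'none'.

    A4 is the default inlet of Type 1/2 enzymes; cores whose BfuA lacks the
    A4 ligands (the Tsib-style exception) must feed through A3 instead.
    """
    if bfuA_calls.get("A4") and bfuA_calls["A4"].status == "present":
        return "A4"
    if bfuA_calls.get("A3") and bfuA_calls["A3"].status == "present":
        return "A3"
    return "none"
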