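"""Reference numbering frame for the BfuABC core (*A. mobile* NiFe-Bfu numbering).

Only the B2 cluster's ligands and the three FMN/NAD(H)-site residues are
experimentally assigned in this frame: B2 is the pentacoordinate [2Fe-2S]
cluster with FeA liganded by C476 + C536 (C476 is Thr in FeFe-type enzymes)
and FeB by C438, C531 and H525; the FMN-site signature is F182/A202/M204.
Ligand positions for every other cluster (A1-A5, B1, B3-B5, C1) are
SYNTHETIC defaults — canonical Cys quartets at fixed positions — packaged so
the scanner and the data generator share one frame.  Real coordinates can be
supplied through :class:`bfuscan.cofactor_scan.ReferenceFrame`.

Positions are 1-based in reference numbering, as is conventional for
residue-level annotation; they are converted to 0-based indices at use sites.
"""

from __future__ import annotations

# Reference subunit lengths (residues).  BfuB must extend past position 536.
SUBUNIT_LENGTHS = {"BfuB": 560, "BfuC": 140, "BfuA": 360}

# B2: pentacoordinate [2Fe-2S]; position 476 admits Cys or Thr.
B2_POSITIONS: dict[int, frozenset[str]] = {
    438: frozenset("C"),
    476: frozenset("CT"),
    525: frozenset("H"),
    531: frozenset("C"),
    536: frozenset("C"),
}

# FMN/NAD(H) secondary-sphere residues conserved in bifurcating cores only.
FMN_SITE: dict[int, str] = {182: "F", 202: "A", 204: "M"}

_C = frozenset("C")


def _quartet(*positions: int) -> list[tuple[int, frozenset[str]]]:
    return [(p, _C) for p in positions]


# cluster name -> [(reference position, allowed residue set)], per subunit.
# The B1 motif is interleaved within the span of the B2 ligands, mirroring
# the overlap that hid B2 from earlier sequence analyses.
LIGANDS: dict[str, dict[str, list[tuple[int, frozenset[str]]]]] = {
    "BfuB": {
        "B1": _quartet(434, 444, 470, 480),
        "B2": sorted(B2_POSITIONS.items()),
        "B3": _quartet(100, 110, 120, 130),
        "B4": _quartet(250, 260, 270, 280),
        "B5": _quartet(320, 330, 340, 350),
    },
    "BfuC": {"C1": _quartet(50, 60, 70, 80)},
    "BfuA": {
        "A1": _quartet(40, 50, 60, 70),
        "A2": _quartet(100, 110, 120, 130),
        "A3": _quartet(160, 170, 180, 190),
        "A4": _quartet(220, 230, 240, 250),
        "A5": _quartet(280, 290, 300, 310),
    },
}

# InterPro domain architecture defining the family.
BFUB_DOMAINS = ("IPR011538", "IPR019554", "IPR019575", "IPR017896")
BFUC_DOMAIN = "IPR002023"
BFUA_DOMAINS = ("IPR017896", "IPR001041")

# Synthetic accessions for the catalytic domains fused to BfuA in Type 1
# enzymes; the role vocabulary maps them onto controlled roles.
FUSED_DOMAIN_ACCESSIONS = {
    "h_cluster": "BFS_HCLUS",
    "nfn_fad": "BFS_NFNFAD",
    "f420_fad": "BFS_F420FAD",
    "fdh_pterin": "BFS_PTERIN",
}
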