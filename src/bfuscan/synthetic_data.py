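"""Synthetic genomes with planted Bfu operons of known class, type and entry.

The generator emulates, at desk scale, the kind of dataset the family was
defined on: operons with the characteristic subunit compositions of the
thirteen functional classes, BfuB/BfuC/BfuA InterPro-style domain
architectures, planted FeS ligand motifs in the reference numbering frame
(including the His/Thr B2 variants), decoy neutral genes, Nqo-like
non-bifurcating homologs lacking the B2-B5 clusters, and tunable neutral
sequence divergence so trees and clades are non-trivial.

The divergence model is deliberately simple: i.i.d. substitutions, uniform
over the 19 alternative residues, with ligand and signature positions exempt
unless explicitly ablated.  No indels, no rate heterogeneity — every
planted subunit therefore keeps an exact register with the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reference as ref
from .io_formats import AMINO_ACIDS, DomainAnnotation, GeneFeature, ProteinRecord

FUSED_DOMAIN_LENGTH = 150
_DEFAULT_ROLE_LENGTH = (200, 600)

# Controlled role vocabulary: role -> kind.  "catalytic"/"partner" roles are
# holoenzyme subunits; "maturation" roles are excluded from holoenzymes.
ROLE_KINDS: dict[str, str] = {
    "bfuA": "bfuA",
    "bfuB": "bfuB",
    "bfuC": "bfuC",
    "nife_small": "catalytic",
    "nife_large": "catalytic",
    "wor_small": "catalytic",
    "wor_large": "catalytic",
    "fdh_catalytic": "catalytic",
    "h_cluster_subunit": "catalytic",
    "rubrerythrin": "partner",
    "hisK": "maturation",
    "hydD": "maturation",
    "hypothetical": "decoy",
    "nqo_like": "decoy",
}
for _fam, _n in (("bam", 5), ("por", 4), ("codh", 3), ("mbh", 6), ("nuo", 11)):
    for _i in range(_n):
        ROLE_KINDS[f"{_fam}_{chr(ord('a') + _i)}"] = "catalytic"


def _fam_roles(fam: str, n: int) -> tuple[str, ...]:
    return tuple(f"{fam}_{chr(ord('a') + i)}" for i in range(n))


@dataclass(frozen=True)
class OperonTemplate:
    """One functional class of the family as an ordered gene layout."""

    name: str
    functional_class: str
    gene_roles: tuple[str, ...]  # operon gene order
    bfuA_clusters: frozenset[str]  # subset of {A1..A5}; empty for Rub
    expected_type: str  # T1..T4
    expected_entry: str  # A3 | A4 | direct
    fused_domains: tuple[str, ...] = ()  # catalytic domains fused to BfuA
    b2_variant: str = "cys"  # "cys" or "thr" at reference position 476

    def __post_init__(self) -> None:
        if self.gene_roles.count("bfuB") != 1:
            raise ValueError(f"template {self.name}: exactly one bfuB required")
        if self.name == "Rub" and "bfuA" in self.gene_roles:
            raise ValueError("Rub template must not contain a bfuA role")


def _t(name, fclass, roles, clusters, etype, entry, fused=(), b2="cys"):
    return OperonTemplate(
        name=name,
        functional_class=fclass,
        gene_roles=tuple(roles),
        bfuA_clusters=frozenset(clusters),
        expected_type=etype,
        expected_entry=entry,
        fused_domains=tuple(fused),
        b2_variant=b2,
    )


#: The fifteen packaged operon layouts.  Fdh1/Fdh2/Fdh3 are the fused,
#: A3-less and A3-containing formate-dehydrogenase configurations; all three
#: map to functional class "Fdh".
TEMPLATES: dict[str, OperonTemplate] = {
    t.name: t
    for t in [
        _t("FeFe", "FeFe", ["bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A4"}, "T1", "A4", fused=["h_cluster"], b2="thr"),
        _t("NiFe", "NiFe",
           ["nife_small", "nife_large", "bfuA", "bfuB", "bfuC", "hisK", "hydD"],
           {"A1", "A2", "A3", "A4", "A5"}, "T3", "A3"),
        _t("Fdh1", "Fdh", ["bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A3", "A4", "A5"}, "T1", "A4", fused=["fdh_pterin"]),
        _t("Fdh2", "Fdh", ["fdh_catalytic", "bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A4"}, "T2", "A4"),
        _t("Fdh3", "Fdh", ["fdh_catalytic", "bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A3", "A4", "A5"}, "T3", "A3"),
        _t("FdhFeFe", "FdhFeFe",
           ["fdh_catalytic", "h_cluster_subunit", "bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A4"}, "T2", "A4", b2="thr"),
        _t("Nfn", "Nfn", ["bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A3", "A5"}, "T1", "A3", fused=["nfn_fad"]),
        _t("F420", "F420", ["bfuA", "bfuB", "bfuC"],
           {"A1", "A2", "A4"}, "T1", "A4", fused=["f420_fad"]),
        _t("Wor", "Wor", ["bfuA", "bfuB", "bfuC", "wor_small", "wor_large"],
           {"A1", "A2", "A4"}, "T2", "A4"),
        # 8-subunit holoenzyme: five extra subunits + the BfuCBA homologs.
        _t("Bam", "Bam",
           list(_fam_roles("bam", 5)) + ["bfuC", "bfuB", "bfuA"],
           {"A1", "A2", "A4"}, "T2", "A4"),
        _t("Por", "Por",
           ["bfuA", "bfuB", "bfuC"] + list(_fam_roles("por", 4)),
           {"A1", "A2", "A4"}, "T2", "A4"),
        # catalytic genes sandwiched between bfuB and bfuA
        _t("Codh", "Codh",
           ["bfuC", "bfuB"] + list(_fam_roles("codh", 3)) + ["bfuA"],
           {"A1", "A2", "A4"}, "T2", "A4"),
        _t("Mbh", "Mbh",
           list(_fam_roles("mbh", 6))[:3] + ["bfuA", "bfuB", "bfuC"]
           + list(_fam_roles("mbh", 6))[3:],
           {"A1", "A2", "A4"}, "T2", "A4"),
        # 14 holoenzyme genes with the BfuABC module in the middle
        _t("Nuo", "Nuo",
           list(_fam_roles("nuo", 11))[:5] + ["bfuA", "bfuB", "bfuC"]
           + list(_fam_roles("nuo", 11))[5:],
           {"A1", "A2", "A3", "A4", "A5"}, "T3", "A3"),
        _t("Rub", "Rub", ["bfuC", "bfuB", "rubrerythrin"],
           frozenset(), "T4", "direct"),
    ]
}


@dataclass
class SyntheticTruth:
    """Ground truth for one generated genome."""

    genome_id: str
    template_name: str
    class_name: str
    expected_type: str
    entry_cluster: str
    anchor_gene_id: str
    bfub_protein_id: str
    clade_id: str
    core_bifurcating: bool = True
    # protein_id -> cluster name -> planted 1-based motif positions
    motif_positions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    ablations: list[str] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    genome_id: str
    records: list[ProteinRecord]
    features: list[GeneFeature]
    domains: list[DomainAnnotation]
    truth: SyntheticTruth


@dataclass
class Cohort:
    genomes: list[SyntheticGenome]

    @property
    def records(self) -> list[ProteinRecord]:
        return [r for g in self.genomes for r in g.records]

    @property
    def features(self) -> list[GeneFeature]:
        return [f for g in self.genomes for f in g.features]

    @property
    def domains(self) -> list[DomainAnnotation]:
        return [d for g in self.genomes for d in g.domains]

    @property
    def truths(self) -> dict[str, SyntheticTruth]:
        return {g.genome_id: g.truth for g in self.genomes}


# ---------------------------------------------------------------------------
# Reference protein construction


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)]


def protected_positions(subunit: str) -> dict[int, str]:
    """1-based position -> required residue for ligand/signature positions."""
    out: dict[int, str] = {}
    for cluster, positions in ref.LIGANDS.get(subunit, {}).items():
        for pos, allowed in positions:
            out[pos] = sorted(allowed)[0]  # C before T; H for 525
    if subunit == "BfuB":
        for pos, res in ref.FMN_SITE.items():
            out[pos] = res
    return out


def make_reference_proteins(
    seed: int, variant: str = "cys"
) -> tuple[dict[str, str], dict[str, dict[str, list[int]]]]:
    """Reference BfuB/BfuC/BfuA sequences with planted ligand motifs.

    Returns ``(sequences, positions)`` where ``positions`` maps subunit ->
    cluster -> planted 1-based positions.  ``variant='thr'`` plants Thr at
    B2 position 476 (the FeFe-style FeA ligand); the default plants Cys.
    Deterministic per ``(seed, variant)``.
    """
    if variant not in {"cys", "thr"}:
        raise ValueError(f"unknown B2 variant {variant!r}")
    sequences: dict[str, str] = {}
    positions: dict[str, dict[str, list[int]]] = {}
    for i, subunit in enumerate(("BfuB", "BfuC", "BfuA")):
        rng = np.random.default_rng([seed, 7001 + i])
        seq = _random_sequence(rng, ref.SUBUNIT_LENGTHS[subunit])
        for pos, res in protected_positions(subunit).items():
            seq[pos - 1] = res
        if subunit == "BfuB" and variant == "thr":
            seq[476 - 1] = "T"
        sequences[subunit] = "".join(seq)
        positions[subunit] = {
            cluster: [p for p, _ in plist]
            for cluster, plist in ref.LIGANDS[subunit].items()
        }
    return sequences, positions


def _mutate(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    protected: set[int] = frozenset(),
) -> str:
    """Substitute each unprotected site with probability ``rate``.

    ``protected`` holds 1-based positions.  Replacement is uniform over the
    19 alternative residues, so a chosen site always changes.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("substitution rate must be in [0, 1]")
    seq = list(sequence)
    if rate > 0:
        hits = rng.random(len(seq)) < rate
        for i in np.flatnonzero(hits):
            if (i + 1) in protected:
                continue
            alternatives = AMINO_ACIDS.replace(seq[i], "")
            seq[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Genome generation

_BFU_SUBUNIT = {"bfuA": "BfuA", "bfuB": "BfuB", "bfuC": "BfuC"}


def _bfub_domain_rows(pid: str, length: int) -> list[DomainAnnotation]:
    step = length // 4
    return [
        DomainAnnotation(pid, dom, i * step, (i + 1) * step if i < 3 else length)
        for i, dom in enumerate(ref.BFUB_DOMAINS)
    ]


def _role_length(role: str, rng: np.random.Generator) -> int:
    lo, hi = _DEFAULT_ROLE_LENGTH
    return int(rng.integers(lo, hi + 1))


def generate_genome(
    template: OperonTemplate | str,
    n_decoy_genes: int = 4,
    divergence: float = 0.0,
    seed: int = 0,
    genome_id: str | None = None,
    ancestor: dict[str, str] | None = None,
    include_nqo_decoy: bool = False,
    standalone_decoy: str | None = None,
    metagenomic: bool = False,
    clade_id: str | None = None,
) -> SyntheticGenome:
    """Generate one genome carrying a single planted operon.

    ``divergence`` (0-0.5 substitutions/site) is applied to every planted
    subunit outside its protected ligand/signature positions.  ``ancestor``
    optionally replaces the seed-0-style reference subunit sequences (used
    by :func:`generate_cohort` to give each template a distinct ancestor).
    ``standalone_decoy`` plants a bfu-less catalytic gene cassette (e.g.
    ``"Codh"`` or ``"Fdh2"`` roles) at least 20 gene positions downstream of
    bfuB, to exercise the neighborhood window.  ``include_nqo_decoy`` adds a
    BfuB-like homolog with the full domain architecture but with the B2-B5
    ligands replaced by Ala — a non-bifurcating decoy.
    """
    if isinstance(template, str):
        if template not in TEMPLATES:
            raise ValueError(f"unknown template {template!r}")
        template = TEMPLATES[template]
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    gid = genome_id or f"g_{template.name}"
    refseqs, motif_pos = make_reference_proteins(0, variant=template.b2_variant)
    if ancestor is not None:
        refseqs = dict(ancestor)
        if template.b2_variant == "thr":
            b = list(refseqs["BfuB"])
            b[476 - 1] = "T"
            refseqs["BfuB"] = "".join(b)

    records: list[ProteinRecord] = []
    features: list[GeneFeature] = []
    domains: list[DomainAnnotation] = []
    truth_motifs: dict[str, dict[str, list[int]]] = {}
    anchor_gene_id = ""
    bfub_pid = ""

    cursor = 0
    gene_index = 0

    def add_gene(role: str, sequence: str, doms: list[DomainAnnotation]) -> str:
        nonlocal cursor, gene_index
        pid = f"{gid}_p{gene_index:03d}_{role}"
        gene_id = f"{gid}_gene{gene_index:03d}"
        length_nt = 3 * len(sequence)
        features.append(
            GeneFeature(
                genome_id=gid, contig=f"{gid}_c1", gene_id=gene_id,
                start=cursor, end=cursor + length_nt, strand="+",
                protein_id=pid, role_label=role,
            )
        )
        records.append(
            ProteinRecord(pid, sequence, genome_id=gid, is_metagenomic=metagenomic)
        )
        for d in doms:
            domains.append(replace(d, protein_id=pid))
        cursor += length_nt + 100
        gene_index += 1
        return pid, gene_id

    # --- planted operon, genes contiguous in template order
    for role in template.gene_roles:
        rng = np.random.default_rng([seed, 101, gene_index])
        if role in _BFU_SUBUNIT:
            subunit = _BFU_SUBUNIT[role]
            protected = set(protected_positions(subunit))
            seq = _mutate(refseqs[subunit], divergence, rng, protected)
            doms: list[DomainAnnotation] = []
            if subunit == "BfuB":
                doms = _bfub_domain_rows("", len(seq))
            elif subunit == "BfuC":
                doms = [DomainAnnotation("", ref.BFUC_DOMAIN, 0, len(seq))]
            else:  # BfuA: realise the cluster profile, then append fusions
                seqlist = list(seq)
                for cluster, plist in ref.LIGANDS["BfuA"].items():
                    if cluster not in template.bfuA_clusters:
                        for pos, _ in plist:
                            seqlist[pos - 1] = "A"
                seq = "".join(seqlist)
                half = len(seq) // 2
                doms = [
                    DomainAnnotation("", ref.BFUA_DOMAINS[0], 0, half),
                    DomainAnnotation("", ref.BFUA_DOMAINS[1], half, len(seq)),
                ]
                base_len = len(seq)
                fused_index = {
                    name: j for j, name in enumerate(sorted(ref.FUSED_DOMAIN_ACCESSIONS))
                }
                for fused in template.fused_domains:
                    frng = np.random.default_rng([seed, 202, fused_index[fused]])
                    fseq = "".join(_random_sequence(frng, FUSED_DOMAIN_LENGTH))
                    doms.append(
                        DomainAnnotation(
                            "", ref.FUSED_DOMAIN_ACCESSIONS[fused],
                            base_len, base_len + len(fseq),
                        )
                    )
                    seq = seq + fseq
                    base_len += len(fseq)
            pid, gene_id = add_gene(role, seq, doms)
            if subunit == "BfuB":
                anchor_gene_id, bfub_pid = gene_id, pid
                truth_motifs[pid] = dict(motif_pos["BfuB"])
            elif subunit == "BfuA":
                truth_motifs[pid] = {
                    c: p for c, p in motif_pos["BfuA"].items()
                    if c in template.bfuA_clusters
                }
            else:
                truth_motifs[pid] = dict(motif_pos[subunit])
        else:
            seq = "".join(_random_sequence(rng, _role_length(role, rng)))
            pid, gene_id = add_gene(role, seq, [])

    anchor_index = next(
        i for i, f in enumerate(features) if f.gene_id == anchor_gene_id
    )

    # --- neutral decoy genes
    for k in range(n_decoy_genes):
        rng = np.random.default_rng([seed, 303, k])
        seq = "".join(_random_sequence(rng, int(rng.integers(120, 400))))
        add_gene("hypothetical", seq, [])

    # --- standalone catalytic cassette, >= 20 gene positions from bfuB
    if standalone_decoy is not None:
        if standalone_decoy not in TEMPLATES:
            raise ValueError(f"unknown standalone decoy template {standalone_decoy!r}")
        while gene_index - anchor_index < 20:
            rng = np.random.default_rng([seed, 404, gene_index])
            seq = "".join(_random_sequence(rng, int(rng.integers(120, 400))))
            add_gene("hypothetical", seq, [])
        cassette = [
            r for r in TEMPLATES[standalone_decoy].gene_roles
            if ROLE_KINDS.get(r) == "catalytic"
        ]
        for role in cassette:
            rng = np.random.default_rng([seed, 505, gene_index])
            seq = "".join(_random_sequence(rng, _role_length(role, rng)))
            add_gene(role, seq, [])

    # --- Nqo-like non-bifurcating BfuB homolog (B2-B5 ligands -> Ala)
    if include_nqo_decoy:
        rng = np.random.default_rng([seed, 606])
        seq = list(refseqs["BfuB"])
        for cluster in ("B2", "B3", "B4", "B5"):
            for pos, _ in ref.LIGANDS["BfuB"][cluster]:
                seq[pos - 1] = "A"
        nqo_seq = _mutate(
            "".join(seq), divergence, rng, set(protected_positions("BfuB"))
        )
        add_gene("nqo_like", nqo_seq, _bfub_domain_rows("", len(nqo_seq)))

    truth = SyntheticTruth(
        genome_id=gid,
        template_name=template.name,
        class_name=template.functional_class,
        expected_type=template.expected_type,
        entry_cluster=template.expected_entry,
        anchor_gene_id=anchor_gene_id,
        bfub_protein_id=bfub_pid,
        clade_id=clade_id or template.name,
        motif_positions=truth_motifs,
    )
    return SyntheticGenome(gid, records, features, domains, truth)


# ---------------------------------------------------------------------------
# Ablation

_CLUSTER_SUBUNIT = {
    **{c: "BfuB" for c in ("B1", "B2", "B3", "B4", "B5")},
    "C1": "BfuC",
    **{c: "BfuA" for c in ("A1", "A2", "A3", "A4", "A5")},
}
_CORE = {"B2", "B3", "B4", "B5", "C1"}


def ablate(genome: SyntheticGenome, target: str, seed: int = 0) -> SyntheticGenome:
    """Remove exactly one planted signal and update the truth accordingly.

    ``target`` is a cluster name (ligand residues -> Ala), ``"His525"``, the
    gene role ``"bfuA"`` (gene deleted), or a domain accession (annotation
    rows dropped).  Raises when the target is absent from the genome.
    """
    records = list(genome.records)
    features = list(genome.features)
    domains = list(genome.domains)
    truth = replace(
        genome.truth,
        motif_positions={k: dict(v) for k, v in genome.truth.motif_positions.items()},
        ablations=list(genome.truth.ablations) + [target],
    )
    template = TEMPLATES[truth.template_name]

    def _mutate_protein(role: str, positions: list[int]) -> None:
        idx = next(
            (i for i, f in enumerate(features)
             if f.role_label == role and f.gene_id.startswith(truth.genome_id)),
            None,
        )
        if idx is None:
            raise ValueError(f"target {target!r}: no {role} gene in genome")
        pid = features[idx].protein_id
        ridx = next(i for i, r in enumerate(records) if r.protein_id == pid)
        seq = list(records[ridx].sequence)
        for pos in positions:
            seq[pos - 1] = "A"
        records[ridx] = replace(records[ridx], sequence="".join(seq))

    if target in _CLUSTER_SUBUNIT:
        subunit = _CLUSTER_SUBUNIT[target]
        if subunit == "BfuA" and target not in template.bfuA_clusters:
            raise ValueError(f"target {target!r} not planted in {template.name}")
        role = {v: k for k, v in _BFU_SUBUNIT.items()}[subunit]
        positions = [p for p, _ in ref.LIGANDS[subunit][target]]
        _mutate_protein(role, positions)
        if target in _CORE:
            truth.core_bifurcating = False
            truth.expected_type = "NonBifurcating"
            truth.entry_cluster = "none"
        elif target == "A4":
            truth.entry_cluster = "A3" if "A3" in template.bfuA_clusters else "none"
        elif target == "A3" and truth.entry_cluster == "A3":
            truth.entry_cluster = "none"
    elif target == "His525":
        _mutate_protein("bfuB", [525])
        truth.core_bifurcating = False
        truth.expected_type = "NonBifurcating"
        truth.entry_cluster = "none"
    elif target == "bfuA":
        idx = next(
            (i for i, f in enumerate(features) if f.role_label == "bfuA"), None
        )
        if idx is None:
            raise ValueError("target 'bfuA': genome has no bfuA gene")
        pid = features[idx].protein_id
        del features[idx]
        records = [r for r in records if r.protein_id != pid]
        domains = [d for d in domains if d.protein_id != pid]
        if truth.class_name != "Rub":
            truth.expected_type = "Unclassified"
            truth.entry_cluster = "none"
    else:  # domain accession
        kept = [d for d in domains if d.domain_id != target]
        if len(kept) == len(domains):
            raise ValueError(f"target {target!r}: no such domain annotation")
        domains = kept
    return SyntheticGenome(genome.genome_id, records, features, domains, truth)


# ---------------------------------------------------------------------------
# Cohorts


def generate_cohort(
    templates: list[str] | None = None,
    n_per_template: int = 1,
    divergence: float = 0.05,
    between_divergence: float = 0.45,
    seed: int = 0,
    n_decoy_genes: int = 3,
) -> Cohort:
    """Generate a multi-genome dataset with intended clade structure.

    Each template is seeded from a distinct ancestor — the reference
    subunits mutated at ``between_divergence`` (substitutions per
    unprotected site, up to 1.0 = full randomisation) — and every copy then
    diverges from its ancestor at ``divergence``.  BfuB sequences therefore
    cluster by template; the truth records the intended clade id (the
    template name) per genome.
    """
    if n_per_template < 1:
        raise ValueError("n_per_template must be >= 1")
    names = sorted(templates) if templates else sorted(TEMPLATES)
    base, _ = make_reference_proteins(0)
    genomes: list[SyntheticGenome] = []
    for ti, name in enumerate(names):
        if name not in TEMPLATES:
            raise ValueError(f"unknown template {name!r}")
        ancestor = {
            subunit: _mutate(
                seq, between_divergence,
                np.random.default_rng([seed, 11, ti, si]),
                set(protected_positions(subunit)),
            )
            for si, (subunit, seq) in enumerate(sorted(base.items()))
        }
        for copy in range(n_per_template):
            genomes.append(
                generate_genome(
                    TEMPLATES[name],
                    n_decoy_genes=n_decoy_genes,
                    divergence=divergence,
                    seed=int(np.random.default_rng([seed, 13, ti, copy]).integers(2**31)),
                    genome_id=f"g_{name}_{copy}",
                    ancestor=ancestor,
                    clade_id=name,
                )
            )
    return Cohort(genomes)
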