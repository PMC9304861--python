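"""End-to-end orchestration: simulate and/or classify a dataset on disk.

Stage order is fixed: domain filtering -> cofactor scanning -> neighborhood
matching -> type assignment -> tree + clade partition -> energetics.  Every
output artifact carries the run's provenance (seed, thresholds, alignment
scoring), and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats, thermo
from .classify import classify_dataset, default_reference_frame
from .cofactor_scan import DEFAULT_SCORING, PRESENCE_THRESHOLD, AlignmentScoring
from .domain_filter import CandidateSet, dedup_and_filter, select_bfua, select_bfub, select_bfuc
from .mechanism import TRANSFER_LIMIT_ANGSTROM
from .operon_context import DEFAULT_WINDOW
from .phylo import DEFAULT_CLADE_THRESHOLD, distance_matrix, nj_tree, partition_clades, clade_summary
from .synthetic_data import TEMPLATES, generate_cohort

logger = logging.getLogger("bfuscan")


@dataclass
class PipelineConfig:
    fasta: str = ""
    domains: str = ""
    features: str = ""
    feature_dialect: str = "gff3"
    out_dir: str = "bfuscan_out"
    window: int = DEFAULT_WINDOW
    clade_threshold: float = DEFAULT_CLADE_THRESHOLD
    presence_threshold: float = PRESENCE_THRESHOLD
    alignment_matrix: str = DEFAULT_SCORING.matrix
    gap_open: float = DEFAULT_SCORING.gap_open
    gap_extend: float = DEFAULT_SCORING.gap_extend
    seed: int = 0
    outgroup: str | None = None
    role_vocab: str = ""  # optional YAML file: label -> controlled role
    # simulate settings
    templates: list[str] = field(default_factory=lambda: sorted(TEMPLATES))
    n_per_template: int = 1
    divergence: float = 0.0
    between_divergence: float = 0.45
    n_decoy_genes: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.clade_threshold:
            raise ValueError("clade threshold must be positive")
        if not 0 < self.presence_threshold <= 1:
            raise ValueError("presence threshold must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @property
    def scoring(self) -> AlignmentScoring:
        return AlignmentScoring(self.alignment_matrix, self.gap_open, self.gap_extend)

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "window": self.window,
            "clade_threshold": self.clade_threshold,
            "presence_threshold": self.presence_threshold,
            "c1_b2_transfer_limit_angstrom": TRANSFER_LIMIT_ANGSTROM,
            "alignment": self.scoring.describe(),
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_role_vocab(config: PipelineConfig):
    if not config.role_vocab:
        return None
    from .operon_context import DEFAULT_ROLE_VOCAB

    extra = yaml.safe_load(Path(config.role_vocab).read_text()) or {}
    return {**DEFAULT_ROLE_VOCAB, **extra}


def simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the pipeline's formats."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        templates=config.templates,
        n_per_template=config.n_per_template,
        divergence=config.divergence,
        between_divergence=config.between_divergence,
        seed=config.seed,
        n_decoy_genes=config.n_decoy_genes,
    )
    paths = {
        "fasta": out / "proteins.faa",
        "features": out / "features.gff3",
        "domains": out / "domains.tsv",
        "truth": out / "truth.json",
    }
    io_formats.write_fasta(cohort.records, paths["fasta"])
    io_formats.write_features(cohort.features, paths["features"], dialect="gff3")
    io_formats.write_domains(cohort.domains, paths["domains"])
    truth_payload = {
        "seed": config.seed,
        "genomes": {gid: asdict(t) for gid, t in sorted(cohort.truths.items())},
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2) + "\n")
    logger.info("simulated %d genomes -> %s", len(cohort.genomes), out)
    return paths


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Classify a dataset end to end and write the full artifact set."""
    for name in ("fasta", "domains", "features"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} missing: {path!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    vocab = _load_role_vocab(config)

    records = io_formats.read_fasta(config.fasta)
    features = io_formats.read_features(config.features, config.feature_dialect)
    domains = io_formats.read_domains(config.domains)

    logger.info("stage classify: %d proteins, %d features", len(records), len(features))
    table = classify_dataset(
        records, features, domains,
        frame=default_reference_frame(),
        window=config.window,
        scoring=config.scoring,
        role_vocab=vocab,
    )
    artifacts: dict[str, Path] = {}
    tsv, js = io_formats.write_report(table, out / "classifications", prov)
    artifacts["classifications_tsv"], artifacts["classifications_json"] = tsv, js

    # tree over deduplicated, non-metagenomic BfuB candidates
    candidates = dedup_and_filter(
        records,
        CandidateSet(
            bfuB_ids=select_bfub(domains),
            bfuC_ids=select_bfuc(domains),
            bfuA_ids=select_bfua(domains),
        ),
    )
    rec_by_id = {r.protein_id: r for r in records}
    leaf_seqs = {pid: rec_by_id[pid].sequence for pid in sorted(candidates.bfuB_ids)}
    if config.outgroup and config.outgroup in rec_by_id:
        leaf_seqs[config.outgroup] = rec_by_id[config.outgroup].sequence
    if len(leaf_seqs) >= 3:
        logger.info("stage tree: %d BfuB leaves", len(leaf_seqs))
        tree = nj_tree(distance_matrix(leaf_seqs, config.scoring))
        io_formats.write_newick(tree, out / "tree.nwk")
        artifacts["tree"] = out / "tree.nwk"
        partition = partition_clades(
            tree, config.clade_threshold, outgroup=config.outgroup
        )
        clade_rows = [
            {"leaf": leaf, "clade": cid,
             "is_orphan": partition.clades[cid]["is_orphan"]}
            for leaf, cid in sorted(partition.leaf_to_clade.items())
        ]
        pd.DataFrame(clade_rows).to_csv(out / "clades.tsv", sep="\t", index=False)
        artifacts["clades"] = out / "clades.tsv"
        class_by_leaf = dict(
            zip(table["anchor_protein_id"], table["class"], strict=True)
        )
        summary = clade_summary(partition, class_by_leaf)
        summary.to_csv(out / "clade_summary.tsv", sep="\t")
        artifacts["clade_summary"] = out / "clade_summary.tsv"

    energy_rows = []
    for class_name in sorted(set(table["class"])):
        if class_name == "Unknown":
            continue
        couple = thermo.lookup_couple(class_name)
        result = thermo.bifurcation_energetics(class_name)
        energy_rows.append(
            {
                "class": class_name,
                "e0_prime_mv": couple.e0_prime_mv,
                "category": thermo.categorize(couple),
                "dG_NAD_leg_kj": round(result.legs[0][2], 3),
                "dG_Fd_leg_kj": round(result.legs[1][2], 3),
                "dG_net_kj": round(result.net_kj_per_mol, 3),
            }
        )
    with open(out / "energetics.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(
            energy_rows,
            columns=["class", "e0_prime_mv", "category",
                     "dG_NAD_leg_kj", "dG_Fd_leg_kj", "dG_net_kj"],
        ).to_csv(fh, sep="\t", index=False)
    artifacts["energetics"] = out / "energetics.tsv"
    return artifacts
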