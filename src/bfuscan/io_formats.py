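"""Readers and writers for every on-disk format the pipeline touches.

All other modules work purely on the in-memory types defined here:
:class:`ProteinRecord`, :class:`DomainAnnotation` and :class:`GeneFeature`.
Coordinates are 0-based half-open everywhere inside the package; GFF3
(1-based inclusive) is converted once, at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DOMAIN_COLUMNS = ["protein_id", "domain_id", "start", "end", "score"]
FEATURE_COLUMNS = [
    "genome_id", "contig", "gene_id", "start", "end", "strand",
    "protein_id", "role_label",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its genome of origin.

    ``is_metagenomic`` is carried as metadata (``metagenome=true`` in the
    FASTA description); it is never inferred from the sequence.
    """

    protein_id: str
    sequence: str
    genome_id: str = ""
    is_metagenomic: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r} contains non-amino-acid letters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain hit on a protein (0-based half-open residue interval)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"domain {self.domain_id} on {self.protein_id}: "
                f"invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus (0-based half-open nucleotide interval) linked to a protein."""

    genome_id: str
    contig: str
    gene_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    role_label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The header token before the first whitespace is the protein id; optional
    ``key=value`` pairs in the description set ``genome_id`` (key ``genome``)
    and ``is_metagenomic`` (key ``metagenome``, value ``true``/``false``).
    Duplicate ids and empty sequences are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = _parse_description(rec.description, rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for protein {rec.id!r} in {path}")
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=seq,
                genome_id=kv.get("genome", ""),
                is_metagenomic=kv.get("metagenome", "false").lower() == "true",
            )
        )
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = sorted(pid for pid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate protein ids in {path}: {dupes}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with ``genome=`` and ``metagenome=`` description keys."""
    out = []
    for r in records:
        desc = f"genome={r.genome_id} metagenome={'true' if r.is_metagenomic else 'false'}"
        out.append(SeqRecord(Seq(r.sequence), id=r.protein_id, description=desc))
    SeqIO.write(out, str(path), "fasta")


def _parse_description(description: str, protein_id: str) -> dict[str, str]:
    kv: dict[str, str] = {}
    for tok in description.split()[1:]:  # first token repeats the id
        if "=" in tok:
            k, v = tok.split("=", 1)
            kv[k] = v
    return kv


# ---------------------------------------------------------------------------
# Gene features: GFF3 (1-based inclusive) and TSV (0-based half-open)

def read_features(path: str | Path, dialect: str = "gff3") -> list[GeneFeature]:
    """Read gene features, normalising coordinates to 0-based half-open.

    ``dialect='gff3'``: standard 9-column GFF3, 1-based inclusive; genome id
    comes from a ``##genome-id`` pragma or the ``genome_id`` attribute.
    ``dialect='tsv'``: the package's own table (columns ``FEATURE_COLUMNS``),
    already 0-based half-open.
    """
    if dialect == "tsv":
        return _read_features_tsv(path)
    if dialect == "gff3":
        return _read_features_gff3(path)
    raise ValueError(f"unknown feature dialect {dialect!r}")


def _read_features_tsv(path: str | Path) -> list[GeneFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(FEATURE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown feature columns in {path}: {sorted(unknown)}")
    feats = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(f"{path} line {i}: start {start} >= end {end}")
        feats.append(
            GeneFeature(
                genome_id=row.genome_id,
                contig=row.contig,
                gene_id=row.gene_id,
                start=start,
                end=end,
                strand=row.strand,
                protein_id=row.protein_id or None,
                role_label=row.role_label,
            )
        )
    return feats


def _read_features_gff3(path: str | Path) -> list[GeneFeature]:
    feats = []
    default_genome = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##genome-id"):
                default_genome = line.split(None, 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path} line {lineno}: expected 9 GFF3 columns")
            contig, _source, _type, start1, end1, _score, strand, _phase, attrs = cols
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            if start >= end:
                raise ValueError(f"{path} line {lineno}: start >= end after normalization")
            a = _parse_gff_attributes(attrs)
            feats.append(
                GeneFeature(
                    genome_id=a.get("genome_id", default_genome),
                    contig=contig,
                    gene_id=a.get("ID", f"gene{lineno}"),
                    start=start,
                    end=end,
                    strand=strand,
                    protein_id=a.get("protein_id") or None,
                    role_label=a.get("role_label", ""),
                )
            )
    return feats


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_features(features: Sequence[GeneFeature], path: str | Path,
                   dialect: str = "gff3") -> None:
    if dialect == "tsv":
        rows = [
            {
                "genome_id": f.genome_id, "contig": f.contig, "gene_id": f.gene_id,
                "start": f.start, "end": f.end, "strand": f.strand,
                "protein_id": f.protein_id or "", "role_label": f.role_label,
            }
            for f in features
        ]
        pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if dialect != "gff3":
        raise ValueError(f"unknown feature dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.gene_id}", f"genome_id={f.genome_id}"]
            if f.protein_id:
                attrs.append(f"protein_id={f.protein_id}")
            if f.role_label:
                attrs.append(f"role_label={f.role_label}")
            fh.write(
                "\t".join(
                    [
                        f.contig, "bfuscan", "gene",
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Domain annotations

def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read the domain TSV (protein_id, domain_id, start, end, score)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(DOMAIN_COLUMNS)
    if unknown:
        raise ValueError(f"unknown domain columns in {path}: {sorted(unknown)}")
    anns = []
    for row in df.itertuples(index=False):
        score = float(row.score) if getattr(row, "score", "") not in ("", None) else None
        anns.append(
            DomainAnnotation(
                protein_id=row.protein_id,
                domain_id=row.domain_id,
                start=int(row.start),
                end=int(row.end),
                score=score,
            )
        )
    return anns


def write_domains(annotations: Sequence[DomainAnnotation], path: str | Path) -> None:
    rows = [
        {
            "protein_id": a.protein_id, "domain_id": a.domain_id,
            "start": a.start, "end": a.end,
            "score": "" if a.score is None else a.score,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`bfuscan.phylo.PhyloTree` as Newick (6 significant digits)."""
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Classification report

def write_report(classifications: pd.DataFrame, path_prefix: str | Path,
                 provenance: Mapping[str, object] | None = None) -> tuple[Path, Path]:
    """Write the final classification table as TSV + JSON.

    Returns the two paths written (``<prefix>.tsv``, ``<prefix>.json``).
    ``provenance`` (seed, thresholds, scoring) is embedded in the JSON and in
    ``#``-prefixed header lines of the TSV so every run is auditable.
    """
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    prov = dict(provenance or {})
    with open(tsv_path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        classifications.to_csv(fh, sep="\t", index=False)
    payload = {
        "provenance": prov,
        "classifications": classifications.to_dict(orient="records"),
    }
    json_path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return tsv_path, json_path
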