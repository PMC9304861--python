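"""Candidate selection by InterPro domain architecture, plus dedup/filtering.

BfuB candidates must carry all four defining domains (IPR011538, IPR019554,
IPR019575, IPR017896), BfuC candidates IPR002023, and BfuA candidates at
least IPR017896 + IPR001041 (extra domains are permitted — they define the
Type 1 fusions).  ``dedup_and_filter`` mirrors the retrieval-stage cleanup:
exact-sequence duplicates collapse to the lexicographically smallest id and
metagenome-derived records are excluded.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import reference as ref
from .io_formats import DomainAnnotation, ProteinRecord

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def _normalize(domain_id: str) -> str:
    """Exact-string accession matching, with version suffixes stripped."""
    return _VERSION_SUFFIX.sub("", domain_id)


def _domains_by_protein(
    annotations: Iterable[DomainAnnotation],
) -> dict[str, set[str]]:
    by_protein: dict[str, set[str]] = defaultdict(set)
    for a in annotations:
        by_protein[a.protein_id].add(_normalize(a.domain_id))
    return by_protein


def _select(
    annotations: Iterable[DomainAnnotation], required: Sequence[str]
) -> set[str]:
    req = {_normalize(d) for d in required}
    return {
        pid for pid, doms in _domains_by_protein(annotations).items()
        if req <= doms
    }


def select_bfub(annotations: Iterable[DomainAnnotation]) -> set[str]:
    """Proteins annotated with all four BfuB-defining domains."""
    return _select(annotations, ref.BFUB_DOMAINS)


def select_bfuc(annotations: Iterable[DomainAnnotation]) -> set[str]:
    """Proteins annotated with the BfuC-defining domain."""
    return _select(annotations, [ref.BFUC_DOMAIN])


def select_bfua(annotations: Iterable[DomainAnnotation]) -> set[str]:
    """Proteins carrying, at a minimum, both BfuA-defining domains."""
    return _select(annotations, ref.BFUA_DOMAINS)


def rejection_reasons(
    annotations: Iterable[DomainAnnotation], required: Sequence[str]
) -> dict[str, str]:
    """For annotated proteins failing the conjunction, list missing domains."""
    req = {_normalize(d) for d in required}
    out = {}
    for pid, doms in _domains_by_protein(annotations).items():
        missing = sorted(req - doms)
        if missing:
            out[pid] = "missing " + ",".join(missing)
    return out


@dataclass
class CandidateSet:
    """Surviving candidate ids per subunit plus per-protein rejection reasons."""

    bfuB_ids: set[str] = field(default_factory=set)
    bfuC_ids: set[str] = field(default_factory=set)
    bfuA_ids: set[str] = field(default_factory=set)
    rejected: dict[str, str] = field(default_factory=dict)


def dedup_and_filter(
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    candidates: CandidateSet,
) -> CandidateSet:
    """Collapse exact-sequence duplicates and drop metagenomic records.

    Within each subunit pool, records with identical full-length sequences
    keep only the lexicographically smallest protein_id; metagenome-flagged
    records are removed with reason ``"metagenomic"``.  Idempotent.
    """
    if not isinstance(records, Mapping):
        records = {r.protein_id: r for r in records}
    out = CandidateSet(rejected=dict(candidates.rejected))
    for attr in ("bfuB_ids", "bfuC_ids", "bfuA_ids"):
        pool = getattr(candidates, attr)
        missing = [pid for pid in pool if pid not in records]
        if missing:
            raise ValueError(f"candidate ids without records: {sorted(missing)}")
        by_seq: dict[str, list[str]] = defaultdict(list)
        for pid in sorted(pool):
            rec = records[pid]
            if rec.is_metagenomic:
                out.rejected[pid] = "metagenomic"
                continue
            by_seq[rec.sequence].append(pid)
        kept = set()
        for pids in by_seq.values():
            keeper, *dupes = sorted(pids)
            kept.add(keeper)
            for d in dupes:
                out.rejected[d] = f"duplicate of {keeper}"
        getattr(out, attr).update(kept)
    return out
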