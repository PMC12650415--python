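"""Coding-sequence quality control and shared-gene-set derivation.

Two inclusion regimes are used downstream: the codon-usage set (strict:
length floor, clean start/stop, no internal stop, no ambiguity) and the
substitution-rate set (relaxed: no length floor, ambiguous codons masked
rather than rejected, so that pairwise codon comparison can simply skip
them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genetics import START_CODON, STOP_CODONS
from .io_plastome import CodingSequence

REASONS = (
    "too_short",
    "non_ATG_start",
    "bad_stop",
    "internal_stop",
    "not_multiple_of_3",
    "ambiguous_base",
)


@dataclass
class QCReport:
    gene: str
    species_id: str
    accepted: bool
    reasons: list[str] = field(default_factory=list)


def _codons(seq: str):
    return (seq[i : i + 3] for i in range(0, len(seq), 3))


def qc_reasons(seq: str, min_len: int = 300, ambiguous_policy: str = "reject") -> list[str]:
    """Independent one-pass predicate evaluation; order fixed by REASONS."""
    reasons = []
    if len(seq) < min_len:
        reasons.append("too_short")
    if seq[:3] != START_CODON:
        reasons.append("non_ATG_start")
    if len(seq) % 3 != 0:
        reasons.append("not_multiple_of_3")
    else:
        codons = list(_codons(seq))
        if codons and codons[-1] not in STOP_CODONS:
            reasons.append("bad_stop")
        if any(c in STOP_CODONS for c in codons[:-1]):
            reasons.append("internal_stop")
    if ambiguous_policy == "reject" and any(b not in "ACGT" for b in seq):
        reasons.append("ambiguous_base")
    return reasons


def filter_cds(
    cds: list[CodingSequence],
    min_len: int = 300,
    ambiguous_policy: str = "reject",
) -> tuple[list[CodingSequence], list[QCReport]]:
    """Apply the gene-inclusion rules.

    Accepted sequences are at least ``min_len`` bases (measured on the
    annotated CDS including its terminal stop), a multiple of three, start
    with ATG, end with TAA/TAG/TGA, and contain no internal stop.  With
    ``ambiguous_policy='reject'`` any non-ACGT base rejects the gene; with
    ``'mask'`` such codons are replaced by NNN and flagged (for pairwise
    substitution counting, which skips masked codons).  The terminal stop
    is stripped from accepted sequences before codon counting; rejections
    are reported as data, never raised.
    """
    accepted: list[CodingSequence] = []
    reports: list[QCReport] = []
    for c in cds:
        reasons = qc_reasons(c.seq, min_len=min_len, ambiguous_policy=ambiguous_policy)
        reports.append(
            QCReport(gene=c.gene, species_id=c.species_id, accepted=not reasons, reasons=reasons)
        )
        if reasons:
            continue
        body = c.seq[:-3]  # strip terminal stop
        if ambiguous_policy == "mask":
            cods = [
                cod if all(b in "ACGT" for b in cod) else "NNN" for cod in _codons(body)
            ]
            body = "".join(cods)
        flags = set(c.flags)
        if "N" in body:
            flags.add("ambiguous_masked")
        accepted.append(
            CodingSequence(
                species_id=c.species_id,
                gene=c.gene,
                seq=body,
                n_codons=len(body) // 3,
                flags=flags,
            )
        )
    return accepted, reports


def filter_for_dnds(cds: list[CodingSequence]) -> tuple[list[CodingSequence], list[QCReport]]:
    """Relaxed regime for substitution-rate work: ATG/stop/internal-stop
    rules only (no length floor), ambiguous codons masked."""
    return filter_cds(cds, min_len=0, ambiguous_policy="mask")


def shared_genes(per_species: dict[str, set[str] | list[str]]) -> list[str]:
    """Alphabetically ordered intersection of per-species accepted gene sets."""
    if len(per_species) < 2:
        raise ValueError("shared_genes needs at least two species")
    sets = [set(v) for v in per_species.values()]
    common = set.intersection(*sets)
    if not common:
        warnings.warn("no genes shared across all species")
    return sorted(common)
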