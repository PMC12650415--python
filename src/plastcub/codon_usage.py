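"""Core codon-usage statistics: counts, positional GC, GC3s, RSCU, ENC.

Positional GC (GC1/GC2/GC3 and their mean GC_all) is computed over all
sense codons after terminal-stop stripping, matching EMBOSS ``cusp``
semantics.  GC3s restricts the third position to codons in synonymous
families of degeneracy >= 2 (Met, Trp and stops excluded).  The effective
number of codons is Wright's estimator built from per-family codon
homozygosities, with six-fold families (Leu, Ser, Arg) treated whole::

    F_hat = (n * sum(p_i^2) - 1) / (n - 1)          per family, n >= 2
    ENC   = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6           means over degeneracy classes

A missing three-fold class (Ile unobserved) is imputed as the mean of the
two- and four-fold class means; families with F <= 0 or fewer than two
counted codons are dropped from their class mean; the result is capped at
61 and is undefined (None) when any class mean cannot be formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genetics import (
    AA_OF,
    DEGENERACY,
    FAMILIES,
    FOURFOLD_FAMILIES,
    SENSE_CODONS,
    SINGLE_CODONS,
    STOP_CODONS,
)
from .io_plastome import CodingSequence

# class sizes under table 11 with whole six-fold families:
# nine two-fold, one three-fold (Ile), five four-fold, three six-fold
_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCountTable:
    """64-cell codon counts grouped into synonymous families."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def sense_counts(self) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in SENSE_CODONS}

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = dict(self.counts)
        for c, x in other.counts.items():
            merged[c] = merged.get(c, 0) + x
        return CodonCountTable(merged)


@dataclass
class GeneCUBProfile:
    """Per-gene codon-usage profile (the per-point record behind the
    neutrality, ENC and PR2 diagnostics)."""

    gene: str
    species_id: str
    n_codons: int
    gc1: float
    gc2: float
    gc3: float
    gc_all: float
    gc12: float
    gc3s: float | None
    a3: int
    t3: int
    g3: int
    c3: int
    enc: float | None
    rscu: dict[str, float | None]


def count_codons(cds: CodingSequence | str) -> CodonCountTable:
    """Frame-0 triplet counts of an in-frame sequence."""
    seq = cds.seq if isinstance(cds, CodingSequence) else cds
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts)


def gc_by_position(t: CodonCountTable) -> tuple[float, float, float, float]:
    """(GC1, GC2, GC3, GC_all) over all counted sense codons."""
    totals = [0, 0, 0]
    gc = [0, 0, 0]
    for codon, x in t.counts.items():
        if codon in STOP_CODONS or codon not in AA_OF:
            continue
        for p in range(3):
            totals[p] += x
            if codon[p] in "GC":
                gc[p] += x
    if totals[0] == 0:
        raise ValueError("gc_by_position: zero sense codons")
    g1, g2, g3 = (gc[p] / totals[p] for p in range(3))
    return g1, g2, g3, (g1 + g2 + g3) / 3.0


def gc3s(t: CodonCountTable) -> float | None:
    """GC fraction at synonymous third positions (degeneracy >= 2 only);
    None when no synonymous codon was observed."""
    total = 0
    gc = 0
    for codon, x in t.counts.items():
        if codon not in AA_OF or codon in SINGLE_CODONS:
            continue
        total += x
        if codon[2] in "GC":
            gc += x
    return gc / total if total else None


def third_position_counts(t: CodonCountTable, base_set: str = "fourfold") -> dict[str, int]:
    """Third-position base counts (A3/T3/G3/C3) for the parity-rule-2 plot.

    ``base_set='fourfold'`` (default, Sueoka's construction) counts third
    positions of four-fold degenerate families only; ``'all'`` counts all
    sense-codon third positions.
    """
    if base_set == "fourfold":
        allowed = {c for fam in FOURFOLD_FAMILIES.values() for c in fam}
    elif base_set == "all":
        allowed = set(SENSE_CODONS)
    else:
        raise ValueError(f"unknown PR2 base set {base_set!r}")
    out = {"A": 0, "C": 0, "G": 0, "T": 0}
    for codon, x in t.counts.items():
        if codon in allowed:
            out[codon[2]] += x
    return out


def rscu(t: CodonCountTable) -> dict[str, float | None]:
    """Relative synonymous codon usage per sense codon.

    RSCU_ij = X_ij / mean(X over the family); families with zero total and
    the single-codon families (Met, Trp) map to None.
    """
    counts = t.sense_counts()
    out: dict[str, float | None] = {}
    for aa, fam in FAMILIES.items():
        if len(fam) == 1:
            for c in fam:
                out[c] = None
            continue
        total = sum(counts[c] for c in fam)
        for c in fam:
            out[c] = None if total == 0 else counts[c] * len(fam) / total
    return out


def enc(t: CodonCountTable) -> float | None:
    """Wright's effective number of codons; None when undefined."""
    counts = t.sense_counts()
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in FAMILIES.items():
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts[c] for c in fam)
        if n < 2:
            continue
        s = sum((counts[c] / n) ** 2 for c in fam)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            f_by_class[k].append(f)
    means = {k: (sum(v) / len(v) if v else None) for k, v in f_by_class.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2.0  # Ile family absent
    if any(means[k] is None for k in (2, 3, 4, 6)):
        return None
    value = 2.0 + sum(_CLASS_WEIGHT[k] / means[k] for k in (2, 3, 4, 6))
    return min(value, 61.0)


def gene_profile(cds: CodingSequence, pr2_base_set: str = "fourfold") -> GeneCUBProfile:
    """Compute the full per-gene profile from a QC-accepted (stop-stripped)
    coding sequence."""
    t = count_codons(cds)
    g1, g2, g3, g_all = gc_by_position(t)
    thirds = third_position_counts(t, base_set=pr2_base_set)
    return GeneCUBProfile(
        gene=cds.gene,
        species_id=cds.species_id,
        n_codons=t.n_codons,
        gc1=g1,
        gc2=g2,
        gc3=g3,
        gc_all=g_all,
        gc12=(g1 + g2) / 2.0,
        gc3s=gc3s(t),
        a3=thirds["A"],
        t3=thirds["T"],
        g3=thirds["G"],
        c3=thirds["C"],
        enc=enc(t),
        rscu=rscu(t),
    )


def species_summary(
    species_id: str,
    cds: list[CodingSequence],
    profiles: list[GeneCUBProfile] | None = None,
    enc_bias_cutoff: float = 35.0,
    per_gene_mean: bool = False,
) -> dict:
    """One summary row per species.

    GC metrics come from the concatenated codon counts of the gene set by
    default (``per_gene_mean=True`` switches to unweighted gene means);
    ENC_AVG is always the unweighted mean of per-gene ENC values, reported
    with the min/max genes and the genes at or below the strong-bias
    cutoff.
    """
    if profiles is None:
        profiles = [gene_profile(c) for c in cds]
    if per_gene_mean:
        g1 = _mean(p.gc1 for p in profiles)
        g2 = _mean(p.gc2 for p in profiles)
        g3 = _mean(p.gc3 for p in profiles)
        g_all = (g1 + g2 + g3) / 3.0
        g3s_val = _mean(p.gc3s for p in profiles if p.gc3s is not None)
        n_total = sum(p.n_codons for p in profiles)
    else:
        pooled = CodonCountTable()
        for c in cds:
            pooled = pooled + count_codons(c)
        g1, g2, g3, g_all = gc_by_position(pooled)
        g3s_val = gc3s(pooled)
        n_total = pooled.n_codons
    with_enc = [p for p in profiles if p.enc is not None]
    enc_avg = _mean(p.enc for p in with_enc) if with_enc else math.nan
    lo = min(with_enc, key=lambda p: (p.enc, p.gene)) if with_enc else None
    hi = max(with_enc, key=lambda p: (p.enc, p.gene)) if with_enc else None
    biased = sorted(
        (p for p in with_enc if p.enc <= enc_bias_cutoff), key=lambda p: p.enc
    )
    return {
        "species": species_id,
        "codon_no": n_total,
        "gc1": g1,
        "gc2": g2,
        "gc3": g3,
        "gc_all": g_all,
        "gc3s": g3s_val,
        "enc_avg": enc_avg,
        "enc_min": lo.enc if lo else math.nan,
        "enc_min_gene": lo.gene if lo else "",
        "enc_max": hi.enc if hi else math.nan,
        "enc_max_gene": hi.gene if hi else "",
        "genes_enc_le_cutoff": ",".join(p.gene for p in biased),
    }


def _mean(values) -> float:
    vals = list(values)
    return sum(vals) / len(vals)
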