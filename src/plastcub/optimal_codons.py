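"""Optimal-codon identification from ENC-ranked expression pools.

Genes are ranked by ENC; the lowest-ENC decile (strongest bias, taken as
the putative high-expression pool) and the highest-ENC decile form the two
pools.  RSCU is computed on the concatenated codon counts of each pool —
not on per-gene RSCU means — which stabilizes sparse families in small
pools.  A codon is called optimal when its high-pool RSCU exceeds 1 and
dRSCU = RSCU_high - RSCU_low is at least 0.08.  Met (ATG), Trp (TGG) and
stops are never candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .codon_usage import CodonCountTable, GeneCUBProfile, count_codons, rscu
from .genetics import AA_OF, FAMILIES, SINGLE_CODONS
from .io_plastome import CodingSequence

_DELTA_TOL = 1e-12


@dataclass
class OptimalCodonResult:
    high_pool: list[str]
    low_pool: list[str]
    rscu_high: dict[str, float | None]
    rscu_low: dict[str, float | None]
    delta: dict[str, float]
    optimal: set[str]


def build_pools(
    profiles: list[GeneCUBProfile], fraction: float = 0.10, invert: bool = False
) -> tuple[list[str], list[str]]:
    """Split genes into (high-expression, low-expression) pools by ENC.

    Pool size is ``max(1, floor(fraction * N))``; ties at the pool boundary
    break alphabetically on gene name for determinism.  ``invert=True``
    swaps the expression reading of the two ENC extremes.
    """
    ranked = sorted(
        (p for p in profiles if p.enc is not None), key=lambda p: (p.enc, p.gene)
    )
    n = len(ranked)
    m = max(1, math.floor(fraction * n))
    if n < 2 * m:
        raise ValueError(f"{n} genes cannot form two disjoint pools of {m}")
    low_enc = [p.gene for p in ranked[:m]]
    high_enc = [p.gene for p in ranked[-m:]]
    return (high_enc, low_enc) if invert else (low_enc, high_enc)


def _pool_rscu(pool: list[str], by_gene: dict[str, CodingSequence]):
    pooled = CodonCountTable()
    for gene in pool:
        pooled = pooled + count_codons(by_gene[gene])
    return rscu(pooled), pooled


def call_optimal(
    high_pool: list[str],
    low_pool: list[str],
    cds: list[CodingSequence],
    delta_min: float = 0.08,
) -> OptimalCodonResult:
    """Call optimal codons from the two pools' concatenated RSCU tables."""
    if not high_pool or not low_pool:
        raise ValueError("both pools must be non-empty")
    by_gene = {c.gene: c for c in cds}
    missing = [g for g in high_pool + low_pool if g not in by_gene]
    if missing:
        raise ValueError(f"pool genes missing from CDS set: {missing}")
    rscu_high, high_counts = _pool_rscu(high_pool, by_gene)
    rscu_low, low_counts = _pool_rscu(low_pool, by_gene)
    delta: dict[str, float] = {}
    optimal: set[str] = set()
    for aa, fam in FAMILIES.items():
        if len(fam) == 1:
            continue
        if any(rscu_high[c] is None for c in fam) or any(rscu_low[c] is None for c in fam):
            warnings.warn(f"family {aa} absent from a pool; its codons excluded")
            continue
        for c in fam:
            delta[c] = rscu_high[c] - rscu_low[c]
            if rscu_high[c] > 1.0 and delta[c] >= delta_min - _DELTA_TOL:
                optimal.add(c)
    return OptimalCodonResult(
        high_pool=list(high_pool),
        low_pool=list(low_pool),
        rscu_high=rscu_high,
        rscu_low=rscu_low,
        delta=delta,
        optimal=optimal,
    )


def find_optimal_codons(
    profiles: list[GeneCUBProfile],
    cds: list[CodingSequence],
    fraction: float = 0.10,
    delta_min: float = 0.08,
    invert: bool = False,
) -> OptimalCodonResult:
    """Convenience pipeline: pools then calling, for one species."""
    high, low = build_pools(profiles, fraction=fraction, invert=invert)
    return call_optimal(high, low, cds, delta_min=delta_min)


def shared_optimal(results: dict[str, OptimalCodonResult]) -> set[str]:
    """Codons optimal in every species (cross-species intersection)."""
    sets = [r.optimal for r in results.values()]
    if not sets:
        return set()
    return set.intersection(*sets)


def result_rows(res: OptimalCodonResult) -> list[dict]:
    """Tabular view: codon, amino acid, pool RSCUs, delta, ending base."""
    rows = []
    for codon in sorted(res.delta):
        rows.append(
            {
                "codon": codon,
                "amino_acid": AA_OF[codon],
                "rscu_high": res.rscu_high[codon],
                "rscu_low": res.rscu_low[codon],
                "delta_rscu": res.delta[codon],
                "ends_with": codon[2],
                "optimal": codon in res.optimal,
            }
        )
    return rows
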