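"""Sliding-window nucleotide diversity and pairwise dN/dS (NG86).

Nucleotide diversity pi is the mean pairwise proportion of differing
sites, computed in windows (default 600 bp stepped by 200 bp) over a
provided alignment; columns containing any gap or ambiguity are excluded
within each window (complete deletion per window, the common DnaSP
convention; pairwise deletion is available by flag).

Substitution rates use the Nei–Gojobori counting method: per-codon
synonymous site fractions from the nine single-base neighbours (changes
to stops count as nonsynonymous, so s + n == 3 for every sense codon),
pathway-averaged difference counts for codons differing at more than one
position (pathways through stop codons excluded), and the Jukes–Cantor
correction d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .genetics import AA_OF, BASES, STOP_CODONS, SENSE_CODONS
from .io_plastome import CodingSequence


@dataclass
class PiWindow:
    start: int
    midpoint: float
    n_sites_used: int
    pi: float | None


@dataclass
class PiProfile:
    windows: list[PiWindow]
    window: int = 600
    step: int = 200


@dataclass
class DnDsResult:
    gene: str
    species_pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None
    dN: float | None
    ratio: float | None
    selection: str  # purifying | neutral | positive | undefined
    codons_compared: int = 0


def _encode_alignment(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def sliding_window_pi(
    seqs: list[str],
    window: int = 600,
    step: int = 200,
    deletion: str = "complete",
) -> PiProfile:
    """Windowed nucleotide diversity over an alignment (list of equal-length
    sequences).  The final short window is reported at its true width; a
    window with no usable site gets pi = None."""
    if len(seqs) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    (L,) = lengths
    mat = _encode_alignment(seqs)
    is_base = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    nseq = len(seqs)
    npairs = nseq * (nseq - 1) // 2
    windows = []
    starts = range(0, max(L - window, 0) + 1, step) if L >= window else [0]
    # also cover a trailing short window when the last full window stops early
    starts = list(starts)
    if starts and starts[-1] + window < L:
        starts.append(starts[-1] + step)
    for w0 in starts:
        w1 = min(w0 + window, L)
        sub = mat[:, w0:w1]
        ok = is_base[:, w0:w1]
        if deletion == "complete":
            use = ok.all(axis=0)
            used = int(use.sum())
            if used == 0:
                windows.append(PiWindow(w0, (w0 + w1) / 2, 0, None))
                continue
            cols = sub[:, use]
            total = 0
            for i, j in itertools.combinations(range(nseq), 2):
                total += (cols[i] != cols[j]).sum() / used
            pi = total / npairs
            windows.append(PiWindow(w0, (w0 + w1) / 2, used, float(pi)))
        elif deletion == "pairwise":
            fracs = []
            used_min = None
            for i, j in itertools.combinations(range(nseq), 2):
                both = ok[i] & ok[j]
                m = int(both.sum())
                if m == 0:
                    continue
                fracs.append((sub[i, both] != sub[j, both]).sum() / m)
                used_min = m if used_min is None else min(used_min, m)
            if not fracs:
                windows.append(PiWindow(w0, (w0 + w1) / 2, 0, None))
            else:
                windows.append(
                    PiWindow(w0, (w0 + w1) / 2, used_min, float(sum(fracs) / len(fracs)))
                )
        else:
            raise ValueError(f"unknown deletion mode {deletion!r}")
    return PiProfile(windows=windows, window=window, step=step)


_SITES_CACHE: dict[str, tuple[float, float]] = {}


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the fraction of the three single-base changes that keep
    the amino acid; changes to stop codons are nonsynonymous.  s + n == 3.
    """
    if codon in _SITES_CACHE:
        return _SITES_CACHE[codon]
    if codon in STOP_CODONS or codon not in AA_OF:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = AA_OF[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if AA_OF.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    _SITES_CACHE[codon] = (s, 3.0 - s)
    return s, 3.0 - s


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons; equal-weight average over substitution orderings that
    avoid stop-codon intermediates (all orderings if none avoids one)."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in perm:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != b:
                blocked = True
                break
            if AA_OF.get(nxt) == AA_OF.get(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every ordering passes through a stop; fall back to all
        for perm in itertools.permutations(diff):
            cur = a
            sd = nd = 0
            for pos in perm:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if AA_OF.get(nxt) == AA_OF.get(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when p >= 3/4 (correction undefined)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


_NEUTRAL_TOL = 1e-9


def ng86_pair(
    cds_a: CodingSequence | str,
    cds_b: CodingSequence | str,
    gene: str = "",
    species_pair: tuple[str, str] = ("", ""),
) -> DnDsResult:
    """NG86 dN/dS between two equal-length in-frame sequences.

    Codon columns containing a gap, N or a stop in either sequence are
    skipped.  Site counts are averaged over the two sequences; the ratio is
    undefined when dS == 0 or either JC correction fails.
    """
    sa = cds_a.seq if isinstance(cds_a, CodingSequence) else cds_a
    sb = cds_b.seq if isinstance(cds_b, CodingSequence) else cds_b
    if isinstance(cds_a, CodingSequence):
        gene = gene or cds_a.gene
        species_pair = species_pair if species_pair != ("", "") else (
            cds_a.species_id,
            cds_b.species_id if isinstance(cds_b, CodingSequence) else "",
        )
    if len(sa) != len(sb):
        raise ValueError(f"{gene}: unequal CDS lengths {len(sa)} vs {len(sb)}")
    if len(sa) % 3:
        raise ValueError(f"{gene}: length {len(sa)} not a multiple of 3")
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(sa), 3):
        ca, cb = sa[i : i + 3], sb[i : i + 3]
        if ca not in AA_OF or cb not in AA_OF:
            continue  # masked, ambiguous or stop codon: skip the column
        compared += 1
        S_a += ng86_sites(ca)[0]
        S_b += ng86_sites(cb)[0]
        if ca != cb:
            sd, nd = _pathway_counts(ca, cb)
            Sd += sd
            Nd += nd
    S = (S_a + S_b) / 2.0
    N = 3.0 * compared - S
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS = jukes_cantor(pS) if pS is not None else None
    dN = jukes_cantor(pN) if pN is not None else None
    ratio = None
    if dS is not None and dN is not None and dS > 0:
        ratio = dN / dS
    if ratio is None:
        selection = "undefined"
    elif abs(ratio - 1.0) <= _NEUTRAL_TOL:
        selection = "neutral"
    elif ratio < 1.0:
        selection = "purifying"
    else:
        selection = "positive"
    return DnDsResult(
        gene=gene, species_pair=species_pair, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, dS=dS, dN=dN, ratio=ratio, selection=selection,
        codons_compared=compared,
    )


def load_gene_categories(path: str | Path | None = None) -> dict[str, str]:
    """Gene -> functional category (photosynthesis / self-replication /
    other); ships with an editable default table."""
    if path is None:
        src = resources.files("plastcub.data").joinpath("gene_categories.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, cat = line.split("\t")[:2]
        out[gene] = cat
    return out


def selection_summary(
    results: list[DnDsResult], categories: dict[str, str] | None = None
) -> tuple[list[dict], list[dict]]:
    """Aggregate pairwise results per gene and per functional category.

    Returns (per-gene rows, per-category rows).  The per-gene mean ratio is
    taken over the pairs where the ratio is defined; genes absent from the
    category table fall into 'other'.
    """
    if categories is None:
        categories = load_gene_categories()
    by_gene: dict[str, list[DnDsResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    gene_rows = []
    by_cat: dict[str, list[float]] = {}
    for gene in sorted(by_gene):
        rs = by_gene[gene]
        ratios = [r.ratio for r in rs if r.ratio is not None]
        mean_ratio = sum(ratios) / len(ratios) if ratios else None
        cat = categories.get(gene, "other")
        if mean_ratio is not None:
            by_cat.setdefault(cat, []).append(mean_ratio)
        gene_rows.append(
            {
                "gene": gene,
                "category": cat,
                "n_pairs": len(rs),
                "n_defined": len(ratios),
                "mean_dn": _mean_or_none([r.dN for r in rs]),
                "mean_ds": _mean_or_none([r.dS for r in rs]),
                "mean_ratio": mean_ratio,
                "selection": (
                    "undefined" if mean_ratio is None
                    else "purifying" if mean_ratio < 1
                    else "positive" if mean_ratio > 1
                    else "neutral"
                ),
            }
        )
    cat_rows = []
    for cat in sorted(by_cat):
        vals = sorted(by_cat[cat])
        cat_rows.append(
            {
                "category": cat,
                "n_genes": len(vals),
                "mean_ratio": sum(vals) / len(vals),
                "median_ratio": vals[len(vals) // 2]
                if len(vals) % 2
                else (vals[len(vals) // 2 - 1] + vals[len(vals) // 2]) / 2,
                "min_ratio": vals[0],
                "max_ratio": vals[-1],
            }
        )
    return gene_rows, cat_rows


def _mean_or_none(vals):
    vals = [v for v in vals if v is not None]
    return sum(vals) / len(vals) if vals else None
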