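"""Independent reference implementations used to cross-check the package.

Everything here derives amino acids through Biopython's translation of
table 11 and uses naive enumeration / regex scanning, deliberately sharing
no code with the package's own implementations.
"""

from __future__ import annotations

import itertools
import math
import re
from functools import lru_cache

from Bio.Seq import Seq

BASES = "ACGT"


@lru_cache(maxsize=None)
def aa_of(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


@lru_cache(maxsize=None)
def families_by_enumeration() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for a in BASES:
        for b in BASES:
            for c in BASES:
                codon = a + b + c
                aa = aa_of(codon)
                if aa != "*":
                    fams.setdefault(aa, []).append(codon)
    return fams


def enc_oracle(counts: dict[str, int]) -> float | None:
    """Wright's effective number of codons by direct family enumeration."""
    fams = families_by_enumeration()
    f_by_deg: dict[int, list[float]] = {}
    for aa, codons in fams.items():
        k = len(codons)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_by_deg.setdefault(k, []).append(f)
    mean = {k: sum(v) / len(v) for k, v in f_by_deg.items()}
    if 3 not in mean and 2 in mean and 4 in mean:
        mean[3] = (mean[2] + mean[4]) / 2
    if any(k not in mean for k in (2, 3, 4, 6)):
        return None
    weights = {2: 9, 3: 1, 4: 5, 6: 3}
    return min(2.0 + sum(weights[k] / mean[k] for k in (2, 3, 4, 6)), 61.0)


def gc_by_position_oracle(seq: str) -> tuple[float, float, float]:
    """Positional GC by a direct per-base scan of the raw sequence."""
    gc = [0, 0, 0]
    tot = [0, 0, 0]
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if aa_of(codon) == "*":
            continue
        for p in range(3):
            tot[p] += 1
            if codon[p] in "GC":
                gc[p] += 1
    return tuple(gc[p] / tot[p] for p in range(3))


def ssr_oracle(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """Regex brute-force enumeration of maximal perfect tandem repeats.

    Returns {(start, unit_len, motif, repeats)} with the same smallest-
    period and whole-unit semantics as the scanner under test.
    """
    found = set()
    for p, min_rep in thresholds.items():
        pat = re.compile(rf"(?=(([ACGT]{{{p}}})\2{{{min_rep - 1},}}))")
        for m in pat.finditer(seq):
            i = m.start()
            unit = m.group(2)
            # smallest-period rule
            if any(
                len(unit) % q == 0 and unit == unit[:q] * (len(unit) // q)
                for q in range(1, p)
            ):
                continue
            # left-maximality: the same-period match run must start here
            if (
                i > 0
                and seq[i - 1] in BASES
                and i - 1 + p < len(seq)
                and seq[i - 1] == seq[i - 1 + p]
            ):
                continue
            repeats = len(m.group(1)) // p
            found.add((i, p, unit, repeats))
    return found


def pi_oracle(seqs: list[str], window: int, step: int) -> list[float | None]:
    """All-pairs sliding-window nucleotide diversity, plain loops."""
    L = len(seqs[0])
    starts = list(range(0, max(L - window, 0) + 1, step)) or [0]
    if starts and starts[-1] + window < L:
        starts.append(starts[-1] + step)
    out = []
    for w0 in starts:
        w1 = min(w0 + window, L)
        cols = [
            c
            for c in range(w0, w1)
            if all(s[c] in BASES for s in seqs)
        ]
        if not cols:
            out.append(None)
            continue
        total, npairs = 0.0, 0
        for a, b in itertools.combinations(seqs, 2):
            diffs = sum(1 for c in cols if a[c] != b[c])
            total += diffs / len(cols)
            npairs += 1
        out.append(total / npairs)
    return out


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Synonymous site count from the nine single-base neighbours."""
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if aa_of(alt) != "*" and aa_of(alt) == aa_of(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def pathway_oracle(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons, enumerating all
    substitution orderings and dropping those through a stop."""
    diff = [i for i in range(3) if a[i] != b[i]]
    paths = []
    for perm in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in perm:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa_of(nxt) == "*" and nxt != b:
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        for perm in itertools.permutations(diff):
            cur, sd, nd = a, 0, 0
            for pos in perm:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if aa_of(nxt) == aa_of(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def slope_oracle(xs: list[float], ys: list[float]) -> float:
    """Closed-form OLS slope cov(x, y) / var(x)."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    var = sum((x - mx) ** 2 for x in xs)
    return cov / var
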