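"""Quadripartite plastome structure: IR detection, rotation, junctions.

The inverted-repeat pair is found as the longest pair of disjoint, exactly
reverse-complementary segments of the circular genome (default minimum
1 kb, which filters tRNA-scale inverted repeats).  Detection anchors
k-mers of the origin-doubled sequence against reverse-complement k-mers —
an inverted match lies on a constant anti-diagonal i + j — then extends
anchor runs base by base to maximality.  Exact matches only: plastid IRa
and IRb are identical by annotation convention, and a mismatch-tolerant
mode is deliberately not offered.

The four junctions are named as in plastome literature: JLB (LSC/IRb),
JSB (IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genetics import revcomp
from .io_plastome import GeneFeature, GenomeRecord

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals.  Each interval is (start, end) with
    0 <= start < genome length; end may exceed the genome length, meaning
    the interval wraps past the origin."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    @property
    def lengths(self) -> dict[str, int]:
        return {
            "lsc": self.lsc[1] - self.lsc[0],
            "irb": self.irb[1] - self.irb[0],
            "ssc": self.ssc[1] - self.ssc[0],
            "ira": self.ira[1] - self.ira[0],
        }

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    def region_seq(self, g: GenomeRecord, region: str) -> str:
        s, e = getattr(self, region)
        doubled = g.seq + g.seq
        return doubled[s:e]


@dataclass
class JunctionOverhang:
    gene: str
    junction: str
    side: str  # which single-copy/IR side the gene body sits on
    overhang: int  # signed bases the gene extends across the junction
    crosses: bool


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-bit packed k-mer codes (forward) and reverse-complement
    k-mer codes at every position; positions touching a non-ACGT base get
    a sentinel that never matches."""
    L = len(codes) - k + 1
    bad = codes > 3
    c = codes.astype(np.uint64)
    fwd = np.zeros(L, dtype=np.uint64)
    rc = np.zeros(L, dtype=np.uint64)
    invalid = np.zeros(L, dtype=bool)
    for t in range(k):
        fwd |= (c[t : t + L] & np.uint64(3)) << np.uint64(2 * (k - 1 - t))
        rc |= ((np.uint64(3) - (c[t : t + L] & np.uint64(3))) & np.uint64(3)) << np.uint64(2 * t)
        invalid |= bad[t : t + L]
    # sentinel: shift invalid forward codes out of the shared value space
    if invalid.any():
        fwd = fwd.copy()
        fwd[invalid] = np.uint64(0xFFFFFFFFFFFFFFFF)
        rc[invalid] = np.uint64(0xFFFFFFFFFFFFFFFE)
    return fwd, rc


def _anchor_pairs(fwd: np.ndarray, rc: np.ndarray, i_max: int):
    """All (i, j) with fwd[i] == rc[j] and i < i_max, vectorized."""
    order = np.argsort(rc, kind="stable")
    sorted_rc = rc[order]
    fi = fwd[:i_max]
    left = np.searchsorted(sorted_rc, fi, side="left")
    right = np.searchsorted(sorted_rc, fi, side="right")
    counts = right - left
    hit = np.flatnonzero(counts)
    if hit.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    reps = counts[hit]
    i_arr = np.repeat(hit, reps)
    total = int(reps.sum())
    # per-group offsets into the sorted order array
    starts = np.repeat(left[hit], reps)
    group_first = np.repeat(np.cumsum(reps) - reps, reps)
    offs = np.arange(total) - group_first
    j_arr = order[starts + offs]
    return i_arr.astype(np.int64), j_arr.astype(np.int64)


def _comp_code(x: int) -> int:
    return 3 - x if x <= 3 else 255


def detect_ir(g: GenomeRecord, min_ir: int = 1000) -> QuadripartitePartition | None:
    """Find the IR pair and partition the circular genome.

    Returns None when no disjoint, exactly reverse-complementary pair of
    length >= ``min_ir`` exists.  Among maximal candidate pairs the longest
    wins; ties break toward the smaller SSC, then deterministically by
    position.  The result is rotation-invariant up to coordinates.
    """
    n = g.length
    if n < 2 * min_ir:
        return None
    k = min(31, min_ir)
    seq2 = g.seq + g.seq
    codes = _BASE_CODE[np.frombuffer(seq2.encode("ascii"), dtype=np.uint8)]
    fwd, rc = _kmer_codes(codes, k)
    i_arr, j_arr = _anchor_pairs(fwd, rc, i_max=n)
    if i_arr.size == 0:
        return None
    d = i_arr + j_arr
    order = np.lexsort((i_arr, d))
    di, ii, jj = d[order], i_arr[order], j_arr[order]
    # split into runs of consecutive i on a constant anti-diagonal
    brk = np.flatnonzero((np.diff(di) != 0) | (np.diff(ii) != 1))
    run_starts = np.concatenate(([0], brk + 1))
    run_ends = np.concatenate((brk + 1, [len(di)]))
    candidates: dict[tuple, tuple] = {}
    two_n = 2 * n
    for rs, re_ in zip(run_starts, run_ends):
        run = re_ - rs
        L0 = run + k - 1
        if L0 < min_ir:
            continue
        i0 = int(ii[rs])
        j0 = int(jj[re_ - 1])  # smallest j in the run = reverse-interval start
        # extend to maximality (anchors can be truncated at the array edge)
        while (
            i0 > 0
            and j0 + L0 < two_n
            and codes[i0 - 1] <= 3
            and codes[j0 + L0] == 3 - codes[i0 - 1]
        ):
            i0 -= 1
            L0 += 1
        while (
            i0 + L0 < two_n
            and j0 > 0
            and codes[i0 + L0] <= 3
            and codes[j0 - 1] == 3 - codes[i0 + L0]
        ):
            j0 -= 1
            L0 += 1
        L0 = min(L0, n)
        a, b = i0 % n, j0 % n
        # the two arcs must be disjoint on the circle
        if (b - a) % n < L0 or (a - b) % n < L0:
            continue
        key = (min(a, b), max(a, b), L0)
        gap_ab = (b - (a + L0)) % n
        gap_ba = (a - (b + L0)) % n
        ssc_len = min(gap_ab, gap_ba)
        candidates[key] = (L0, ssc_len, a, b, gap_ab, gap_ba)
    if not candidates:
        return None
    L0, ssc_len, a, b, gap_ab, gap_ba = (
        int(v) for v in sorted(candidates.values(), key=lambda c: (-c[0], c[1], c[2]))[0]
    )
    if L0 < min_ir:
        return None
    # orient: LSC is the longer single-copy arc; IRb follows LSC
    if gap_ab >= gap_ba:
        lsc_start, lsc_len = (a + L0) % n, gap_ab
        irb_start, ira_start = b, a
        ssc_len_final = gap_ba
    else:
        lsc_start, lsc_len = (b + L0) % n, gap_ba
        irb_start, ira_start = a, b
        ssc_len_final = gap_ab
    ssc_start = (irb_start + L0) % n
    return QuadripartitePartition(
        lsc=(lsc_start, lsc_start + lsc_len),
        irb=(irb_start, irb_start + L0),
        ssc=(ssc_start, ssc_start + ssc_len_final),
        ira=(ira_start, ira_start + L0),
        genome_length=n,
    )


def canonical_partition(p: QuadripartitePartition) -> QuadripartitePartition:
    """The same partition in rotated coordinates (LSC starting at 0)."""
    L = p.lengths
    a = L["lsc"]
    b = a + L["irb"]
    c = b + L["ssc"]
    return QuadripartitePartition(
        lsc=(0, a), irb=(a, b), ssc=(b, c), ira=(c, p.genome_length),
        genome_length=p.genome_length,
    )


def canonical_rotation(g: GenomeRecord, p: QuadripartitePartition) -> GenomeRecord:
    """Rotate a circular genome so the LSC starts at coordinate 0 (order
    LSC-IRb-SSC-IRa) and remap all annotations.

    A feature that previously spanned the origin becomes a single
    contiguous interval; a feature that comes to span the new origin is
    split at it (segment order preserving the transcript).
    """
    n = g.length
    rot = p.lsc[0] % n
    if rot == 0:
        return g
    seq = g.seq[rot:] + g.seq[:rot]
    feats = []
    for f in g.features:
        segs: list[tuple[int, int]] = []
        for s, e in f.segments:
            ns = (s - rot) % n
            length = e - s
            if ns + length <= n:
                segs.append((ns, ns + length))
            else:  # crosses the new origin: split
                segs.append((ns, n))
                segs.append((0, length - (n - ns)))
        # merge segments made contiguous by the rotation
        merged = [segs[0]]
        for s, e in segs[1:]:
            if merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        feats.append(replace(f, segments=merged))
    return GenomeRecord(id=g.id, seq=seq, features=feats, topology=g.topology)


def _span_near(f: GeneFeature, n: int, junction: int) -> tuple[int, int]:
    """Feature span in coordinates re-centred on a junction so circular
    proximity is plain interval arithmetic."""
    half = n // 2
    lo, hi = None, None
    for s, e in f.segments:
        ms = ((s - junction + half) % n) - half + junction
        lo = ms if lo is None else min(lo, ms)
        hi = ms + (e - s) if hi is None else max(hi, ms + (e - s))
    return lo, hi


def junction_report(
    g: GenomeRecord, p: QuadripartitePartition, kinds: tuple[str, ...] = ("CDS", "tRNA", "rRNA")
) -> list[JunctionOverhang]:
    """Nearest/overlapping genes at each junction of a rotated genome.

    For each junction the nearest gene on each side is reported with a
    signed overhang: positive means the gene extends that many bases
    across the junction, negative that it stops short of it; zero that it
    abuts without crossing.
    """
    n = g.length
    cp = canonical_partition(p)
    coords = {
        "JLB": cp.lsc[1],
        "JSB": cp.irb[1],
        "JSA": cp.ssc[1],
        "JLA": n,
    }
    feats = [f for f in g.features if f.kind in kinds and not f.pseudo]
    out: list[JunctionOverhang] = []
    for name in JUNCTIONS:
        J = coords[name]
        spans = [(f.name, *_span_near(f, n, J)) for f in feats]
        left = [sp for sp in spans if sp[1] < J]
        right = [sp for sp in spans if sp[2] > J]
        if left:
            gname, s, e = max(left, key=lambda sp: sp[2])
            out.append(
                JunctionOverhang(
                    gene=gname, junction=name, side="left",
                    overhang=e - J, crosses=s < J < e,
                )
            )
        if right:
            gname, s, e = min(right, key=lambda sp: sp[1])
            out.append(
                JunctionOverhang(
                    gene=gname, junction=name, side="right",
                    overhang=J - s, crosses=s < J < e,
                )
            )
    return out


def partition_rows(species_id: str, p: QuadripartitePartition | None) -> dict:
    """One per-species structure row (genome size plus region lengths)."""
    if p is None:
        return {
            "species": species_id, "genome_size": None, "lsc": None,
            "ssc": None, "ir": None, "quadripartite": False,
        }
    L = p.lengths
    return {
        "species": species_id,
        "genome_size": p.genome_length,
        "lsc": L["lsc"],
        "ssc": L["ssc"],
        "ir": L["irb"],
        "quadripartite": True,
    }
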