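"""Perfect-microsatellite (SSR) detection with MISA-compatible semantics.

A locus is a maximal perfect tandem run of a 1-6 bp motif whose complete
repeat count meets the per-unit-length threshold (default 10 for
mononucleotides, 6 for dinucleotides, 5 for tri- through hexanucleotides).
Runs are reported at their smallest period only (a run of unit "ATAT" is a
dinucleotide locus, never a tetranucleotide one), motifs as-observed with
no reverse-complement canonicalization, and any non-ACGT base breaks a
run.  Circular genomes are scanned linearly after canonical rotation; an
origin-bridging run can be caught by scanning an origin-doubled copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SSRLocus:
    species_id: str
    motif: str
    unit_len: int
    repeats: int
    start: int
    end: int
    compound_id: int | None = None


def _smallest_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)


def find_ssrs(
    seq: str,
    thresholds: dict[int, int] | None = None,
    species_id: str = "",
) -> list[SSRLocus]:
    """Scan a sequence for maximal perfect tandem repeats.

    Returns loci sorted by (start, unit_len).  The locus interval covers
    complete repeat units only (``end - start == unit_len * repeats``).
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    loci: list[SSRLocus] = []
    for p, min_rep in sorted(thresholds.items()):
        if n <= p:
            continue
        m = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        if not m.any():
            continue
        # maximal runs of consecutive matches
        padded = np.concatenate(([False], m, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = stop - start  # number of matching offsets
            total = run + p  # length of the perfect region
            repeats = total // p
            if repeats < min_rep:
                continue
            motif = seq[start : start + p]
            if _smallest_period(motif) != p:
                continue  # reported at its smaller period instead
            loci.append(
                SSRLocus(
                    species_id=species_id,
                    motif=motif,
                    unit_len=p,
                    repeats=int(repeats),
                    start=int(start),
                    end=int(start) + int(repeats) * p,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def group_compound(loci: list[SSRLocus], max_interrupt: int = 100) -> list[SSRLocus]:
    """Assign compound ids: adjacent loci separated by at most
    ``max_interrupt`` bases share a group (MISA's compound convention)."""
    out = sorted(loci, key=lambda l: (l.start, l.unit_len))
    gid = -1
    prev_end = None
    for l in out:
        if prev_end is None or l.start - prev_end > max_interrupt:
            gid += 1
        l.compound_id = gid
        prev_end = max(prev_end, l.end) if prev_end is not None else l.end
    return out


def ssr_type_counts(loci: list[SSRLocus]) -> dict[int, int]:
    """Per-unit-length locus counts (the mono/di/tri/... summary)."""
    counts: dict[int, int] = {}
    for l in loci:
        counts[l.unit_len] = counts.get(l.unit_len, 0) + 1
    return counts


def loci_rows(loci: list[SSRLocus]) -> list[dict]:
    """MISA-style tabular view."""
    return [
        {
            "ID": l.species_id,
            "SSR nr.": i + 1,
            "type": f"p{l.unit_len}",
            "SSR": f"({l.motif}){l.repeats}",
            "size": l.end - l.start,
            "start": l.start,
            "end": l.end,
            "compound": l.compound_id if l.compound_id is not None else "",
        }
        for i, l in enumerate(loci)
    ]
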