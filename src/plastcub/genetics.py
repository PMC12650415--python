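"""Genetic-code constants shared across the package.

All coding-sequence work uses NCBI translation table 11 (bacterial,
archaeal and plant plastid), under which the stop codons are TAA, TAG and
TGA and the 61 sense codons partition into 20 synonymous families.  The
two- and six-fold families are kept whole (Leu, Ser and Arg are each one
family of six, the CodonW convention), which matters for the effective
number of codons.
"""

from __future__ import annotations

from Bio.Data import CodonTable

PLASTID_TABLE_ID = 11

_table = CodonTable.unambiguous_dna_by_id[PLASTID_TABLE_ID]

BASES = "ACGT"

#: All 64 codons in lexicographic order.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: The 61 sense codons under table 11.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: Sense codon -> one-letter amino acid.
AA_OF: dict[str, str] = {c: _table.forward_table[c] for c in SENSE_CODONS}

#: Amino acid -> sorted tuple of its synonymous codons.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in AA_OF.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if AA_OF[c] == aa)) for aa in FAMILIES
}

#: Codon -> size of its synonymous family (degeneracy, in {1, 2, 3, 4, 6}).
DEGENERACY: dict[str, int] = {c: len(FAMILIES[AA_OF[c]]) for c in SENSE_CODONS}

#: Codons that are their amino acid's only codon (ATG/Met, TGG/Trp).
SINGLE_CODONS: frozenset[str] = frozenset(c for c, k in DEGENERACY.items() if k == 1)

#: Four-fold degenerate families (third position fully free) -- the base
#: set for the strict parity-rule-2 construction.
FOURFOLD_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: fam for aa, fam in FAMILIES.items() if len(fam) == 4
}

START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Complement without reversal."""
    return seq.translate(_COMPLEMENT)


def translate(seq: str) -> str:
    """Translate an in-frame sequence; stops become ``*``, codons with
    ambiguity become ``X``."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            out.append("*")
        elif codon in AA_OF:
            out.append(AA_OF[codon])
        else:
            out.append("X")
    return "".join(out)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
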