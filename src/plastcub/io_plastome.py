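"""Reading and writing annotated plastomes and coding-sequence sets.

Internal coordinates are always 0-based, half-open; the GenBank boundary
(1-based, inclusive) is crossed only inside :func:`read_genbank` and
:func:`write_genbank`, which delegate the actual flat-file syntax to
Biopython.  Coding sequences are assembled from feature segments by this
module rather than by ``SeqFeature.extract`` so that the same segment
arithmetic serves junction analysis and genome rotation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genetics import revcomp

FEATURE_KINDS = ("CDS", "tRNA", "rRNA")


@dataclass
class GeneFeature:
    """One annotated gene on a plastome.

    ``segments`` are [start, end) intervals in assembly order: concatenating
    the genomic slices in this order and reverse-complementing the result
    when ``strand`` is '-' yields the transcribed sequence.  Trans-spliced
    features (plastid rps12) carry per-segment strands instead.
    """

    name: str
    kind: str
    strand: str
    segments: list[tuple[int, int]]
    trans_spliced: bool = False
    pseudo: bool = False
    segment_strands: list[str] | None = None

    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) over all segments."""
        return min(s for s, _ in self.segments), max(e for _, e in self.segments)


@dataclass
class GenomeRecord:
    """An annotated (usually circular) plastome."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    @property
    def length(self) -> int:
        return len(self.seq)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass
class CodingSequence:
    """An extracted, strand-resolved coding sequence."""

    species_id: str
    gene: str
    seq: str
    n_codons: int = 0
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if not self.n_codons:
            self.n_codons = len(self.seq) // 3


class PlastomeParseError(ValueError):
    pass


def _feature_name(feat: SeqFeature, index: int) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    name = f"{feat.type}_{index}"
    warnings.warn(f"feature {index} ({feat.type}) has no gene/product name; using {name}")
    return name


def _convert_feature(feat: SeqFeature, index: int, genome_len: int) -> GeneFeature:
    parts = feat.location.parts
    strands = ["-" if (p.strand or 1) < 0 else "+" for p in parts]
    trans = len(set(strands)) > 1 or "trans_splicing" in feat.qualifiers
    segs = [(int(p.start), int(p.end)) for p in parts]
    if trans:
        strand = strands[0]
        seg_strands = strands
    else:
        strand = strands[0]
        seg_strands = None
        if strand == "-":
            # Biopython lists parts in transcription order; store them so
            # that one whole-sequence reverse complement after genomic-order
            # concatenation reproduces the transcript.
            segs = segs[::-1]
    for s, e in segs:
        if not (0 <= s < e <= genome_len):
            raise PlastomeParseError(
                f"feature {index} segment [{s},{e}) outside genome of length {genome_len}"
            )
    return GeneFeature(
        name=_feature_name(feat, index),
        kind=feat.type,
        strand=strand,
        segments=segs,
        trans_spliced=trans,
        pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
        segment_strands=seg_strands,
    )


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read one or more GenBank flat-file records into :class:`GenomeRecord`.

    Coordinates are converted to 0-based half-open; ``join()`` /
    ``complement()`` location operators are resolved into ordered segments
    plus a strand.  A record that fails to parse raises
    :class:`PlastomeParseError` naming its LOCUS.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        try:
            seq = str(rec.seq).upper()
        except Exception as exc:  # pragma: no cover - biopython internals
            raise PlastomeParseError(f"record {rec.id}: no sequence ({exc})")
        if not seq:
            raise PlastomeParseError(f"record {rec.id}: empty sequence")
        topology = rec.annotations.get("topology", "linear")
        feats = []
        for i, feat in enumerate(rec.features):
            if feat.type not in FEATURE_KINDS:
                continue
            try:
                feats.append(_convert_feature(feat, i, len(seq)))
            except PlastomeParseError:
                raise
            except Exception as exc:
                raise PlastomeParseError(f"record {rec.id} feature {i}: {exc}")
        records.append(GenomeRecord(id=rec.id.split(".")[0], seq=seq, features=feats, topology=topology))
    if not records:
        raise PlastomeParseError(f"{path}: no GenBank records found")
    return records


def write_genbank(g: GenomeRecord, path: str | Path) -> None:
    """Serialize a GenomeRecord back to a GenBank flat file."""
    rec = SeqRecord(Seq(g.seq), id=g.id, name=g.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = g.topology
    for f in g.features:
        strand_of = (
            f.segment_strands
            if f.segment_strands is not None
            else [f.strand] * len(f.segments)
        )
        segs = f.segments if f.strand == "+" or f.trans_spliced else f.segments[::-1]
        strand_of = strand_of if f.strand == "+" or f.trans_spliced else strand_of[::-1]
        locs = [
            FeatureLocation(s, e, 1 if st == "+" else -1)
            for (s, e), st in zip(segs, strand_of)
        ]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.trans_spliced:
            quals["trans_splicing"] = [""]
        if f.pseudo:
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def assemble_feature_seq(g: GenomeRecord, f: GeneFeature) -> str:
    """Assemble the transcribed sequence of a feature from its segments."""
    for s, e in f.segments:
        if not (0 <= s < e <= g.length):
            raise PlastomeParseError(
                f"{g.id}:{f.name} segment [{s},{e}) exceeds genome bounds"
            )
    if f.trans_spliced and f.segment_strands is not None:
        parts = []
        for (s, e), st in zip(f.segments, f.segment_strands):
            piece = g.seq[s:e]
            parts.append(revcomp(piece) if st == "-" else piece)
        return "".join(parts)
    raw = "".join(g.seq[s:e] for s, e in f.segments)
    return revcomp(raw) if f.strand == "-" else raw


def extract_cds(g: GenomeRecord) -> list[CodingSequence]:
    """Extract all coding sequences from an annotated genome.

    IR-duplicated genes annotated with identical sequence are deduplicated
    by (name, sequence), keeping one copy; same-named copies with differing
    sequence are both kept, the later suffixed.  Trans-spliced features are
    assembled from their per-segment strands.  Sequences containing N are
    kept but flagged for downstream QC.
    """
    out: list[CodingSequence] = []
    seen: dict[tuple[str, str], bool] = {}
    name_counts: dict[str, int] = {}
    for f in g.cds_features():
        if f.pseudo:
            continue
        seq = assemble_feature_seq(g, f)
        key = (f.name, seq)
        if key in seen:
            continue  # identical IR copy
        seen[key] = True
        name_counts[f.name] = name_counts.get(f.name, 0) + 1
        name = f.name if name_counts[f.name] == 1 else f"{f.name}_{name_counts[f.name]}"
        flags = set()
        if "N" in seq:
            flags.add("ambiguous_base")
        if f.trans_spliced:
            flags.add("trans_spliced")
        out.append(CodingSequence(species_id=g.id, gene=name, seq=seq, flags=flags))
    return out


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a CDS multi-FASTA with ``>species|gene`` headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            species, gene = rec.id.split("|", 1)
        else:
            species, gene = "unknown", rec.id
        out.append(CodingSequence(species_id=species, gene=gene, seq=str(rec.seq).upper()))
    return out


def write_cds_fasta(cds: Iterable[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cds:
            fh.write(f">{c.species_id}|{c.gene}\n{c.seq}\n")


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write a homogeneous result table as TSV (header line, floats at four
    decimals, UTF-8).  An empty table produces a header-only file."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
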