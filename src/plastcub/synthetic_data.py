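"""Synthetic plastomes and coding sequences with known ground truth.

Every detector in the pipeline has a matching generator here: quadripartite
genomes with an exact planted LSC/IRb/SSC/IRa layout (IRa is always the
reverse complement of IRb), perfect SSR tracts whose flanks are
rejection-sampled so the planted run is maximal, junction-spanning genes
with chosen overhangs, coding sequences drawn from a target amino-acid
profile and per-family codon weights (hence controllable RSCU, ENC and
GC3), and CDS pairs separated by exact planted counts of synonymous and
nonsynonymous single-base changes at distinct codons.

Randomness derives from one integer master seed; each component draws from
a labelled substream so regenerating one piece never perturbs another.
Background (non-genic) sequence is i.i.d. with configurable GC, default
0.374 — the genus-wide plastome GC content the package's species summaries
are calibrated against.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .genetics import (
    AA_OF,
    BASES,
    FAMILIES,
    STOP_CODONS,
    revcomp,
)
from .io_plastome import CodingSequence, GeneFeature, GenomeRecord

DEFAULT_BACKGROUND_GC = 0.374


def _rng(seed: int, label: str) -> np.random.Generator:
    """Labelled substream of the master seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float = DEFAULT_BACKGROUND_GC) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    idx = rng.choice(4, size=n, p=probs)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# coding-sequence sampling

def uniform_rscu() -> dict[str, float]:
    """Equal within-family weights (target RSCU 1 everywhere)."""
    return {c: 1.0 for c in AA_OF}


def gc3_biased_rscu(gc3: float) -> dict[str, float]:
    """Within-family weights giving third-position GC probability ~ gc3."""
    return {c: (gc3 if c[2] in "GC" else 1.0 - gc3) for c in AA_OF}


def uniform_aa_profile() -> dict[str, float]:
    return {aa: 1.0 for aa in FAMILIES}


def sample_cds(
    aa_profile: dict[str, float],
    rscu_target: dict[str, float],
    n_codons: int,
    seed: int,
    species_id: str = "sim",
    gene: str = "gene",
) -> CodingSequence:
    """Sample an in-frame CDS: ATG + (n_codons - 2) codons drawn with amino
    acid ~ aa_profile and codon-within-family ~ rscu_target + one stop.
    Deterministic under the seed."""
    if n_codons < 2:
        raise ValueError("n_codons must be at least 2")
    rng = _rng(seed, f"cds:{species_id}:{gene}")
    aas = [aa for aa in sorted(aa_profile) if aa_profile[aa] > 0]
    if not aas:
        raise ValueError("empty amino-acid profile")
    aa_w = np.array([aa_profile[a] for a in aas], dtype=float)
    aa_w /= aa_w.sum()
    fam_choices: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in aas:
        fam = list(FAMILIES[aa])
        w = np.array([max(rscu_target.get(c, 0.0), 0.0) for c in fam], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"all-zero codon weights in family {aa}")
        fam_choices[aa] = (fam, w / w.sum())
    n_body = n_codons - 2
    picks = rng.choice(len(aas), size=n_body, p=aa_w)
    body = np.empty(n_body, dtype=object)
    for k, aa in enumerate(aas):
        at = np.flatnonzero(picks == k)
        if at.size == 0:
            continue
        fam, w = fam_choices[aa]
        body[at] = np.array(fam, dtype=object)[rng.choice(len(fam), size=at.size, p=w)]
    stop = sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))]
    return CodingSequence(
        species_id=species_id, gene=gene, seq="ATG" + "".join(body) + stop
    )


# ---------------------------------------------------------------------------
# plastome assembly

@dataclass
class PlantedGene:
    name: str
    start: int
    length: int | None = None
    strand: str = "+"
    kind: str = "CDS"
    cds_seq: str | None = None  # spliced verbatim ('+') or revcomped ('-')
    splice: bool = True  # False: annotation only, background content kept
    annotate_ir_copy: bool = True  # mirror the annotation when inside IRb

    def end(self) -> int:
        n = len(self.cds_seq) if self.cds_seq is not None else self.length
        if n is None:
            raise ValueError(f"gene {self.name}: neither cds_seq nor length given")
        return self.start + n


@dataclass
class PlantedSSR:
    motif: str
    repeats: int
    start: int

    def end(self) -> int:
        return self.start + len(self.motif) * self.repeats


@dataclass
class PlastomeConfig:
    lsc_len: int
    irb_len: int
    ssc_len: int
    background_gc: float = DEFAULT_BACKGROUND_GC
    genes: list[PlantedGene] = field(default_factory=list)
    ssrs: list[PlantedSSR] = field(default_factory=list)
    accession: str = "SYN000001"

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.irb_len + self.ssc_len


@dataclass
class TruthManifest:
    """Ground truth fully determining the emitted record given the seed."""

    seed: int
    accession: str
    planted_partition: dict[str, int]
    planted_ssrs: list[dict] = field(default_factory=list)
    planted_genes: list[dict] = field(default_factory=list)
    cds_params: dict = field(default_factory=dict)
    divergence_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _junction_overhangs(s: int, e: int, boundaries: dict[str, int]) -> dict[str, int]:
    """Bases by which [s, e) extends across each junction it crosses,
    measured on the side holding less of the gene."""
    return {name: min(e - j, j - s) for name, j in boundaries.items() if s < j < e}


def build_plastome(config: PlastomeConfig, seed: int) -> tuple[GenomeRecord, TruthManifest]:
    """Assemble an annotated synthetic quadripartite genome.

    Layout is LSC [0, A) + IRb [A, B) + SSC [B, C) + IRa [C, n) with
    IRa = revcomp(IRb) computed after all planted content is spliced in, so
    anything planted inside IRb is mirrored exactly.  Spliced intervals
    must be disjoint and lie in [0, C); overlapping plants raise an error
    naming both intervals.
    """
    A = config.lsc_len
    B = A + config.irb_len
    C = B + config.ssc_len
    n = config.genome_length
    rng = _rng(seed, "plastome:background")
    body = list(_random_bases(rng, C, gc=config.background_gc))

    spliced: list[tuple[int, int, str]] = []
    for g in config.genes:
        if g.splice and g.cds_seq is not None:
            spliced.append((g.start, g.end(), f"gene {g.name}"))
    for s in config.ssrs:
        spliced.append((s.start, s.end(), f"SSR ({s.motif}){s.repeats}@{s.start}"))
    spliced.sort()
    for (s1, e1, n1), (s2, e2, n2) in zip(spliced, spliced[1:]):
        if s2 < e1:
            raise ValueError(f"planted intervals overlap: {n1} [{s1},{e1}) and {n2} [{s2},{e2})")
    for s, e, name in spliced:
        if not (0 <= s < e <= C):
            raise ValueError(f"{name}: interval [{s},{e}) outside splice range [0,{C})")

    for g in config.genes:
        if g.splice and g.cds_seq is not None:
            piece = g.cds_seq if g.strand == "+" else revcomp(g.cds_seq)
            body[g.start : g.start + len(piece)] = piece

    ssr_truth = []
    for s in config.ssrs:
        run = s.motif * s.repeats
        body[s.start : s.start + len(run)] = run
        p = len(s.motif)
        # flanks must not extend the planted run (period-p maximality)
        if s.start > 0:
            forbidden = s.motif[p - 1]
            while body[s.start - 1] == forbidden:
                body[s.start - 1] = str(rng.choice(list("ACGT")))
        if s.end() < C:
            forbidden = s.motif[0]
            while body[s.end()] == forbidden:
                body[s.end()] = str(rng.choice(list("ACGT")))
        ssr_truth.append(
            {"motif": s.motif, "repeats": s.repeats, "start": s.start, "end": s.end()}
        )

    # keep the planted IR maximal: the bases flanking its two single-copy
    # junctions must not accidentally extend the reverse-complement match
    covered = [False] * C
    for s, e, _ in spliced:
        for i in range(s, e):
            covered[i] = True
    _COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos, partner in (((0, A - 1)), ((B, C - 1))):
        target, other = (pos, partner) if not covered[pos] else (partner, pos)
        if covered[target]:
            raise ValueError(
                f"planted content covers both bases flanking the IR junction at {pos}"
            )
        while body[target] == _COMP[body[other]]:
            body[target] = str(rng.choice(list("ACGT")))

    seq = "".join(body)
    seq = seq + revcomp(seq[A:B])
    boundaries = {"JLB": A, "JSB": B, "JSA": C, "JLA": n}

    features: list[GeneFeature] = []
    gene_truth = []
    for g in config.genes:
        e = g.end()
        features.append(
            GeneFeature(name=g.name, kind=g.kind, strand=g.strand, segments=[(g.start, e)])
        )
        gene_truth.append(
            {
                "name": g.name, "start": g.start, "end": e, "strand": g.strand,
                "kind": g.kind, "overhangs": _junction_overhangs(g.start, e, boundaries),
            }
        )
        if g.annotate_ir_copy and A <= g.start and e <= B:
            u = g.start - A
            ms = C + (B - A) - (u + (e - g.start))
            me = ms + (e - g.start)
            features.append(
                GeneFeature(
                    name=g.name, kind=g.kind,
                    strand="-" if g.strand == "+" else "+",
                    segments=[(ms, me)],
                )
            )
            gene_truth.append(
                {
                    "name": g.name, "start": ms, "end": me,
                    "strand": "-" if g.strand == "+" else "+",
                    "kind": g.kind, "overhangs": {}, "ir_copy": True,
                }
            )

    record = GenomeRecord(id=config.accession, seq=seq, features=features, topology="circular")
    manifest = TruthManifest(
        seed=seed,
        accession=config.accession,
        planted_partition={
            "lsc": config.lsc_len, "irb": config.irb_len,
            "ssc": config.ssc_len, "ira": config.irb_len,
            "genome": n,
        },
        planted_ssrs=ssr_truth,
        planted_genes=gene_truth,
    )
    return record, manifest


# ---------------------------------------------------------------------------
# divergence planting

def _neighbors(codon: str, synonymous: bool) -> list[str]:
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            same = AA_OF[alt] == AA_OF[codon]
            if same == synonymous:
                out.append(alt)
    return out


def mutate_cds(
    cds: CodingSequence,
    sd_target: int,
    nd_target: int,
    seed: int,
    species_id: str | None = None,
) -> CodingSequence:
    """Apply exactly ``sd_target`` synonymous and ``nd_target``
    nonsynonymous single-base changes at distinct codons (never the start
    codon, never creating a stop).  Raises when the sequence cannot host
    the requested counts."""
    rng = _rng(seed, f"mutate:{cds.species_id}:{cds.gene}")
    codons = [cds.seq[i : i + 3] for i in range(0, len(cds.seq), 3)]
    body_idx = [
        i for i in range(1, len(codons))
        if codons[i] in AA_OF and codons[i] not in STOP_CODONS
    ]
    order = list(rng.permutation(body_idx))
    syn_sites = [i for i in order if _neighbors(codons[i], synonymous=True)]
    non_sites = [i for i in order if _neighbors(codons[i], synonymous=False)]
    chosen_syn = syn_sites[:sd_target]
    if len(chosen_syn) < sd_target:
        raise ValueError(f"cannot place {sd_target} synonymous changes")
    remaining = [i for i in non_sites if i not in set(chosen_syn)]
    chosen_non = remaining[:nd_target]
    if len(chosen_non) < nd_target:
        raise ValueError(f"cannot place {nd_target} nonsynonymous changes")
    for i in chosen_syn:
        opts = _neighbors(codons[i], synonymous=True)
        codons[i] = opts[rng.integers(len(opts))]
    for i in chosen_non:
        opts = _neighbors(codons[i], synonymous=False)
        codons[i] = opts[rng.integers(len(opts))]
    return CodingSequence(
        species_id=species_id or f"{cds.species_id}_mut",
        gene=cds.gene,
        seq="".join(codons),
    )


# ---------------------------------------------------------------------------
# neutrality-regime simulation

def simulate_neutral_regime(
    n_genes: int = 52,
    slope_beta: float = 0.10,
    noise_sd: float = 0.01,
    seed: int = 0,
    gc3_range: tuple[float, float] = (0.15, 0.45),
    intercept: float | None = None,
    n_codons_range: tuple[int, int] = (150, 600),
) -> tuple[list[dict], list[CodingSequence]]:
    """Genes with a planted linear GC12-on-GC3 relation.

    gc3 is uniform on ``gc3_range``; gc12 = beta * gc3 + c + eps with
    gaussian eps.  Each gene is realized as a CDS mixing three codon
    families whose first-two-position GC contributions are 1 (Ala, GCN),
    1/2 (Val, GTN) and 0 (Lys, AAR), with family counts and third-position
    GC counts allocated deterministically by rounding, so the measured
    per-gene GC12 and GC3 reproduce their targets to within 1/(2n) — the
    planted scatter is degraded only by the gaussian eps, not by
    multinomial sampling noise.
    """
    if not 0.0 <= slope_beta <= 1.0:
        raise ValueError("slope_beta must be in [0, 1]")
    rng = _rng(seed, "neutral_regime")
    lo, hi = gc3_range
    if intercept is None:
        intercept = 0.43 - slope_beta * (lo + hi) / 2.0
    targets = []
    cds_list = []
    for g in range(n_genes):
        gc3 = float(rng.uniform(lo, hi))
        gc12 = float(
            np.clip(slope_beta * gc3 + intercept + rng.normal(0.0, noise_sd), 0.02, 0.95)
        )
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        n_body = n_codons - 1  # codons after the fixed ATG
        # positions 1-2: ATG contributes 0 GC of the 2*n_codons sites
        t12 = round(gc12 * 2 * n_codons)
        n_ala, n_val = t12 // 2, t12 % 2
        n_lys = n_body - n_ala - n_val
        if n_lys < 0:
            raise ValueError("gc12 target too high for the codon families used")
        fam = ["GC"] * n_ala + ["GT"] * n_val + ["AA"] * n_lys
        # third position: ATG's G counts toward the GC3 target
        t3 = max(round(gc3 * n_codons) - 1, 0)
        gc_third = [True] * t3 + [False] * (n_body - t3)
        order = rng.permutation(n_body)
        body = []
        for idx in range(n_body):
            stem = fam[idx]
            hot = gc_third[int(order[idx])]
            if stem == "AA":  # Lys: third base A or G only
                body.append(stem + ("G" if hot else "A"))
            else:
                body.append(
                    stem + (("G", "C")[idx % 2] if hot else ("A", "T")[idx % 2])
                )
        body = [body[int(i)] for i in rng.permutation(n_body)]
        gene = f"g{g:03d}"
        cds_list.append(
            CodingSequence(species_id="sim", gene=gene, seq="ATG" + "".join(body))
        )
        targets.append({"gene": gene, "gc3_target": gc3, "gc12_target": gc12,
                        "n_codons": n_codons})
    return targets, cds_list
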