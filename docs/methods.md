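# Methods

This note documents the models, conventions and numerical choices behind
`plastcub`, in the order the pipeline runs them.

## Coordinates, genetic code, CDS extraction

All internal coordinates are 0-based half-open; GenBank's 1-based
inclusive convention is converted only at the I/O boundary.  Translation
table 11 (plant plastid) is used throughout; its stop codons are TAA, TAG
and TGA, leaving 61 sense codons in 20 synonymous families.  Leucine,
serine and arginine are each treated as one six-fold family rather than
split into sub-boxes — the convention of the classic codon-usage tools —
which slightly lowers ENC relative to a split-box treatment.

Coding sequences are assembled from feature segments in annotation order,
reverse-complemented as a whole on the minus strand (trans-spliced
features are assembled per segment with per-segment strands).  Genes
duplicated between the two IRs are deduplicated by (name, sequence): the
two IR copies of a plastid gene are identical by construction, and
counting both would double-weight their codons.  Same-named copies whose
sequences differ are both kept, the later suffixed, so real divergence is
never silently collapsed.

## Quality control

Two inclusion regimes reflect the two downstream uses:

- **Codon-usage set (strict):** annotated length ≥ 300 bp (measured
  including the terminal stop; the stop is stripped only afterwards),
  length ≡ 0 mod 3, ATG start, TAA/TAG/TGA terminal stop, no internal
  stop, no ambiguity codes.  Short genes are excluded because preference
  indices computed on a few dozen codons are dominated by sampling noise.
- **Substitution-rate set (relaxed):** the start/stop/internal-stop rules
  only.  Ambiguous codons are masked (NNN) rather than rejecting the
  gene, because pairwise codon comparison can simply skip masked columns;
  no length floor applies.

Rejections are data (a QC report), never exceptions.  Shared gene sets
across species are alphabetically ordered intersections, derived from the
data rather than hard-coded.

## Codon-usage statistics

Positional GC (GC1/GC2/GC3/GC_all) is computed over all sense codons of
the stop-stripped CDS, matching EMBOSS `cusp` semantics.  GC3s restricts
the third position to families of degeneracy ≥ 2 (ATG and TGG excluded).
RSCU is count over family mean; single-codon families are undefined by
convention.

ENC follows Wright's estimator.  Per family with n ≥ 2 counted codons the
homozygosity is F̂ = (n Σp_i² − 1)/(n − 1); families with F̂ ≤ 0 are
dropped from their degeneracy-class mean rather than floored (they carry
no usable signal at small n); a missing three-fold class (isoleucine
absent) is imputed as the mean of the two- and four-fold class means; the
total 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ is capped at 61.  ENC is undefined
(None, flagged downstream) when a class mean cannot be formed at all —
preferable to inventing a number for genes that lack, say, any six-fold
family observation.

Per-species summaries compute GC metrics on the concatenated codon counts
of the shared gene set (one value per species); a `per_gene_mean` switch
gives unweighted gene means instead.  Mean ENC is always the unweighted
mean over genes, reported with the extreme genes and those at or below
the strong-bias cutoff (default 35).

## Mutation-versus-selection diagnostics

The neutrality plot regresses per-gene GC12 on GC3 by unweighted OLS
(slope, intercept, r², two-sided p, standard error); 100·slope is read as
the percentage of codon-usage variance attributable to mutation pressure.
The ENC-plot compares observed ENC with the mutation-only expectation
2 + GC3s + 29/(GC3s² + (1 − GC3s)²) and bins the relative deviation
(ENC_exp − ENC_obs)/ENC_exp into width-0.1, left-closed intervals placed
so that one bin is exactly [−0.05, 0.05).  Note the expectation curve is
*not* symmetric in GC3s ↔ 1 − GC3s: its homozygosity term is, but the
linear GC3s term adds up to one codon at the GC-rich end (f(0) = 31,
f(1) = 32).

The parity-rule-2 point is A3/(A3+T3) against G3/(G3+C3).  By default the
third-position base counts come from four-fold degenerate families only
(Sueoka's construction, where PR2 has its clean mutation-selection
interpretation); `base_set="all"` uses all sense-codon third positions.
The module reports quadrant occupancy and leaves interpretation to the
caller.

## Optimal codons

Genes with defined ENC are ranked ascending; pool size is
max(1, ⌊fraction·N⌋) with fraction 0.10, ties at the boundary broken by
gene name.  The lowest-ENC pool is taken as the putative high-expression
pool (strongest bias); an `invert` flag flips the reading, and the choice
is recorded in run metadata.  Pool RSCU is computed on the concatenated
counts of each pool — per-gene RSCU means would be dominated by sparse
families in five-gene pools.  A codon is optimal when RSCU_high > 1 and
ΔRSCU ≥ 0.08 (inclusive, with a 1e−12 float guard); stops, ATG and TGG
are never candidates, and families absent from a pool are excluded with a
warning.

## SSR scanning

A locus is a maximal perfect tandem run whose complete-repeat count meets
the per-unit-length threshold (1:10, 2:6, 3–6:5).  Runs are found by
shift-compare match arrays per period; a run of r matching offsets at
period p spans r + p bases and contains ⌊(r+p)/p⌋ complete units, and the
reported interval covers complete units only, so end − start =
unit × repeats.  Runs whose unit is itself periodic are reported at their
smallest period only; motifs are reported as observed (no
reverse-complement canonicalization — A- and T-homopolymers are distinct
loci, which any A/T-richness claim depends on); any non-ACGT base breaks
a run.  Compound grouping joins loci separated by ≤ 100 bases.  Scanning
is linear; for circular genomes the caller rotates canonically first, and
an origin-bridging run can be caught by scanning an origin-doubled copy.

## Quadripartite structure

The IR pair is the longest pair of disjoint, exactly reverse-complementary
arcs of the circle, minimum 1 kb by default (filtering tRNA-scale inverted
repeats; plastome IRs run 10–30 kb).  Detection packs 2-bit k-mer codes
(k = 31) of the origin-doubled sequence and of its reverse complement;
a true inverted match places anchor pairs (i, j) on a constant
anti-diagonal i + j, so sorted anchor runs yield candidates, which are
then extended base-by-base to maximality and checked for circular
disjointness.  Exact matching only: annotated plastid IRa/IRb are
identical, and a mismatch-tolerant mode is out of scope.  Ties prefer the
longer IR, then the smaller SSC, then position — deterministic under
rotation.  The longer single-copy arc is labelled LSC; IRb is the IR
following the LSC.

Canonical rotation shifts the origin to the LSC start and remaps
annotations (origin-spanning segments become contiguous; features landing
on the new origin are split).  Junction reports give, for each of
JLB/JSB/JSA/JLA, the nearest gene on each side with a signed overhang:
positive = extends that many bases across the junction, negative = stops
short.  Circular proximity is handled by re-centring coordinates on each
junction.

## Diversity and substitution rates

Sliding-window π (default 600/200 bp, after the standard plastome
window convention) excludes alignment columns containing any gap or
ambiguity within each window (complete deletion per window, the common
DnaSP-style default; pairwise deletion is available).  π is the mean over
sequence pairs of the per-pair difference fraction.  Windows advance by
the step while a full window fits; one trailing short window covers any
remainder at its true width.

dN/dS uses Nei–Gojobori (1986) counting.  Synonymous site fractions per
codon come from the nine single-base neighbours, with changes to stop
codons counted as nonsynonymous (so s + n = 3 for every sense codon);
site totals are averaged over the two sequences.  Codons differing at
k > 1 positions contribute difference counts averaged equally over the k!
substitution orderings, excluding orderings that pass through a stop
codon (if every ordering does, all are used and the pair is rare enough
to ignore).  Proportions are corrected by Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4.  The ratio is undefined
when dS = 0; classification is purifying/neutral/positive with a 1e−9
neutrality tolerance.  Orthologs must be supplied at equal length (the
pipeline performs no alignment); codon columns with gaps or masked bases
in either sequence are skipped.  Per-gene summaries average the ratio
over the defined species pairs — a mean over pairs, not a concatenated
estimate — and attach a functional category (photosynthesis /
self-replication / other) from an editable bundled table.

## Synthetic data

The generator emits fully specified inputs for every stage from one
integer master seed; per-component streams are derived by labelled
offsets, so regenerating one piece never shifts another.  Background
sequence is i.i.d. with GC 0.374, the genus-level plastome GC content the
package's summaries are calibrated against.

- `build_plastome` assembles LSC + IRb + SSC and appends
  IRa = revcomp(IRb) after all content is spliced, so IR-planted genes are
  mirrored exactly.  Planted SSR flanks are rejection-sampled so the
  planted run is maximal, and the two single-copy bases flanking the IR
  junctions are likewise resampled so the planted IR pair is the true
  maximal inverted repeat — without this, random flanks extend the match
  in roughly half of genomes and exact-recovery ground truth would be
  wrong.  Spliced intervals must be disjoint; conflicts raise an error
  naming both intervals.
- `sample_cds` draws amino acids from a target profile and codons within
  families from target weights (hence controllable RSCU/ENC/GC3),
  wrapping the body in ATG … stop.
- `mutate_cds` applies exactly the requested numbers of synonymous and
  nonsynonymous single-base changes at distinct codons, never touching
  the start codon and never creating stops, so NG86 counting must recover
  the planted (Sd, Nd) exactly.
- `simulate_neutral_regime` plants gc12 = β·gc3 + c + ε with gc3 uniform
  (default range 0.15–0.45, gene lengths 150–600 codons — the scale of a
  52-gene plastid set).  Genes are realized from three codon stems whose
  GC12 contributions are 1 (GCN), ½ (GTN) and 0 (AAR), with family and
  third-position-GC counts allocated by deterministic rounding rather
  than i.i.d. draws.  This matters: multinomial noise in realized GC3
  acts as measurement error in the regressor and attenuates the
  recovered slope (a classic errors-in-variables bias, ≈ −0.005 at these
  sizes); deterministic allocation reduces per-gene target error to
  ~1/(2n) and leaves ε as the only residual noise, so the generator
  actually emits the relation it promises.

What the generator does **not** emulate: indels and rearrangements,
phylogenetic correlation among species (species are sampled
independently), intron structure, compositional heterogeneity along the
genome, and imperfect (mismatched) repeats.  Passing tests therefore
validate the detectors and estimators on clean, known-truth inputs; they
do not certify behaviour on poorly annotated or structurally unusual
real plastomes.

## Scale of the shipped checks

The test suite validates each estimator against an independent oracle at
full property scale: 1,000 fuzzed codon-count tables (RSCU/ENC), 1,000
random 10-kb sequences against a regex enumerator (SSR), 1,000 fuzzed
quadripartite genomes with IRs of 1–30 kb (exact recovery), all 61 sense
codons against exhaustive neighbour enumeration (NG86 sites), toy
alignments against an all-pairs π oracle, and exact recovery of planted
substitution counts.  The slope calibration runs 60 seeded replicates of
the β = 0.10, 52-gene regime and requires the recovered slope to fall in
the diagnostic reading window [0.05, 0.15] at least 95% of the time with
no systematic bias; a per-fit two-standard-error check is exercised on a
single seed, because the event |β̂ − β| ≤ 2·SE has probability ≈ 0.95 by
construction for any unbiased estimator, making a ≥ 95%-of-seeds demand
on it a coin flip at any replicate count rather than a meaningful test.

`scripts/acceptance.py` runs the reference-scale recomputation (157 kb
genome, 15 × 52 cohort, 80-gene divergence, 15-sequence alignment) in a
few seconds; its cohort plants a per-gene bias gradient toward one
A/T-ending codon per family, shared across species, because without a
shared gradient the ENC-ranked pools differ only by sampling noise and
the cross-species optimal-codon intersection is empty — real plastomes
have the same strongly biased genes in every species.
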