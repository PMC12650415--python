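import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import enc_oracle, gc_by_position_oracle
from plastcub.codon_usage import (
    CodonCountTable,
    count_codons,
    enc,
    gc3s,
    gc_by_position,
    gene_profile,
    rscu,
    species_summary,
)
from plastcub.genetics import FAMILIES, SENSE_CODONS
from plastcub.io_plastome import CodingSequence
from plastcub.synthetic_data import sample_cds, uniform_aa_profile, uniform_rscu

codon_strategy = st.sampled_from(SENSE_CODONS)


def test_count_codons_basic():
    t = count_codons("ATGAAA")
    assert t.counts == {"ATG": 1, "AAA": 1}
    assert count_codons("").counts == {}
    with pytest.raises(ValueError):
        count_codons("ATGA")


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(codon_strategy, max_size=30), st.lists(codon_strategy, max_size=30))
def test_count_codons_additive_under_concatenation(c1, c2):
    s1, s2 = "".join(c1), "".join(c2)
    merged = (count_codons(s1) + count_codons(s2)).counts
    assert merged == count_codons(s1 + s2).counts


def test_gc_by_position_examples():
    assert gc_by_position(CodonCountTable({"ATG": 1, "AAA": 1})) == (0, 0, 0.5, 0.5 / 3)
    # a gene of identical G-T-G codons: GC at positions 1 and 3 only
    g1, g2, g3, gall = gc_by_position(CodonCountTable({"GTG": 7}))
    assert (g1, g2, g3) == (1, 0, 1) and gall == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        gc_by_position(CodonCountTable({}))


def test_gc_by_position_matches_per_base_scan():
    cds = sample_cds(uniform_aa_profile(), uniform_rscu(), 500, seed=3)
    body = cds.seq[:-3]
    g1, g2, g3, _ = gc_by_position(count_codons(body))
    assert (g1, g2, g3) == pytest.approx(gc_by_position_oracle(body))


def test_gc3s_rules():
    assert gc3s(CodonCountTable({"ATG": 3, "TGG": 2})) is None
    assert gc3s(CodonCountTable({"AAA": 5, "AAG": 5})) == 0.5
    # Met/Trp shift gc3 but never gc3s
    with_met = CodonCountTable({"AAA": 5, "AAG": 5, "ATG": 10, "TGG": 10})
    assert gc3s(with_met) == 0.5
    assert gc_by_position(with_met)[2] != 0.5
    # without single-codon families the two coincide
    no_met = CodonCountTable({"AAA": 3, "AAG": 9, "GGC": 2, "GGA": 1})
    assert gc3s(no_met) == pytest.approx(gc_by_position(no_met)[2])


def test_rscu_closed_form_and_uniform():
    vals = rscu(CodonCountTable({"AAA": 3, "AAG": 1}))
    assert vals["AAA"] == 1.5 and vals["AAG"] == 0.5
    uniform = rscu(CodonCountTable({c: 5 for c in SENSE_CODONS}))
    assert all(
        uniform[c] == pytest.approx(1.0)
        for c in SENSE_CODONS
        if uniform[c] is not None
    )
    assert uniform["ATG"] is None and uniform["TGG"] is None


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_rscu_family_sums_equal_family_sizes(seed):
    rng = np.random.default_rng(seed)
    t = CodonCountTable({c: int(rng.integers(0, 20)) for c in SENSE_CODONS})
    vals = rscu(t)
    for fam in FAMILIES.values():
        if len(fam) == 1:
            continue
        if sum(t.counts.get(c, 0) for c in fam) == 0:
            assert all(vals[c] is None for c in fam)
        else:
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam))


def test_enc_extremes():
    # one codon per family used heavily: every F = 1, ENC = 20 exactly
    one_each = CodonCountTable({fam[0]: 100 for fam in FAMILIES.values()})
    assert enc(one_each) == pytest.approx(20.0)
    # perfectly uniform heavy usage: capped at Wright's maximum
    assert enc(CodonCountTable({c: 10000 for c in SENSE_CODONS})) == 61.0


def test_enc_undefined_without_computable_classes():
    assert enc(CodonCountTable({"AAA": 100})) is None  # single family only
    assert enc(CodonCountTable({})) is None


def test_enc_concentration_never_increases():
    base = {c: 50 for c in SENSE_CODONS}
    e0 = enc(CodonCountTable(dict(base)))
    fam = FAMILIES["L"]
    shifted = dict(base)
    total = sum(shifted[c] for c in fam)
    for c in fam:
        shifted[c] = 0
    shifted[fam[0]] = total
    assert enc(CodonCountTable(shifted)) < e0


def test_enc_matches_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(200):
        lam = rng.uniform(0.2, 15)
        t = {c: int(rng.poisson(lam)) for c in SENSE_CODONS}
        ours = enc(CodonCountTable(t))
        ref = enc_oracle(t)
        if ref is None:
            assert ours is None
        else:
            assert ours == pytest.approx(ref, abs=1e-9)


def test_species_summary_single_gene_and_concatenation():
    # gene a spans the 2-, 4- and 6-fold classes so its ENC is defined
    a = CodingSequence("sp", "a", "AAAAAGGGGGGACTTCTA" * 20)  # 120 codons
    b = CodingSequence("sp", "b", "GGGGGC" * 10)  # 20 codons, Gly only
    pa, pb = gene_profile(a), gene_profile(b)
    solo = species_summary("sp", [a], [pa])
    assert solo["enc_avg"] == pa.enc and solo["codon_no"] == 120
    both = species_summary("sp", [a, b], [pa, pb])
    pooled = count_codons(a) + count_codons(b)
    assert both["gc3"] == pytest.approx(gc_by_position(pooled)[2])
    # concatenation weights by length, unlike the per-gene mean
    assert both["gc3"] != pytest.approx((pa.gc3 + pb.gc3) / 2)
    per_gene = species_summary("sp", [a, b], [pa, pb], per_gene_mean=True)
    assert per_gene["gc3"] == pytest.approx((pa.gc3 + pb.gc3) / 2)


def test_species_summary_flags_low_enc_genes():
    one_per_family = {
        c: (1.0 if c == FAMILIES[aa][0] else 0.0)
        for aa in FAMILIES
        for c in FAMILIES[aa]
    }
    strong = sample_cds(uniform_aa_profile(), one_per_family, 400, seed=5, gene="biased")
    weak = sample_cds(uniform_aa_profile(), uniform_rscu(), 400, seed=6, gene="even")
    from plastcub.cds_qc import filter_cds

    accepted, _ = filter_cds([strong, weak])
    profiles = [gene_profile(c) for c in accepted]
    row = species_summary("sp", accepted, profiles)
    assert row["enc_min_gene"] == "biased"
    assert row["enc_max_gene"] == "even"
    assert "biased" in row["genes_enc_le_cutoff"]
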