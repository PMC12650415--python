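import math

import numpy as np
import pytest

from _oracles import ng86_sites_oracle, pathway_oracle, pi_oracle
from plastcub.diversity_selection import (
    load_gene_categories,
    ng86_pair,
    ng86_sites,
    selection_summary,
    sliding_window_pi,
    DnDsResult,
)
from plastcub.genetics import SENSE_CODONS
from plastcub.io_plastome import CodingSequence
from plastcub.cds_qc import filter_cds
from plastcub.synthetic_data import mutate_cds, sample_cds, uniform_aa_profile, uniform_rscu


def test_pi_identical_sequences_zero():
    prof = sliding_window_pi(["ACGT" * 200, "ACGT" * 200])
    assert all(w.pi == 0.0 for w in prof.windows)


def test_pi_six_differences_in_600():
    a = "A" * 600
    b = "C" * 6 + "A" * 594
    (w,) = sliding_window_pi([a, b]).windows
    assert w.pi == pytest.approx(0.01)
    assert w.n_sites_used == 600


def test_pi_matches_allpairs_oracle_with_gaps():
    rng = np.random.default_rng(13)
    base = rng.choice(list("ACGT"), size=1500)
    seqs = []
    for _ in range(4):
        s = base.copy()
        mut = rng.random(1500) < 0.03
        s[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
        gap = rng.random(1500) < 0.01
        s[gap] = "-"
        seqs.append("".join(s))
    prof = sliding_window_pi(seqs)
    expected = pi_oracle(seqs, 600, 200)
    assert len(prof.windows) == len(expected)
    for w, e in zip(prof.windows, expected):
        if e is None:
            assert w.pi is None
        else:
            assert w.pi == pytest.approx(e, abs=1e-12)


def test_pi_invariant_to_sequence_order_and_gap_column():
    seqs = ["ACGTACGTAC" * 30, "ACGTACGTCC" * 30, "AGGTACGTAC" * 30]
    a = sliding_window_pi(seqs, window=300, step=100)
    b = sliding_window_pi(seqs[::-1], window=300, step=100)
    assert [w.pi for w in a.windows] == [w.pi for w in b.windows]
    short = [s[:250] for s in seqs]
    with_gap = [s + "-" for s in short]
    x = sliding_window_pi(short, window=300, step=100)
    y = sliding_window_pi(with_gap, window=300, step=100)
    assert [w.pi for w in x.windows] == [w.pi for w in y.windows]


def test_pi_trailing_short_window_true_width():
    prof = sliding_window_pi(["A" * 700, "A" * 700])
    assert prof.windows[-1].n_sites_used < 600


def test_pi_input_validation():
    with pytest.raises(ValueError):
        sliding_window_pi(["ACGT"])
    with pytest.raises(ValueError):
        sliding_window_pi(["ACGT", "ACG"])


def test_ng86_sites_reference_codons():
    s, n = ng86_sites("TTT")
    assert (s, n) == pytest.approx((1 / 3, 8 / 3))
    assert ng86_sites("ATG") == pytest.approx((0.0, 3.0))
    with pytest.raises(ValueError):
        ng86_sites("TAA")


def test_ng86_sites_exhaustive_against_enumeration():
    for codon in SENSE_CODONS:
        s, n = ng86_sites(codon)
        assert (s, n) == pytest.approx(ng86_sites_oracle(codon))
        assert s + n == pytest.approx(3.0)


def test_pair_identical_and_single_synonymous_change():
    a = "ATG" + "AAA" * 50 + "TTT" * 49
    same = ng86_pair(a, a)
    assert same.dN == 0 and same.dS == 0 and same.ratio is None
    assert same.selection == "undefined"
    b = a[:-3] + "TTC"  # one synonymous change in the last codon
    res = ng86_pair(a, b)
    assert (res.Sd, res.Nd) == (1.0, 0.0)
    assert res.dN == 0 and res.ratio == 0 and res.selection == "purifying"


def test_pair_two_position_codon_matches_pathway_oracle():
    res = ng86_pair("ATGTTT", "ATGGTA")
    sd, nd = pathway_oracle("TTT", "GTA")
    assert (sd, nd) == (0.5, 1.5)
    assert (res.Sd, res.Nd) == pytest.approx((sd, nd))


def test_pathways_through_stops_excluded():
    # TAT -> TGG: the route via TAG (stop) is dropped, leaving TAT->TGT->TGG
    res = ng86_pair("ATGTAT", "ATGTGG")
    assert (res.Sd, res.Nd) == pytest.approx(pathway_oracle("TAT", "TGG")) == (0.0, 2.0)


def test_site_counts_conserved():
    a = "ATG" + "GGG" * 40 + "TTT" * 40
    b = "ATG" + "GGA" * 40 + "TTT" * 40
    res = ng86_pair(a, b)
    assert res.S + res.N == pytest.approx(3 * res.codons_compared)


def test_masked_codons_skipped():
    a = "ATGAAATTT"
    b = "ATGNNNTTT"
    res = ng86_pair(a, b)
    assert res.codons_compared == 2


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        ng86_pair("ATGAAA", "ATGAAATTT")


def test_mutated_pairs_recover_planted_counts():
    base = sample_cds(uniform_aa_profile(), uniform_rscu(), 200, seed=21)
    (body,), _ = filter_cds([base])
    for sd, nd in [(0, 0), (5, 1), (2, 7), (10, 0)]:
        mut = mutate_cds(body, sd, nd, seed=sd * 100 + nd)
        res = ng86_pair(body, mut)
        assert (res.Sd, res.Nd) == (float(sd), float(nd))
        if sd and nd:
            assert res.selection in ("purifying", "positive", "neutral")


def test_selection_summary_aggregation():
    rs = [
        DnDsResult("psbI", ("a", s), 100, 200, 1, 1, 0.01, 0.005, 0.2, 0.04,
                   0.2, "purifying")
        for s in "bcd"
    ] + [
        DnDsResult("mystery", ("a", "b"), 100, 200, 1, 1, 0.01, 0.005, 0.1, 0.15,
                   1.5, "positive")
    ]
    gene_rows, cat_rows = selection_summary(rs)
    by_gene = {r["gene"]: r for r in gene_rows}
    assert by_gene["psbI"]["mean_ratio"] == pytest.approx(0.2)
    assert by_gene["psbI"]["selection"] == "purifying"
    assert by_gene["psbI"]["category"] == "photosynthesis"
    assert by_gene["mystery"]["category"] == "other"
    cats = {r["category"] for r in cat_rows}
    assert cats == {"photosynthesis", "other"}  # empty categories omitted


def test_bundled_category_table():
    cats = load_gene_categories()
    assert cats["rbcL"] == "photosynthesis"
    assert cats["rps18"] == "self-replication"
    assert cats["matK"] == "other"
    assert len(cats) >= 75
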