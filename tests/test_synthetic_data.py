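import json

import numpy as np
import pytest

from _oracles import aa_of
from plastcub.bias_drivers import neutral_plot
from plastcub.cds_qc import filter_cds
from plastcub.codon_usage import count_codons, enc, gene_profile, rscu
from plastcub.genetics import FAMILIES, revcomp
from plastcub.io_plastome import CodingSequence
from plastcub.synthetic_data import (
    PlantedGene,
    PlantedSSR,
    PlastomeConfig,
    build_plastome,
    mutate_cds,
    sample_cds,
    simulate_neutral_regime,
    uniform_aa_profile,
    uniform_rscu,
)


def test_sample_cds_deterministic_under_seed():
    a = sample_cds(uniform_aa_profile(), uniform_rscu(), 500, seed=1)
    b = sample_cds(uniform_aa_profile(), uniform_rscu(), 500, seed=1)
    c = sample_cds(uniform_aa_profile(), uniform_rscu(), 500, seed=2)
    assert a.seq == b.seq and a.seq != c.seq


def test_sample_cds_recovers_uniform_rscu_at_scale():
    """Sampling consistency: with every synonymous family given enough
    codons that the multinomial error is far below the 0.05 band (a 6-fold
    family needs tens of thousands of draws for a 4-sigma margin), the
    empirical RSCU of a uniform target is 1 +/- 0.05 everywhere."""
    by_family_size = {aa: float(len(fam)) for aa, fam in FAMILIES.items()}
    cds = sample_cds(by_family_size, uniform_rscu(), 400_000, seed=17)
    (body,), _ = filter_cds([cds], min_len=0)
    vals = rscu(count_codons(body))
    for codon, v in vals.items():
        if v is not None:
            assert abs(v - 1.0) <= 0.05, codon


def test_sample_cds_concentrated_weights_reach_minimum_enc():
    one_per_family = {
        c: (1.0 if c == FAMILIES[aa_of(c)][0] else 0.0)
        for fam in FAMILIES.values()
        for c in fam
    }
    cds = sample_cds(uniform_aa_profile(), one_per_family, 2000, seed=23)
    (body,), _ = filter_cds([cds], min_len=0)
    assert enc(count_codons(body)) == pytest.approx(20.0)


def test_sample_cds_rejects_degenerate_weights():
    bad = uniform_rscu()
    for c in FAMILIES["K"]:
        bad[c] = 0.0
    with pytest.raises(ValueError):
        sample_cds(uniform_aa_profile(), bad, 100, seed=1)


def test_build_plastome_deterministic(toy_plastome):
    record, manifest, config = toy_plastome
    again, manifest2 = build_plastome(config, seed=7)
    assert again.seq == record.seq
    assert manifest2.to_json() == manifest.to_json()
    json.loads(manifest.to_json())  # manifest is valid JSON


def test_build_plastome_structure_invariants(toy_plastome):
    record, manifest, config = toy_plastome
    n = config.genome_length
    assert record.length == n
    A, B = config.lsc_len, config.lsc_len + config.irb_len
    C = B + config.ssc_len
    assert record.seq[C:] == revcomp(record.seq[A:B])


def test_build_plastome_overlap_error_names_both():
    config = PlastomeConfig(
        lsc_len=5000, irb_len=1200, ssc_len=1500,
        ssrs=[PlantedSSR("A", 12, 100), PlantedSSR("AT", 7, 105)],
    )
    with pytest.raises(ValueError, match=r"\(A\)12.*\(AT\)7"):
        build_plastome(config, seed=1)


def test_build_plastome_records_junction_overhangs(toy_plastome):
    _, manifest, _ = toy_plastome
    truth = {g["name"]: g for g in manifest.planted_genes if g.get("overhangs")}
    assert truth["rps19"]["overhangs"] == {"JLB": 7}
    assert truth["ndhF"]["overhangs"] == {"JSB": 4}  # 4 bp across from the SSC side
    assert truth["ycf1"]["overhangs"] == {"JSA": 75}


def test_mutate_cds_zero_targets_identity():
    base = sample_cds(uniform_aa_profile(), uniform_rscu(), 100, seed=31)
    (body,), _ = filter_cds([base], min_len=0)
    assert mutate_cds(body, 0, 0, seed=1).seq == body.seq


def test_mutate_cds_changes_distinct_codons_single_base():
    base = sample_cds(uniform_aa_profile(), uniform_rscu(), 300, seed=33)
    (body,), _ = filter_cds([base])
    mut = mutate_cds(body, 6, 3, seed=2)
    syn = non = 0
    for i in range(0, len(body.seq), 3):
        ca, cb = body.seq[i : i + 3], mut.seq[i : i + 3]
        if ca == cb:
            continue
        assert sum(x != y for x, y in zip(ca, cb)) == 1  # distinct codons, one base
        assert aa_of(cb) != "*"
        if aa_of(ca) == aa_of(cb):
            syn += 1
        else:
            non += 1
    assert (syn, non) == (6, 3)


def test_mutate_cds_infeasible_targets_error():
    tiny = CodingSequence("s", "g", "ATGAAA")
    with pytest.raises(ValueError):
        mutate_cds(tiny, 50, 0, seed=1)


def test_neutral_regime_targets_exact_for_extreme_slopes():
    targets, _ = simulate_neutral_regime(n_genes=20, slope_beta=1.0, noise_sd=0.0, seed=3)
    xs = [t["gc3_target"] for t in targets]
    ys = [t["gc12_target"] for t in targets]
    fit = np.polyfit(xs, ys, 1)
    assert fit[0] == pytest.approx(1.0, abs=1e-9)
    targets0, _ = simulate_neutral_regime(n_genes=20, slope_beta=0.0, noise_sd=0.0, seed=3)
    assert len({round(t["gc12_target"], 12) for t in targets0}) == 1


def test_neutral_regime_realized_profiles_track_targets():
    targets, cds = simulate_neutral_regime(n_genes=10, slope_beta=0.10, seed=5)
    for t, c in zip(targets, cds):
        p = gene_profile(c)
        assert p.gc3 == pytest.approx(t["gc3_target"], abs=0.01)
        assert p.gc12 == pytest.approx(t["gc12_target"], abs=0.01)


def test_neutral_regime_slope_recovered_within_two_se():
    targets, cds = simulate_neutral_regime(n_genes=52, slope_beta=0.10, seed=0)
    res = neutral_plot([gene_profile(c) for c in cds])
    assert abs(res.slope - 0.10) <= 2 * res.stderr
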