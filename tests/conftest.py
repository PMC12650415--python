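import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plastcub.codon_usage import GeneCUBProfile
from plastcub.synthetic_data import (
    PlantedGene,
    PlantedSSR,
    PlastomeConfig,
    build_plastome,
    gc3_biased_rscu,
    sample_cds,
    uniform_aa_profile,
)


def make_profile(
    gene="g", species="sp", gc3=0.3, gc12=0.4, enc=45.0, gc3s=0.3,
    a3=10, t3=10, g3=10, c3=10, n_codons=100,
):
    """Minimal hand-set per-gene profile for diagnostics tests."""
    gc1 = gc2 = gc12
    return GeneCUBProfile(
        gene=gene, species_id=species, n_codons=n_codons,
        gc1=gc1, gc2=gc2, gc3=gc3, gc_all=(gc1 + gc2 + gc3) / 3,
        gc12=gc12, gc3s=gc3s, a3=a3, t3=t3, g3=g3, c3=c3,
        enc=enc, rscu={},
    )


@pytest.fixture(scope="session")
def toy_plastome():
    """Small annotated quadripartite genome with planted ground truth.

    Layout: LSC 8,000 + IRb 2,000 + SSC 3,000 + IRa 2,000 (15 kb total).
    Contains plus- and minus-strand CDS in the LSC, an IR-resident CDS
    (hence a mirrored IRa annotation), junction-spanning genes at JLB
    (+7), JSB (+4 from the SSC side) and JSA (+75), and three planted SSRs.
    """
    genes = [
        PlantedGene(
            name="psbA", start=100, strand="+",
            cds_seq=sample_cds(
                uniform_aa_profile(), gc3_biased_rscu(0.28), 120, 11,
                species_id="TOY", gene="psbA",
            ).seq,
        ),
        PlantedGene(
            name="rbcL", start=600, strand="-",
            cds_seq=sample_cds(
                uniform_aa_profile(), gc3_biased_rscu(0.28), 150, 11,
                species_id="TOY", gene="rbcL",
            ).seq,
        ),
        PlantedGene(
            name="ndhX", start=8200, strand="+",
            cds_seq=sample_cds(
                uniform_aa_profile(), gc3_biased_rscu(0.28), 80, 11,
                species_id="TOY", gene="ndhX",
            ).seq,
        ),
        # junction-spanning annotations (content-free)
        PlantedGene(name="rps19", start=7728, length=279, splice=False),  # JLB +7
        PlantedGene(name="ndhF", start=9996, length=300, splice=False),  # JSB, SSC side
        PlantedGene(name="ycf1", start=12200, length=875, splice=False),  # JSA +75
    ]
    ssrs = [
        PlantedSSR("A", 12, 3000),
        PlantedSSR("AT", 7, 3500),
        PlantedSSR("AGC", 5, 4000),
    ]
    config = PlastomeConfig(
        lsc_len=8000, irb_len=2000, ssc_len=3000,
        genes=genes, ssrs=ssrs, accession="TOY00001",
    )
    record, manifest = build_plastome(config, seed=7)
    return record, manifest, config
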