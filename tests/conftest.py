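import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from plastoflip import (GeneBlock, PlantedHairpin, PlantedSSR, SimConfig,
                        simulate_dataset)
from plastoflip.simulate import survey_like_config

EIGHT_TAXON_NEWICK = ("((((t1:0.01,t2:0.01):0.01,(t3:0.01,t4:0.01):0.01)"
                      ":0.01,(t5:0.01,t6:0.01):0.02):0.01,"
                      "(t7:0.01,t8:0.02):0.01);")


def eight_taxon_config(seed: int = 7, **overrides) -> SimConfig:
    """Small 8-taxon dataset: 3 flip loci, 2 monomorphic hairpins, 2 SSRs."""
    cfg = SimConfig(
        seed=seed,
        newick=EIGHT_TAXON_NEWICK,
        lsc_blocks=[GeneBlock("petA", 300, "gene"),
                    GeneBlock("sp1", 400),
                    GeneBlock("psbJ", 200, "gene"),
                    GeneBlock("sp2", 600),
                    GeneBlock("ndhA", 500, "gene",
                              exons=[(0, 200), (400, 500)])],
        ssc_blocks=[GeneBlock("ssc_sp", 500)],
        ir_len=400,
        planted_hairpins=[
            PlantedHairpin("sp1", 50, "TTTGATTTT", "TTCCT", ["t3"]),
            PlantedHairpin("sp1", 200, "TGGCTCGGCTA", "GGTGGGA",
                           [("t1", "t2", "t3", "t4")]),
            PlantedHairpin("sp2", 100, "ACATCTTCGG", "TATGC",
                           ["t7", ("t5", "t6")]),
            PlantedHairpin("sp2", 300, "AAGTTTTTTCGAACCATTTGAATCA",
                           "CTACT", []),
            PlantedHairpin("ssc_sp", 100, "GGATCAATACCAAACTTCTT",
                           "AATAGAAC", []),
        ],
        planted_ssrs=[PlantedSSR("sp2", 480, "A", 12),
                      PlantedSSR("sp1", 350, "AT", 6)],
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def eight_taxon_dataset():
    return simulate_dataset(eight_taxon_config())


@pytest.fixture(scope="session")
def survey_like_dataset():
    return simulate_dataset(survey_like_config(seed=1))
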