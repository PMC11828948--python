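import numpy as np
import pandas as pd
import pytest

from cas13gi.library import build_guide_set, build_library, random_spacer_table
from cas13gi.simulate import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def tiny_library():
    """2 genes x 3 guides + 4 NTCs, dual promoter: 100 constructs."""
    table = random_spacer_table(["GENEA", "GENEB"], 3, 4, seed=11)
    guides = build_guide_set(["GENEA", "GENEB"], 3, 4, table)
    return build_library(guides, "U6-g1-U6-g2")


@pytest.fixture(scope="session")
def tiny_screen():
    """Deterministic small simulated dual-promoter screen with its truth."""
    cfg = SimConfig(
        genes=("GENEA", "GENEB"), guides_per_gene=3, ntc_count=4,
        replicates=2, coverage=500, seed=17,
    )
    library, truth, screen = simulate_screen(cfg)
    return cfg, library, truth, screen


def toy_counts():
    """Hand-built 5-construct count matrix used by the tau oracle tests.

    Constructs: two gene-gene, one gene-NTC, two NTC-NTC; one baseline and
    two treated replicates.
    """
    counts = pd.DataFrame(
        {
            "t0": [100, 80, 120, 90, 110],
            "treated_r1": [50, 160, 130, 95, 100],
            "treated_r2": [60, 150, 125, 88, 115],
        },
        index=pd.Index(
            ["c_gg1", "c_gg2", "c_gn1", "c_nn1", "c_nn2"], name="construct_id"
        ),
    )
    samples = pd.DataFrame(
        {
            "condition": ["baseline", "treated", "treated"],
            "replicate": [0, 1, 2],
            "day": [0.0, 19.0, 19.0],
        },
        index=pd.Index(["t0", "treated_r1", "treated_r2"], name="sample_id"),
    )
    annotations = pd.DataFrame(
        {
            "pos1": ["A_g01", "A_g02", "A_g01", "NTC_01", "NTC_02"],
            "pos2": ["B_g01", "B_g02", "NTC_01", "NTC_02", "NTC_01"],
            "target1": ["GENEA", "GENEA", "GENEA", "NTC", "NTC"],
            "target2": ["GENEB", "GENEB", "NTC", "NTC", "NTC"],
            "pair_class": ["gene-gene", "gene-gene", "gene-NTC", "NTC-NTC", "NTC-NTC"],
        },
        index=counts.index,
    )
    return counts, samples, annotations


@pytest.fixture
def toy_screen():
    from cas13gi.containers import ScreenCounts

    counts, samples, annotations = toy_counts()
    return ScreenCounts(counts=counts, samples=samples, annotations=annotations)
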