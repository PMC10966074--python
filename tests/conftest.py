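import numpy as np
import pandas as pd
import pytest

from mws3 import synthdata


@pytest.fixture(scope="session")
def small_chip_rna():
    """Small RNA chip: 60 wells, deterministic seed."""
    params = synthdata.ChipParams(
        n_wells=60,
        bead_count_distribution={1: 0.3, 2: 0.4, 3: 0.3},
        nuclei_count_distribution={0: 0.2, 1: 0.5, 2: 0.3},
        molecules_per_nucleus=120,
    )
    return synthdata.simulate_chip(params, assay="rna", seed=7)


@pytest.fixture(scope="session")
def small_chip_atac():
    """Small ATAC chip with spike-ins."""
    params = synthdata.ChipParams(
        n_wells=60,
        bead_count_distribution={1: 0.3, 2: 0.4, 3: 0.3},
        nuclei_count_distribution={0: 0.2, 1: 0.5, 2: 0.3},
        molecules_per_nucleus=120,
        spikeins_per_well=4,
        accessible_sites=50_000,
    )
    return synthdata.simulate_chip(params, assay="atac", seed=7)


@pytest.fixture(scope="session")
def small_cnv_study():
    """Scaled-down CNV study (same clone structure, fewer cells)."""
    params = synthdata.CnvStudyParams.default(
        amplitude=0.3,
        noise_sd=0.1,
        n_genes=1000,
        group_cells={"tumor": 900, "adjacent": 600, "normal": 300},
    )
    return synthdata.simulate_cnv_study(params, seed=11)
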