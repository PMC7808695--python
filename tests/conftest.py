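import numpy as np
import pytest

from ancientkin.simulate import (ReadSpec, SimulationConfig, build_reference,
                                 simulate_panel, simulate_reads)


@pytest.fixture(scope="session")
def medium_dataset():
    """One shared mixed-sex dataset: panel, reads and truth (seeded)."""
    cfg = SimulationConfig(
        seed=101, n_snps=800, n_x_snps=200, n_source_pops=2,
        fst_per_pop=(0.1, 0.1), n_panel_per_pop=8,
        admixed_specs=[((0.5, 0.5), "adm1")],
        read_specs=[
            ReadSpec("male_hi", sex="XY", coverage_x=2.0,
                     endogenous_fraction=0.147, contamination_fraction=0.01,
                     ancestry=(0.6, 0.4)),
            ReadSpec("female_lo", sex="XX", coverage_x=0.5,
                     endogenous_fraction=0.02, contamination_fraction=0.0),
        ])
    panel, truth = simulate_panel(cfg)
    readsets, truth = simulate_reads(cfg, panel, truth)
    return cfg, panel, readsets, truth


@pytest.fixture(scope="session")
def reference_small():
    cfg = SimulationConfig(seed=7, n_snps=10, n_x_snps=0)
    return build_reference(cfg)
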