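import numpy as np
import pandas as pd
import pytest

from cojopred import simulate as sim


@pytest.fixture(scope="session")
def masked_scenario():
    return sim.preset_masked_pair(7)


@pytest.fixture(scope="session")
def small_masked_sim(masked_scenario):
    """Masked-pair scenario at reduced cohort sizes for fast unit tests."""
    from dataclasses import replace

    sc = replace(masked_scenario, n_gwas=20_000, n_ref=2_000, n_val=1_000)
    return sim.simulate(sc)


@pytest.fixture()
def toy_sumstats():
    """Five SNPs on two chromosomes with easy-to-reason-about values."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "chrom": ["1", "1", "1", "2", "2"],
            "bp": [100, 200, 300, 100, 200],
            "a1": ["A", "C", "G", "T", "A"],
            "a2": ["G", "T", "A", "C", "G"],
            "freq": [0.2, 0.4, 0.5, 0.3, 0.25],
            "b": [0.10, -0.05, 0.20, 0.0, 0.15],
            "se": [0.02, 0.03, 0.04, 0.05, 0.02],
            "p": [1e-6, 0.05, 1e-8, 0.9, 1e-4],
            "n": [1000.0, 1000.0, 900.5, 1200.0, 1000.0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
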