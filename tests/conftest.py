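import numpy as np
import pytest

import seedarray as sa


@pytest.fixture(scope="session")
def small_cfg() -> sa.SimulationConfig:
    return sa.SimulationConfig(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def truth_small(small_cfg):
    return sa.generate_truth(small_cfg)


@pytest.fixture(scope="session")
def summary_small(small_cfg, truth_small):
    comparisons, detection = sa.generate_affymetrix(truth_small, small_cfg)
    dyeswap = sa.generate_agilent(truth_small, small_cfg)
    return sa.summarize_genes(comparisons, detection, dyeswap, truth_small.gene_map())


@pytest.fixture(scope="session")
def calls_small(summary_small):
    return sa.build_call_table(summary_small)


@pytest.fixture(scope="session")
def noiseless_cfg() -> sa.SimulationConfig:
    return sa.SimulationConfig(
        n_genes=400, seed=7, noise_sd_affy=0.0, noise_sd_agilent=0.0, dye_bias_sd=0.0
    )


@pytest.fixture(scope="session")
def noiseless_summary(noiseless_cfg):
    truth = sa.generate_truth(noiseless_cfg)
    comparisons, detection = sa.generate_affymetrix(truth, noiseless_cfg)
    dyeswap = sa.generate_agilent(truth, noiseless_cfg)
    summary = sa.summarize_genes(comparisons, detection, dyeswap, truth.gene_map())
    return truth, summary


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
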