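import numpy as np
import pandas as pd
import pytest

from genekm import GeneConfig, SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(seed=7, n_replicates=30):
    genes = [
        GeneConfig("GXE1", n_snps=6, beta_gxe=0.5),
        GeneConfig("MAIN1", n_snps=6, beta_main=0.5),
        GeneConfig("NOISE1", n_snps=6),
    ]
    return SimConfig(n_samples=120, genes=genes, n_background_snps=80,
                     n_replicates=n_replicates, seed=seed)


@pytest.fixture(scope="session")
def small_rs():
    """A compact fixture shared across scan/CLI tests."""
    return simulate(small_config())


@pytest.fixture
def toy_covariates(rng):
    n = 40
    return pd.DataFrame(
        {
            "Sex": rng.binomial(1, 0.5, n),
            "Age": rng.normal(50, 10, n),
            "Smoking": rng.binomial(1, 0.4, n),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )


@pytest.fixture
def toy_genotypes(rng, toy_covariates):
    n = len(toy_covariates)
    G = rng.binomial(2, rng.uniform(0.1, 0.4, 5), size=(n, 5))
    return pd.DataFrame(G, index=toy_covariates.index,
                        columns=[f"snp{j}" for j in range(5)])
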