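import numpy as np
import pandas as pd
import pytest

import canepheno as cp


@pytest.fixture(scope="session")
def default_config():
    return cp.default_config()


@pytest.fixture(scope="session")
def small_design():
    """A reduced trial (faster than the full 135-genotype layout)."""
    return cp.TrialDesign(n_genotypes=40, environments=("2020", "2021"), n_replicates=3)


@pytest.fixture(scope="session")
def full_design():
    return cp.TrialDesign()


@pytest.fixture(scope="session")
def small_trial(default_config, small_design):
    return cp.simulate_trial(default_config, small_design, seed=11)


@pytest.fixture(scope="session")
def full_trial(default_config, full_design):
    """One study-scale trial: 135 hybrids + check, 2 years, 3 replicates."""
    return cp.simulate_trial(default_config, full_design, seed=7)


@pytest.fixture(scope="session")
def full_means(full_trial):
    return cp.genotype_means(full_trial)


def single_trait_config(mean=20.0, sd=np.sqrt(10.0), h2=0.8, **kwargs):
    """One-trait generator config (defaults: entry variance 10, h2 = 0.8)."""
    corr = pd.DataFrame([[1.0]], index=["SN"], columns=["SN"])
    return cp.SyntheticConfig(
        means={"SN": mean}, sds={"SN": float(sd)}, h2={"SN": h2},
        genotypic_corr=corr, **kwargs,
    )
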