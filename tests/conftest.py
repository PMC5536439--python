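import numpy as np
import pytest

from admixscan import simulate


@pytest.fixture(scope="session")
def small_panel():
    return simulate.make_aim_panel(60, seed=101, n_chrom=3)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """A 250-individual cohort with a planted interaction at rs000030."""
    acfg = simulate.AdmixtureConfig(seed=202)
    pcfg = simulate.PhenotypeConfig(
        n_individuals=250, causal_marker="rs000030", seed=303
    )
    return simulate.simulate_cohort(small_panel, acfg, pcfg)


@pytest.fixture(scope="session")
def admix_config():
    return simulate.AdmixtureConfig(seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
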