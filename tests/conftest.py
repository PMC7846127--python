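import numpy as np
import pytest

from structkin import SimConfig, simulate_admix, simulate_indep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def admix_bundle():
    """Small admixture dataset shared across estimator-vs-limit tests.

    n=100 individuals, m=20,000 loci: large enough that ratio-of-means
    estimators sit within a few percent of their infinite-loci limits,
    small enough to simulate in well under a second.
    """
    cfg = SimConfig(n=100, m=20_000)
    return simulate_admix(cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def indep_bundle():
    cfg = SimConfig(n=90, m=20_000)
    return simulate_indep(cfg, np.random.default_rng(11))
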