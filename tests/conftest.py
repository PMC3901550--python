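import numpy as np
import pytest

from sexsel import DFEParams, sample_bivariate_gamma


@pytest.fixture(scope="session")
def headline_sample():
    """The 10^6-locus DFE of the headline scenario (k=0.2, mean 0.02,
    r_st=0.75), shared across tests to keep the suite fast."""
    return sample_bivariate_gamma(
        DFEParams(shape=0.2, scale=0.1, r_st=0.75, n=10**6, seed=20130904)
    )


@pytest.fixture(scope="session")
def medium_sample():
    """2*10^5-locus sample of the same scenario for cheaper scans."""
    return sample_bivariate_gamma(
        DFEParams(shape=0.2, scale=0.1, r_st=0.75, n=200_000, seed=7)
    )
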