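import pytest

from cssd.prior import (
    DEFAULT_MIXTURE,
    HistoricalSummary,
    collective_prior,
)

# Five expert-opinion summaries on the log-odds-ratio scale used throughout
# the worked application, with their incommensurability weights.
APPLICATION_MEANS = [-0.26, -0.24, -0.37, -0.34, -0.32]
APPLICATION_VARIANCES = [0.25, 0.23, 0.22, 0.36, 0.26]
APPLICATION_WEIGHTS = [0.15, 0.20, 0.17, 0.13, 0.20]


@pytest.fixture(scope="session")
def application_sources():
    return [
        HistoricalSummary(mean=m, variance=v, w=w)
        for m, v, w in zip(APPLICATION_MEANS, APPLICATION_VARIANCES, APPLICATION_WEIGHTS)
    ]


@pytest.fixture(scope="session")
def application_prior(application_sources):
    return collective_prior(application_sources, DEFAULT_MIXTURE, s0=0.05)
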