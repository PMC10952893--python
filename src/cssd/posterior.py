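"""Conjugate posterior and marginal predictive machinery.

With a normal collective prior ``mu_Delta ~ N(mu0, S)`` and a realized
difference in sample means ``xbar_Delta`` carrying sampling variance
``(1/nA + 1/nB) * sigma0^2``, the posterior for mu_Delta is normal with
precision-additive variance.  The same update applies conditionally on
sigma0^2 when the variance is unknown; the design criteria integrate over its
prior at the criterion level rather than manipulating the marginal
normal-times-t posterior kernel directly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import math

from scipy import stats

from .prior import CollectivePrior

__all__ = [
    "NewDataSummary",
    "PosteriorState",
    "posterior_known_var",
    "marginal_predictive",
    "hpd_coverage",
    "hpd_interval",
]


@dataclass(frozen=True)
class NewDataSummary:
    """Realized difference in sample means and the per-arm sizes behind it."""

    xbar_delta: float
    nA: float
    nB: float

    def __post_init__(self) -> None:
        if not (self.nA > 0 and self.nB > 0):
            raise ValueError("group sizes must be positive")


@dataclass(frozen=True)
class PosteriorState:
    """Normal posterior N(eta, sigmaN2) for the treatment effect."""

    eta: float
    sigmaN2: float

    def to_dict(self) -> dict:
        return asdict(self)


def posterior_known_var(
    prior: CollectivePrior, data: NewDataSummary, sigma02: float
) -> PosteriorState:
    """Normal-normal conjugate update of the collective prior.

    Posterior precision is the sum of prior and data precisions; the posterior
    mean is the precision-weighted average of the prior mean and the observed
    ``xbar_delta``.
    """
    if not sigma02 > 0:
        raise ValueError("sigma02 must be > 0")
    sampling_var = (1.0 / data.nA + 1.0 / data.nB) * sigma02
    sigmaN2 = 1.0 / (1.0 / prior.variance + 1.0 / sampling_var)
    eta = sigmaN2 * (prior.mean / prior.variance + data.xbar_delta / sampling_var)
    return PosteriorState(eta=eta, sigmaN2=sigmaN2)


def marginal_predictive(
    prior: CollectivePrior, nA: float, nB: float, sigma02: float
):
    """Marginal law of the difference in sample means before the experiment.

    Integrating mu_Delta out of the sampling model gives
    ``Xbar_Delta ~ N(prior.mean, (1/nA + 1/nB)*sigma0^2 + S)``; this is the
    distribution the SSD criteria average the posterior over.
    """
    if not (nA > 0 and nB > 0 and sigma02 > 0):
        raise ValueError("nA, nB, sigma02 must all be > 0")
    var = (1.0 / nA + 1.0 / nB) * sigma02 + prior.variance
    return stats.norm(loc=prior.mean, scale=math.sqrt(var))


def hpd_coverage(post: PosteriorState, l0: float) -> float:
    """Coverage of the length-l0 HPD interval centered at the posterior mean.

    For the normal posterior this is ``2*Phi(l0/(2*sigmaN)) - 1``; the centered
    interval is the HPD (shortest) interval of its coverage by symmetry and
    unimodality.
    """
    if not l0 > 0:
        raise ValueError("l0 must be > 0")
    half = l0 / (2.0 * math.sqrt(post.sigmaN2))
    return 2.0 * stats.norm.cdf(half) - 1.0


def hpd_interval(post: PosteriorState, level: float) -> tuple[float, float]:
    """Central (= HPD, by symmetry) credible interval of the given coverage."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    half = stats.norm.ppf(0.5 + level / 2.0) * math.sqrt(post.sigmaN2)
    return post.eta - half, post.eta + half
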