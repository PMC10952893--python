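"""Synthesis of a collective normal prior from multiple pre-experimental sources.

Each source k reports a normal summary ``theta_k | y_k ~ N(m_k, s_k^2)`` of the
effect (e.g. a log-odds ratio or mean difference).  A commensurate predictive
distribution links the historical parameter to the new-experiment parameter
through an unknown precision ``nu_k`` carrying a two-component Gamma mixture
prior: one diffuse component that down-weights the source, one concentrated
component that borrows strongly.  Marginally the predictive prior for the
source is a two-component mixture of nonstandardized t distributions; it is
moment-matched by a normal with inflated variance

    xi_k^2 = s_k^2 + w_k * b01/(a01-1) + (1-w_k) * b02/(a02-1),

where ``w_k`` in [0, 1] is the prior probability that the source is
*incommensurate* with the new experiment.  The K moment-matched priors are then
combined with synthesis weights ``p_k \\propto exp(-w_k^2 / s0)`` into a single
normal "collective" prior with mean ``sum p_k m_k`` and variance
``sum p_k^2 xi_k^2``.

Gamma components use the shape--rate parameterization throughout: Gamma(a, b)
has mean a/b, and the matched predictive variance contribution is b/(a-1).
Reading the pairs as shape--scale silently rescales every variance downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HistoricalSummary",
    "PrecisionMixturePrior",
    "PredictiveComponent",
    "CollectivePrior",
    "DEFAULT_MIXTURE",
    "DEFAULT_S0",
    "t_mixture_pdf",
    "moment_match_variance",
    "synthesis_weights",
    "collective_prior",
    "hellinger_distance",
    "logodds_summary",
]


class InvalidPriorError(ValueError):
    """A prior hyperparameter violates its admissible range."""


@dataclass(frozen=True)
class HistoricalSummary:
    """Normal summary of one pre-experimental source.

    Parameters
    ----------
    mean
        Point estimate ``m_k`` on the effect scale.
    variance
        Its variance ``s_k^2`` (> 0).
    w
        Prior probability of incommensurability in [0, 1].  ``w=0`` trusts the
        source fully; ``w=1`` down-weights it maximally.
    """

    mean: float
    variance: float
    w: float = 0.0

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise InvalidPriorError(f"variance must be > 0, got {self.variance}")
        if not 0.0 <= self.w <= 1.0:
            raise InvalidPriorError(f"w must lie in [0, 1], got {self.w}")


@dataclass(frozen=True)
class PrecisionMixturePrior:
    """Two-component Gamma mixture prior (shape--rate) for a commensurate precision.

    Component 1 ``Gamma(a01, b01)`` concentrates on small precisions and
    down-weights the source; component 2 ``Gamma(a02, b02)`` covers large
    precisions and borrows strongly.  The convention is enforced through the
    matched predictive variances: ``b01/(a01-1) > b02/(a02-1)``.
    """

    a01: float
    b01: float
    a02: float
    b02: float

    def __post_init__(self) -> None:
        for name in ("a01", "b01", "a02", "b02"):
            if not getattr(self, name) > 0:
                raise InvalidPriorError(f"{name} must be > 0, got {getattr(self, name)}")

    def component_variances(self) -> tuple[float, float]:
        """Matched predictive variances (b01/(a01-1), b02/(a02-1)); needs shapes > 1."""
        if self.a01 <= 1 or self.a02 <= 1:
            raise InvalidPriorError(
                "moment matching requires a01 > 1 and a02 > 1; the t components "
                f"have no finite variance at a01={self.a01}, a02={self.a02}"
            )
        return self.b01 / (self.a01 - 1.0), self.b02 / (self.a02 - 1.0)


#: Mixture used in all worked examples: diffuse Gamma(2, 2) for down-weighting,
#: concentrated Gamma(18, 3) for strong borrowing.
DEFAULT_MIXTURE = PrecisionMixturePrior(2.0, 2.0, 18.0, 3.0)

#: Default concentration of the synthesis-weight map p_k = exp(-w_k^2/s0).
DEFAULT_S0 = 0.05


@dataclass(frozen=True)
class PredictiveComponent:
    """One source's moment-matched contribution to the collective prior."""

    lam: float  # predictive mean, equals the source mean m_k
    xi2: float  # inflated predictive variance s_k^2 + mixture term
    p: float  # synthesis weight


@dataclass(frozen=True)
class CollectivePrior:
    """Normal prior ``mu_Delta ~ N(mean, variance)`` synthesized from K sources."""

    mean: float
    variance: float
    components: tuple[PredictiveComponent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise InvalidPriorError(f"variance must be > 0, got {self.variance}")


def t_mixture_pdf(
    x: float | np.ndarray,
    theta_k: float,
    mix: PrecisionMixturePrior,
    w: float,
) -> float | np.ndarray:
    """Marginal predictive density of a source effect before moment matching.

    Integrating the Gamma-mixture precision out of the conditional normal gives
    a two-component mixture of nonstandardized t densities, both located at
    ``theta_k``, with degrees of freedom ``2*a0j`` and scales ``sqrt(b0j/a0j)``.
    """
    if not 0.0 <= w <= 1.0:
        raise InvalidPriorError(f"w must lie in [0, 1], got {w}")
    comp1 = stats.t.pdf(x, df=2 * mix.a01, loc=theta_k, scale=math.sqrt(mix.b01 / mix.a01))
    comp2 = stats.t.pdf(x, df=2 * mix.a02, loc=theta_k, scale=math.sqrt(mix.b02 / mix.a02))
    return w * comp1 + (1.0 - w) * comp2


def moment_match_variance(mix: PrecisionMixturePrior, w: float) -> float:
    """Variance of the normal approximation to the t-mixture predictive density.

    Equals the exact second central moment of the mixture about ``theta_k``:
    ``w*b01/(a01-1) + (1-w)*b02/(a02-1)``.  Requires both shapes > 1 (finite
    second moments).
    """
    if not 0.0 <= w <= 1.0:
        raise InvalidPriorError(f"w must lie in [0, 1], got {w}")
    v1, v2 = mix.component_variances()
    return w * v1 + (1.0 - w) * v2


def synthesis_weights(w_vec, s0: float) -> np.ndarray:
    """Map incommensurability weights to normalized synthesis weights.

    ``p_k = exp(-w_k^2/s0) / sum_j exp(-w_j^2/s0)``.  Larger incommensurability
    yields a smaller share of the collective prior.  As ``s0 -> inf`` the
    weights flatten to 1/K; as ``s0 -> 0+`` all mass concentrates on the
    smallest ``w_k`` (ties split equally).
    """
    if not s0 > 0:
        raise InvalidPriorError(f"s0 must be > 0, got {s0}")
    w = np.asarray(w_vec, dtype=float)
    if w.size < 1:
        raise InvalidPriorError("need at least one source")
    if np.any(w < 0) or np.any(w > 1):
        raise InvalidPriorError("all w_k must lie in [0, 1]")
    # subtract the max exponent so the s0 -> 0+ limit stays finite
    e = -(w**2) / s0
    e -= e.max()
    p = np.exp(e)
    return p / p.sum()


def collective_prior(
    summaries: list[HistoricalSummary],
    mix: PrecisionMixturePrior = DEFAULT_MIXTURE,
    s0: float = DEFAULT_S0,
) -> CollectivePrior:
    """Synthesize the collective normal prior for the new-experiment effect.

    Each source contributes a moment-matched normal ``N(m_k, xi_k^2)``; the
    synthesis weights come from the sources' ``w`` fields through
    :func:`synthesis_weights`.
    """
    if not summaries:
        raise InvalidPriorError("need at least one historical summary")
    w = np.array([h.w for h in summaries])
    p = synthesis_weights(w, s0)
    comps = tuple(
        PredictiveComponent(
            lam=h.mean,
            xi2=h.variance + moment_match_variance(mix, h.w),
            p=float(pk),
        )
        for h, pk in zip(summaries, p)
    )
    mean = sum(c.p * c.lam for c in comps)
    variance = sum(c.p**2 * c.xi2 for c in comps)
    return CollectivePrior(mean=mean, variance=variance, components=comps)


def hellinger_distance(mean1: float, var1: float, mean2: float, var2: float) -> float:
    """Hellinger distance between two univariate normal distributions.

    Closed form: ``H^2 = 1 - sqrt(2*s1*s2/(s1^2+s2^2)) *
    exp(-(m1-m2)^2 / (4*(s1^2+s2^2)))`` with ``s_i`` the standard deviations.
    Useful for quantifying pairwise (in)commensurability between source
    summaries when eliciting the ``w_k``; the mapping from distance to weight
    is left to the analyst.
    """
    if not (var1 > 0 and var2 > 0):
        raise InvalidPriorError("variances must be > 0")
    s1, s2 = math.sqrt(var1), math.sqrt(var2)
    h2 = 1.0 - math.sqrt(2.0 * s1 * s2 / (var1 + var2)) * math.exp(
        -((mean1 - mean2) ** 2) / (4.0 * (var1 + var2))
    )
    # clip tiny negative round-off before the root
    return math.sqrt(max(h2, 0.0))


def logodds_summary(a: float, b: float, c: float, d: float) -> HistoricalSummary:
    """Normal summary of a log-odds ratio from a 2x2 table.

    ``a``/``b`` are events/non-events in arm A, ``c``/``d`` in arm B.  Mean is
    ``log(ad/bc)``; variance is the Woolf estimate ``1/a+1/b+1/c+1/d``.  Zero
    cells raise: whether and how to apply a continuity correction is a modeling
    decision made upstream, never silently here.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "all four cell counts must be positive; apply a continuity "
            "correction upstream before summarizing a table with zero cells"
        )
    mean = math.log((a * d) / (b * c))
    variance = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return HistoricalSummary(mean=mean, variance=variance, w=0.0)
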