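"""Sample-size solvers for the average coverage, length, and variance criteria.

All three criteria bound the harmonic-mean information level
``Q = nA*nB/(nA+nB)`` from below:

* ACC — the fixed-length ``l0`` HPD interval, centered at the posterior mean,
  must have average posterior coverage at least ``1 - alpha``:
  ``Q >= (4*z_{alpha/2}^2/l0^2 - 1/S) * E[sigma0^2]``.
* APVC — the average posterior variance must not exceed ``eps0``:
  ``Q >= (1/eps0 - 1/S) * E[sigma0^2]``.
* ALC — the average length of the ``(1-alpha0)`` HPD interval must not exceed
  ``l``: ``2*z_{alpha0/2} * E[sigma_N] <= l``.  With a known sampling variance
  the interval length is deterministic and ALC coincides with ACC; with the
  inverse-gamma variance prior the expectation has no closed form and the
  smallest integer total is found by search.

A negative right-hand side means the collective prior alone already satisfies
the target, so the required information level clamps at zero.

The comparator strategies transform the prior before solving: forcing every
``w_k = 0`` (no robustification, full trust), ``w_k = 1`` (no borrowing for
the effect; pre-experimental data may still inform the variance prior), using
only the single most informative source, or the optimal benchmark that equates
sigma0^2 to the collective-prior variance.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, asdict

from scipy import stats

from .prior import (
    CollectivePrior,
    DEFAULT_MIXTURE,
    DEFAULT_S0,
    HistoricalSummary,
    PrecisionMixturePrior,
    collective_prior,
)
from .variance import VarianceModel, expected_sigma02, expected_sigmaN, known_variance

__all__ = [
    "CriterionSpec",
    "DesignResult",
    "STRATEGIES",
    "z_quantile",
    "required_Q_acc",
    "required_Q_apvc",
    "alc_expected_length",
    "solve_alc",
    "allocate",
    "apply_strategy",
    "design",
]

STRATEGIES = ("robust", "no_robustification", "no_borrowing", "single_source", "optimal")


@dataclass(frozen=True)
class CriterionSpec:
    """One design criterion: ACC{l0, alpha}, ALC{l, alpha0}, or APVC{eps0}."""

    kind: str
    l0: float | None = None
    alpha: float | None = None
    l: float | None = None
    alpha0: float | None = None
    eps0: float | None = None

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        object.__setattr__(self, "kind", kind)
        if kind == "ACC":
            if self.l0 is None or not self.l0 > 0:
                raise ValueError("ACC requires l0 > 0")
            if self.alpha is None or not 0 < self.alpha < 1:
                raise ValueError("ACC requires alpha in (0, 1)")
        elif kind == "ALC":
            if self.l is None or not self.l > 0:
                raise ValueError("ALC requires l > 0")
            if self.alpha0 is None or not 0 < self.alpha0 < 1:
                raise ValueError("ALC requires alpha0 in (0, 1)")
        elif kind == "APVC":
            if self.eps0 is None or not self.eps0 > 0:
                raise ValueError("APVC requires eps0 > 0")
        else:
            raise ValueError(f"unknown criterion kind {self.kind!r}")


@dataclass(frozen=True)
class DesignResult:
    """Solved design: information level, allocation, and attained criterion value."""

    Q: float
    nA: float
    nB: float
    total: float
    attained: float
    criterion: str
    strategy: str = "robust"

    def to_dict(self) -> dict:
        return asdict(self)


def z_quantile(q: float) -> float:
    """Upper q-th standard-normal quantile, Phi^{-1}(1 - q)."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    return float(stats.norm.ppf(1.0 - q))


def required_Q_acc(S: float, l0: float, alpha: float, model: VarianceModel) -> float:
    """Information level meeting the average coverage criterion (closed form)."""
    z = z_quantile(alpha / 2.0)
    return max(0.0, (4.0 * z**2 / l0**2 - 1.0 / S) * expected_sigma02(model))


def required_Q_apvc(S: float, eps0: float, model: VarianceModel) -> float:
    """Information level meeting the average posterior variance criterion."""
    return max(0.0, (1.0 / eps0 - 1.0 / S) * expected_sigma02(model))


def alc_expected_length(
    S: float, nA: float, nB: float, alpha0: float, model: VarianceModel
) -> float:
    """Average length of the (1-alpha0) HPD interval at the given allocation.

    ``2*z_{alpha0/2} * E[sigma_N]``; deterministic (so ALC = ACC) for a known
    variance, integrated over the inverse-gamma prior otherwise.
    """
    return 2.0 * z_quantile(alpha0 / 2.0) * expected_sigmaN(model, S, nA, nB)


def allocate(Q: float, r: float = 1.0, policy: str = "continuous"):
    """Turn a required information level into per-arm sizes at ratio r = nA/nB.

    Solving ``nA = r*nB`` with ``nA*nB/(nA+nB) = Q`` gives ``nB = Q*(1+r)/r``
    and ``nA = Q*(1+r)``; at r=1 the total is exactly 4Q.  The continuous
    policy keeps real-valued sizes (the convention for closed-form criteria);
    ``integer_total`` ceils the total and splits it by the ratio.
    """
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    if not r > 0:
        raise ValueError("allocation ratio must be > 0")
    nA = Q * (1.0 + r)
    nB = Q * (1.0 + r) / r
    total = nA + nB
    if policy == "integer_total":
        total = math.ceil(total - 1e-9)
        nA = total * r / (1.0 + r)
        nB = total / (1.0 + r)
    elif policy != "continuous":
        raise ValueError(f"unknown allocation policy {policy!r}")
    return nA, nB, total


def _split_total(total: float, r: float) -> tuple[float, float]:
    return total * r / (1.0 + r), total / (1.0 + r)


def solve_alc(
    S: float,
    l: float,
    alpha0: float,
    model: VarianceModel,
    r: float = 1.0,
    even_total: bool = False,
) -> DesignResult:
    """Smallest integer total whose average HPD length meets the bound.

    The expected length is strictly decreasing in the total (per-arm sizes may
    be fractional under the ratio split), so an exponential bracket followed by
    bisection finds the crossing; a final downward scan guarantees minimality.
    ``even_total`` restricts the search to even totals (whole per-arm sizes at
    r=1).
    """
    if not l > 0:
        raise ValueError("ALC target length must be > 0")
    step = 2 if even_total else 1

    def length_at(total: float) -> float:
        nA, nB = _split_total(total, r)
        return alc_expected_length(S, nA, nB, alpha0, model)

    prior_length = 2.0 * z_quantile(alpha0 / 2.0) * math.sqrt(S)
    if prior_length <= l:
        return DesignResult(
            Q=0.0, nA=0.0, nB=0.0, total=0, attained=prior_length,
            criterion="ALC", strategy="robust",
        )

    hi = step
    while length_at(hi) > l:
        hi *= 2
    lo = hi // 2  # length_at(lo) > l (or lo < step)
    while hi - lo > step:
        mid = (lo + hi) // 2
        mid -= mid % step
        if length_at(mid) > l:
            lo = mid
        else:
            hi = mid
    # downward confirmation scan
    while hi - step >= step and length_at(hi - step) <= l:
        hi -= step
    nA, nB = _split_total(hi, r)
    return DesignResult(
        Q=nA * nB / (nA + nB), nA=nA, nB=nB, total=hi,
        attained=length_at(hi), criterion="ALC", strategy="robust",
    )


def apply_strategy(
    summaries: list[HistoricalSummary],
    strategy: str,
    mix: PrecisionMixturePrior = DEFAULT_MIXTURE,
    s0: float = DEFAULT_S0,
) -> CollectivePrior:
    """Build the effect prior under one of the comparator borrowing strategies."""
    if strategy in ("robust", "optimal"):
        return collective_prior(summaries, mix, s0)
    if strategy == "no_robustification":
        forced = [dataclasses.replace(h, w=0.0) for h in summaries]
        return collective_prior(forced, mix, s0)
    if strategy == "no_borrowing":
        forced = [dataclasses.replace(h, w=1.0) for h in summaries]
        return collective_prior(forced, mix, s0)
    if strategy == "single_source":
        best = min(summaries, key=lambda h: h.variance)  # ties: first listed
        return CollectivePrior(mean=best.mean, variance=best.variance)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def design(
    summaries: list[HistoricalSummary],
    spec: CriterionSpec,
    model: VarianceModel | None,
    strategy: str = "robust",
    mix: PrecisionMixturePrior = DEFAULT_MIXTURE,
    s0: float = DEFAULT_S0,
    r: float = 1.0,
    even_total: bool = False,
) -> DesignResult:
    """Solve one design: strategy-adjusted prior, variance model, criterion.

    ``model=None`` defers the variance model to the strategy: the optimal
    benchmark equates the known sigma0^2 to the collective-prior variance S.
    For the inverse-gamma model the stored S is refreshed to match the
    strategy-adjusted prior (so no-borrowing inflates the variance prior too,
    unless an explicit model pins S).
    """
    prior = apply_strategy(summaries, strategy, mix, s0)
    S = prior.variance
    if strategy == "optimal":
        if model is None or model.kind == "known":
            model = known_variance(S)
        else:
            model = VarianceModel(kind="invgamma", c=model.c, S=S)
    elif model is None:
        raise ValueError("a variance model is required for non-optimal strategies")
    elif model.kind == "invgamma":
        model = VarianceModel(kind="invgamma", c=model.c, S=S)

    if spec.kind == "ACC":
        Q = required_Q_acc(S, spec.l0, spec.alpha, model)
        nA, nB, total = allocate(Q, r)
        if Q > 0:
            attained = 1.0 - spec.alpha
        else:
            z_half = spec.l0 / (2.0 * math.sqrt(S))
            attained = 2.0 * stats.norm.cdf(z_half) - 1.0
        result = DesignResult(Q=Q, nA=nA, nB=nB, total=total,
                              attained=attained, criterion="ACC")
    elif spec.kind == "APVC":
        Q = required_Q_apvc(S, spec.eps0, model)
        nA, nB, total = allocate(Q, r)
        attained = min(spec.eps0, S) if Q >= 0 else spec.eps0
        result = DesignResult(Q=Q, nA=nA, nB=nB, total=total,
                              attained=attained, criterion="APVC")
    else:  # ALC
        result = solve_alc(S, spec.l, spec.alpha0, model, r=r, even_total=even_total)
    return dataclasses.replace(result, strategy=strategy)
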