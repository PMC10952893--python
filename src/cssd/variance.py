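"""Sampling-variance models for the new experiment.

The common outcome variance sigma0^2 is either known, or assigned an
inverse-gamma prior induced by the chi-square link ``c*S/sigma0^2 ~ chi2(c)``,
where ``S`` is the collective-prior variance and ``c`` the degrees of freedom
controlling how strongly pre-experimental data inform the variance.  The link
is equivalent to ``sigma0^2 ~ Inv-Gamma(c/2, c*S/2)`` in the shape--scale
parameterization (density proportional to ``x^(-shape-1) * exp(-scale/x)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "VarianceModel",
    "known_variance",
    "invgamma_from_collective",
    "expected_sigma02",
    "expected_sigmaN",
]


class NoFiniteMeanError(ValueError):
    """E[sigma0^2] does not exist (inverse-gamma with c <= 2)."""


@dataclass(frozen=True)
class VarianceModel:
    """Known sigma0^2, or Inv-Gamma(c/2, c*S/2) via the chi-square link."""

    kind: str  # "known" | "invgamma"
    sigma02: float | None = None
    c: float | None = None
    S: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "known":
            if self.sigma02 is None or not self.sigma02 > 0:
                raise ValueError(f"known variance requires sigma02 > 0, got {self.sigma02}")
        elif self.kind == "invgamma":
            if self.c is None or not self.c > 0:
                raise ValueError(f"invgamma requires c > 0, got {self.c}")
            if self.S is None or not self.S > 0:
                raise ValueError(f"invgamma requires S > 0, got {self.S}")
        else:
            raise ValueError(f"unknown variance model kind {self.kind!r}")

    @property
    def shape(self) -> float:
        if self.kind != "invgamma":
            raise ValueError("shape defined only for invgamma models")
        return self.c / 2.0

    @property
    def scale(self) -> float:
        if self.kind != "invgamma":
            raise ValueError("scale defined only for invgamma models")
        return self.c * self.S / 2.0

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw sigma0^2 values (degenerate at sigma02 for the known case)."""
        if self.kind == "known":
            return np.full(size, self.sigma02)
        return self.scale / rng.gamma(self.shape, size=size)


def known_variance(sigma02: float) -> VarianceModel:
    return VarianceModel(kind="known", sigma02=sigma02)


def invgamma_from_collective(S: float, c: float) -> VarianceModel:
    """Inverse-gamma prior on sigma0^2 from the chi-square link at strength c.

    ``c*S/sigma0^2 ~ chi2(c)`` gives ``sigma0^2 ~ Inv-Gamma(c/2, c*S/2)``; the
    implied Gamma prior on the precision ``1/sigma0^2`` has mean ``1/S``.
    Larger c ties sigma0^2 more tightly to the collective-prior variance S.
    """
    return VarianceModel(kind="invgamma", c=c, S=S)


def expected_sigma02(model: VarianceModel) -> float:
    """Prior mean of sigma0^2: the known value, or c*S/(c-2) for c > 2."""
    if model.kind == "known":
        return model.sigma02
    if model.c <= 2:
        raise NoFiniteMeanError(
            f"E[sigma0^2] is infinite for c={model.c} <= 2; the closed-form "
            "coverage and variance criteria are unavailable"
        )
    return model.c * model.S / (model.c - 2.0)


def expected_sigmaN(model: VarianceModel, S: float, nA: float, nB: float) -> float:
    """Expected posterior standard deviation E[(1/S + Q/sigma0^2)^(-1/2)].

    ``Q = nA*nB/(nA+nB)`` is the harmonic-mean information level.  For a known
    variance the expectation is the deterministic posterior SD itself.  For the
    inverse-gamma model the expectation is taken over the precision
    ``tau = 1/sigma0^2 ~ Gamma(c/2, rate c*S/2)`` by adaptive quadrature; the
    integrand is bounded by sqrt(S), so the integral exists for every c > 0.
    """
    if not (S > 0 and nA > 0 and nB > 0):
        raise ValueError("S, nA, nB must all be > 0")
    Q = nA * nB / (nA + nB)
    if model.kind == "known":
        return (1.0 / S + Q / model.sigma02) ** -0.5

    shape, rate = model.c / 2.0, model.c * model.S / 2.0
    tau = stats.gamma(shape, scale=1.0 / rate)

    def integrand(t: float) -> float:
        return (1.0 / S + Q * t) ** -0.5 * tau.pdf(t)

    value, abserr = integrate.quad(
        integrand, 0.0, np.inf, epsrel=1e-10, epsabs=1e-12, limit=200
    )
    if not np.isfinite(value) or abserr > 1e-6 * max(abs(value), 1e-12):
        raise ArithmeticError(
            f"expected_sigmaN quadrature did not converge: value={value}, abserr={abserr}"
        )
    return value
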