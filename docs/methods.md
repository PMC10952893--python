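# Methods

## Model and assumptions

The package plans a two-group experiment whose outcome is the difference in
means μΔ = μ_A − μ_B of independent normal samples with common variance σ₀²
(binomial outcomes enter through the log-odds ratio with its Woolf
normal approximation; the normality of every source summary is assumed, not
checked). Pre-experimental information from K sources, each summarized as
θₖ|yₖ ~ N(mₖ, sₖ²), is linked to μΔ by commensurate predictive priors: a
conditional normal with unknown precision νₖ, on which a two-component Gamma
mixture prior encodes prior skepticism wₖ about source k's relevance.
Integrating νₖ out yields a two-component mixture of nonstandardized t
distributions (both located at θₖ, scales √(b0j/a0j), degrees of freedom
2·a0j); the package replaces it by the normal that carries its exact first
two moments. This moment match requires a01, a02 > 1 and is the step that
makes every downstream formula conjugate; its accuracy is itself verified in
the test suite by comparing the matched variance against quadrature of the
t-mixture density to 1e−6 relative tolerance.

Two conventions are load-bearing and worth stating twice:

* **Gamma components are shape–rate.** Gamma(a, b) has mean a/b and the
  matched predictive variance contribution is b/(a−1). A shape–scale misread
  silently rescales every variance and therefore every sample size.
* **The inverse-gamma variance prior is shape–scale**, density ∝
  x^(−α−1)·e^(−β/x). The chi-square link c·S/σ₀² ~ χ²(c) is equivalent to
  σ₀² ~ Inv-Gamma(c/2, c·S/2) in this parameterization.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| a01, b01 | down-weighting Gamma component (shape–rate) | 2, 2 | diffuse on the precision; predictive variance inflation 2.0 when wₖ=1 |
| a02, b02 | strong-borrowing component | 18, 3 | concentrated near precision 6; inflation only 3/17 ≈ 0.18 when wₖ=0 |
| s₀ | concentration of pₖ ∝ exp(−wₖ²/s₀) | 0.05 | small relative to typical wₖ so the map discriminates between sources; s₀→∞ flattens to 1/K, s₀→0⁺ concentrates on argmin wₖ (ties split equally) |
| c | degrees of freedom of the variance link | user | c ≤ 2 leaves E[σ₀²] infinite (closed-form ACC/APVC unavailable); c→∞ recovers the known-variance design at σ₀² = S |
| ℓ₀, α / ℓ, α₀ / ε₀ | criterion targets | 0.65, 0.05, 0.03 in the CLI | the worked application's choices; effect-scale units (log-odds ratio), so domain-specific |

The wₖ themselves are user input. The package ships `hellinger_distance`
(closed form between normals, cross-checked against quadrature) as the
recommended discrepancy measure for eliciting them, but deliberately provides
no automatic distance-to-weight mapping: that choice is subjective and should
stay visible to the analyst.

## Criteria and solvers

ACC and APVC have closed forms once E[σ₀²] is available, and both clamp the
required information level at Q = 0 when the collective prior alone already
meets the target. Their reported totals are continuous (4Q under equal
allocation): rounding up to integers is a reporting decision left to the
user, and the continuous value is what the closed form actually solves.

ALC with unknown variance requires E[σ_N] = E[(1/S + Q/σ₀²)^(−1/2)], computed
by adaptive quadrature after transforming to the precision τ = 1/σ₀² ~
Gamma(c/2, rate c·S/2); the integrand is bounded by √S so the expectation
exists for every c > 0 even when E[σ₀²] does not. The solver searches the
smallest *integer total* (per-arm sizes may be fractional under the
allocation ratio; an opt-in `even_total` policy restricts to whole per-arm
sizes at r = 1): exponential bracketing, bisection on the strictly decreasing
expected length, and a final downward scan that guarantees minimality.
Quadrature runs at 1e−10 relative tolerance and raises with diagnostics
rather than returning a doubtful value.

Two structural identities are worth knowing when interpreting output:

* With known σ₀² the HPD length is deterministic, so ACC and ALC coincide
  exactly; under the inverse-gamma prior with small c the ALC total is
  systematically below the ACC total, and the two converge as c grows.
* The unknown-variance ACC and APVC solutions substitute E[σ₀²] into the
  known-variance bound. For APVC this plug-in is *conservative*: σ_N² is
  concave in σ₀², so by Jensen's inequality the simulated average posterior
  variance at the solved design sits below ε₀ (about 0.027 versus 0.030 in
  the worked application at c = 5) rather than exactly at it. The Monte-Carlo
  verifier asserts equality only where it is exact (known variance) and the
  guaranteed bound otherwise.

## Comparator strategies

`no_robustification` forces every wₖ = 0 (full trust), `no_borrowing` forces
wₖ = 1 — which also flattens the synthesis weights to 1/K — and brackets the
robust design from above; `single_source` uses the smallest-variance source
directly (ties broken by listed order); `optimal` equates σ₀² to the
collective-prior variance S as the perfect-commensurability benchmark. Under
`no_borrowing` with the inverse-gamma model, S is still recomputed from the
wₖ=1 prior and feeds the variance prior: historical data are then excluded
from the effect prior but may still inform σ₀², which matters increasingly as
c grows.

## Monte-Carlo verification and the generator

`mc_average_properties` emulates the design-stage uncertainty exactly as the
criteria define it: draw σ₀² from its prior (degenerate if known), draw the
realized mean difference from the marginal predictive N(prior mean,
(1/n_A+1/n_B)σ₀² + S), form the conjugate posterior, and average HPD
coverage, credible length, and posterior variance over replicates (default
n_sim = 10⁵, seeded generator, seed recorded in the report). All three
recorded properties depend on the data only through σ₀², so the simulation is
a check of the integration in the criteria, not of robustness to prior–data
conflict: passing it says the averages are computed correctly under the
model's own predictive distribution, nothing about misspecified priors or
non-normal data. The bundled benchmark configurations are hypothetical
five-source summaries spanning consistent/divergent means and high/low
informativeness; only their raw (mₖ, sₖ², wₖ) inputs are stored and every
derived quantity is recomputed.

## Numerical choices and edge cases

* Synthesis weights subtract the maximal exponent before normalizing, so the
  s₀ → 0⁺ limit is exact (ties at the minimum split equally) instead of 0/0.
* Zero cells in a 2×2 table raise instead of auto-applying +0.5; continuity
  corrections change the estimand and belong upstream.
* `hellinger_distance` clips the tiny negative round-off of H² before the
  square root; identical inputs return ~1e−8, not exactly 0.
* Criterion and config validation reject unknown keys and name the offending
  field, so YAML typos fail loudly before any computation.

## Limitations

* The collective prior is the moment-matched normal; the exact t-mixture
  posterior is not implemented (the moment match is verified, but heavy-tail
  behavior under severe prior–data conflict is not represented).
* Unequal per-arm variances, time-to-event outcomes, interim re-estimation of
  wₖ, and hypothesis-testing (type-I-error calibrated) sample sizes are out
  of scope.
* The APVC with unknown variance is conservative by construction (see above);
  users wanting exact average-variance calibration should solve the ALC-style
  search against the integrated posterior variance instead.
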