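"""Sample-size solvers: closed forms, the ALC integer search, allocation,
and the comparator borrowing strategies."""

import numpy as np
import pytest
from scipy import stats

from cssd.prior import HistoricalSummary
from cssd.ssd import (
    CriterionSpec,
    alc_expected_length,
    allocate,
    apply_strategy,
    design,
    required_Q_acc,
    required_Q_apvc,
    solve_alc,
    z_quantile,
)
from cssd.variance import invgamma_from_collective, known_variance

ACC = CriterionSpec(kind="ACC", l0=0.65, alpha=0.05)
ALC = CriterionSpec(kind="ALC", l=0.65, alpha0=0.05)
APVC = CriterionSpec(kind="APVC", eps0=0.03)


class TestZQuantile:
    def test_standard_values(self):
        assert z_quantile(0.025) == pytest.approx(1.95996, abs=1e-5)
        assert z_quantile(0.5) == 0.0

    def test_round_trip_with_cdf(self):
        for q in np.linspace(0.01, 0.99, 23):
            assert stats.norm.cdf(z_quantile(q)) == pytest.approx(1 - q, rel=1e-10)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            z_quantile(1.0)


class TestClosedFormCriteria:
    def test_acc_known_variance_total(self, application_prior):
        Q = required_Q_acc(application_prior.variance, 0.65, 0.05, known_variance(0.35))
        _, _, total = allocate(Q, r=1.0)
        assert total == pytest.approx(41.8, abs=0.05)

    def test_acc_unknown_variance_total(self, application_prior):
        S = application_prior.variance
        Q = required_Q_acc(S, 0.65, 0.05, invgamma_from_collective(S, 5))
        assert 4 * Q == pytest.approx(30.7, abs=0.05)

    def test_apvc_unknown_variance_total(self, application_prior):
        S = application_prior.variance
        Q = required_Q_apvc(S, 0.03, invgamma_from_collective(S, 5))
        assert 4 * Q == pytest.approx(27.6, abs=0.05)

    def test_clamps_to_zero_when_prior_suffices(self):
        # tiny prior variance: the information target is already met
        assert required_Q_acc(1e-4, 0.65, 0.05, known_variance(0.35)) == 0.0
        assert required_Q_apvc(0.02, 0.03, known_variance(0.35)) == 0.0
        assert required_Q_apvc(0.03, 0.03, known_variance(0.35)) == 0.0


class TestAllocate:
    def test_equal_allocation_total_is_four_Q(self):
        nA, nB, total = allocate(10.456, r=1.0)
        assert total == pytest.approx(4 * 10.456)
        assert nA == nB

    def test_unequal_ratio_preserves_information_level(self):
        Q = 7.3
        nA, nB, total = allocate(Q, r=2.0)
        assert nA == pytest.approx(3 * Q) and nB == pytest.approx(1.5 * Q)
        assert nA * nB / (nA + nB) == pytest.approx(Q)

    def test_integer_total_policy_ceils(self):
        _, _, total = allocate(10.456, r=1.0, policy="integer_total")
        assert total == 42


class TestAlcSearch:
    def test_known_variance_alc_equals_acc(self, application_prior):
        """With a known sampling variance the HPD length is deterministic, so
        the ALC information requirement coincides with the ACC closed form."""
        S = application_prior.variance
        model = known_variance(0.35)
        Q_acc = required_Q_acc(S, 0.65, 0.05, model)
        nA, nB, _ = allocate(Q_acc, 1.0)
        assert alc_expected_length(S, nA, nB, 0.05, model) == pytest.approx(0.65, rel=1e-9)

    def test_application_integer_total(self, application_prior):
        S = application_prior.variance
        res = solve_alc(S, 0.65, 0.05, invgamma_from_collective(S, 5))
        assert res.total == 24
        assert res.attained <= 0.65
        # minimality: one step down violates the bound
        assert alc_expected_length(S, 11.5, 11.5, 0.05,
                                   invgamma_from_collective(S, 5)) > 0.65

    def test_expected_length_decreases_with_sample_size(self, application_prior):
        S = application_prior.variance
        model = invgamma_from_collective(S, 3)
        lengths = [alc_expected_length(S, n, n, 0.05, model) for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(lengths, lengths[1:]))

    def test_generous_target_needs_no_data(self, application_prior):
        S = application_prior.variance
        res = solve_alc(S, 10 * np.sqrt(S), 0.05, invgamma_from_collective(S, 5))
        assert res.total == 0
        assert res.attained == pytest.approx(2 * z_quantile(0.025) * np.sqrt(S))

    def test_even_total_policy(self, application_prior):
        S = application_prior.variance
        res = solve_alc(S, 0.65, 0.05, invgamma_from_collective(S, 5), even_total=True)
        assert res.total % 2 == 0
        assert res.total == 24  # already even here

    def test_agrees_with_monte_carlo_expected_length(self, application_prior):
        S = application_prior.variance
        model = invgamma_from_collective(S, 5)
        rng = np.random.default_rng(29)
        n = 400_000
        sig02 = model.rvs(n, rng)
        Q = 6.0  # nA=nB=12
        sigmaN = (1 / S + Q / sig02) ** -0.5
        mc = 2 * z_quantile(0.025) * sigmaN
        se = mc.std(ddof=1) / np.sqrt(n)
        assert alc_expected_length(S, 12, 12, 0.05, model) == pytest.approx(
            mc.mean(), abs=3 * se
        )


class TestStrategies:
    def test_forced_weight_extremes(self, application_sources):
        none = apply_strategy(application_sources, "no_robustification")
        full = apply_strategy(application_sources, "no_borrowing")
        robust = apply_strategy(application_sources, "robust")
        assert none.variance < robust.variance < full.variance
        # w=1 everywhere flattens the synthesis weights
        np.testing.assert_allclose([c.p for c in full.components], [0.2] * 5)

    def test_single_source_picks_most_informative(self, application_sources):
        prior = apply_strategy(application_sources, "single_source")
        assert prior.mean == -0.37 and prior.variance == 0.22

    def test_optimal_benchmark_equates_variance_to_prior(self, application_sources):
        res = design(application_sources, ACC, None, strategy="optimal")
        robust = apply_strategy(application_sources, "robust")
        S = robust.variance
        expected_Q = required_Q_acc(S, 0.65, 0.05, known_variance(S))
        assert res.Q == pytest.approx(expected_Q)

    def test_bounding_by_weight_extremes(self, application_sources):
        """Robust totals sit between no-robustification and no-borrowing."""
        model = invgamma_from_collective(1.0, 3)  # S refreshed per strategy
        for spec in (ACC, ALC, APVC):
            totals = {
                s: design(application_sources, spec, model, strategy=s).total
                for s in ("no_robustification", "robust", "no_borrowing")
            }
            assert totals["no_robustification"] <= totals["robust"] <= totals["no_borrowing"]

    def test_totals_monotone_in_targets(self, application_sources):
        model = known_variance(0.35)
        t_tight = design(application_sources,
                         CriterionSpec(kind="ACC", l0=0.55, alpha=0.05), model).total
        t_loose = design(application_sources, ACC, model).total
        assert t_tight > t_loose
        t_high_cov = design(application_sources,
                            CriterionSpec(kind="ACC", l0=0.65, alpha=0.01), model).total
        assert t_high_cov > t_loose
        e_tight = design(application_sources,
                         CriterionSpec(kind="APVC", eps0=0.02), model).total
        assert e_tight > design(application_sources, APVC, model).total

    def test_c_sweep_converges_to_known_variance_benchmark(self, application_sources):
        """Totals decrease in c and approach the sigma0^2 = S known-variance
        answer; ACC and ALC agree closely once c is large."""
        robust = apply_strategy(application_sources, "robust")
        S = robust.variance
        acc_totals = [
            design(application_sources, ACC, invgamma_from_collective(S, c)).total
            for c in (3, 5, 10, 20, 40)
        ]
        assert all(a >= b for a, b in zip(acc_totals, acc_totals[1:]))
        benchmark = design(application_sources, ACC, known_variance(S)).total
        big_c = design(application_sources, ACC, invgamma_from_collective(S, 400)).total
        assert big_c == pytest.approx(benchmark, rel=0.01)
        acc20 = design(application_sources, ACC, invgamma_from_collective(S, 20)).total
        alc20 = design(application_sources, ALC, invgamma_from_collective(S, 20)).total
        assert abs(acc20 - alc20) <= 1.0

    def test_alc_below_acc_at_small_c(self, application_sources):
        model = invgamma_from_collective(1.0, 3)
        acc = design(application_sources, ACC, model).total
        alc = design(application_sources, ALC, model).total
        assert alc < acc

    def test_unknown_strategy_raises(self, application_sources):
        with pytest.raises(ValueError):
            apply_strategy(application_sources, "pooled")


class TestCriterionSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"kind": "ACC", "l0": -1, "alpha": 0.05},
        {"kind": "ACC", "l0": 0.65, "alpha": 1.5},
        {"kind": "ALC", "l": 0.65},
        {"kind": "APVC"},
        {"kind": "BOGUS", "l0": 0.65, "alpha": 0.05},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CriterionSpec(**kwargs)
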