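"""Sensitivity analyses: tornado, PSA sampling, CEAC, price threshold, subgroups."""

import numpy as np
import pytest

from nsclc_cea import (
    ParamSpec,
    SubgroupSpec,
    WTP_CHINA_2022,
    ceac,
    one_way_sa,
    run_psa,
    run_subgroup,
    sample_psa_inputs,
    table_param_specs,
    threshold_price,
)
from nsclc_cea.uncertainty import acceptability_at


class TestParamSpec:
    def test_order_enforced(self):
        with pytest.raises(ValueError, match="low <= base <= high"):
            ParamSpec("x", 1.0, 2.0, 3.0, "gamma")

    def test_beta_support(self):
        with pytest.raises(ValueError, match="beta"):
            ParamSpec("x", 1.5, 1.0, 2.0, "beta")

    def test_sd_from_95_interval(self):
        spec = ParamSpec("x", 1.0, 0.5, 1.5, "normal")
        assert spec.sd == pytest.approx(1.0 / 3.92)


class TestOneWaySA:
    def test_degenerate_range_zero_spread(self, model):
        spec = ParamSpec("hr_os", 0.71, 0.71, 0.71, "normal")
        entries = one_way_sa(model, [spec])
        assert entries[0].spread == 0.0

    def test_icer_monotone_in_hr_os(self, model):
        """Higher OS hazard ratio shrinks the QALY gain, raising the ICER."""
        icers = [
            model.evaluate({"hr_os": h}).icer for h in (0.53, 0.71, 0.93)
        ]
        assert icers[0] < icers[1] < icers[2]

    def test_base_values_reproduce_base_icer(self, model):
        """Evaluating any parameter at its base value gives the base-case ICER."""
        base_icer = model.evaluate().icer
        for spec in table_param_specs(model)[::5]:
            assert model.evaluate({spec.name: spec.base}).icer == pytest.approx(base_icer)

    def test_top_drivers(self, model):
        """The OS hazard ratio, cemiplimab price and PFS hazard ratio dominate."""
        entries = one_way_sa(model, table_param_specs(model))
        top = {e.name for e in entries[:4]}
        assert {"hr_os", "cost_cemiplimab", "hr_pfs"} <= top

    def test_entries_sorted_by_spread(self, model):
        entries = one_way_sa(model, table_param_specs(model)[:8])
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)


class TestSampling:
    def test_beta_moment_match(self):
        """Beta draws moment-matched to (0.804, sd) have the right mean and support."""
        spec = ParamSpec("u", 0.804, 0.643, 0.965, "beta")
        rng = np.random.default_rng(0)
        draws = np.array([sample_psa_inputs([spec], rng)["u"] for _ in range(10_000)])
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.804, rel=0.01)

    def test_gamma_support_positive(self):
        spec = ParamSpec("c", 1521.38, 1217.10, 1825.65, "gamma")
        rng = np.random.default_rng(1)
        draws = np.array([sample_psa_inputs([spec], rng)["c"] for _ in range(1000)])
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(1521.38, rel=0.05)

    def test_fixed_parameter_untouched(self):
        spec = ParamSpec("discount_rate", 0.05, 0.0, 0.08, "fixed")
        rng = np.random.default_rng(2)
        draws = {sample_psa_inputs([spec], rng)["discount_rate"] for _ in range(50)}
        assert draws == {0.05}

    def test_truncated_normal_positive(self):
        spec = ParamSpec("hr", 0.1, 0.01, 1.0, "normal")
        rng = np.random.default_rng(3)
        draws = np.array([sample_psa_inputs([spec], rng)["hr"] for _ in range(2000)])
        assert np.all(draws > 0)


class TestPSA:
    def test_reproducible_per_seed(self, model):
        a = run_psa(model, n_iter=50, seed=9)
        b = run_psa(model, n_iter=50, seed=9)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)

    def test_different_seeds_differ(self, model):
        a = run_psa(model, n_iter=20, seed=1)
        b = run_psa(model, n_iter=20, seed=2)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_ceac_bounded_and_single_sample(self, model):
        """CEAC probabilities lie in [0,1] and reuse one PSA draw across the grid."""
        psa = run_psa(model, n_iter=100, seed=4)
        grid = np.linspace(0, 1e6, 21)
        curve = ceac(psa, grid)
        assert ((curve["probability"] >= 0) & (curve["probability"] <= 1)).all()
        # the infinite-WTP limit is the fraction of iterations with a QALY gain
        assert ceac(psa, [1e12])["probability"].iloc[0] == pytest.approx(
            (psa.delta_qaly > 0).mean()
        )

    def test_acceptability_near_zero_at_chinese_wtp(self, model):
        psa = run_psa(model, n_iter=200, seed=5)
        assert acceptability_at(psa, WTP_CHINA_2022) <= 0.005


class TestThresholdPrice:
    def test_deterministic_solver_hits_wtp_exactly(self, model):
        """ICER evaluated at the solved price equals the WTP to 1e-6 relative."""
        res = threshold_price(model, WTP_CHINA_2022, mode="deterministic")
        check = model.evaluate({"cost_cemiplimab": res["price_per_100mg"]})
        assert check.icer == pytest.approx(WTP_CHINA_2022, rel=1e-6)

    def test_modes_agree(self, model):
        """The closed-form and 50%-acceptability solvers agree within 10%."""
        det = threshold_price(model, WTP_CHINA_2022, mode="deterministic")
        psa50 = threshold_price(model, WTP_CHINA_2022, mode="psa50", n_iter=300, seed=6)
        assert psa50["price_per_100mg"] == pytest.approx(
            det["price_per_100mg"], rel=0.10
        )

    def test_no_crossing_status(self, model):
        """A WTP unreachable even with a free drug reports no crossing."""
        res = threshold_price(model, 100.0, mode="deterministic")
        assert res["status"] == "no_crossing"

    def test_already_cost_effective_rejected(self, model):
        with pytest.raises(ValueError, match="already below"):
            threshold_price(model, 1e9, mode="deterministic")


class TestSubgroups:
    def test_overall_hrs_reproduce_base_case(self, model):
        """A subgroup with the whole-population HRs is the base case exactly."""
        res = run_subgroup(SubgroupSpec("overall", 0.56, 0.71), model)
        base = model.evaluate()
        assert res.icer == pytest.approx(base.icer, rel=1e-12)
        assert res.delta_cost == pytest.approx(base.delta_cost, rel=1e-12)

    def test_female_subgroup_dominated(self, model):
        """OS HR 2.11 makes the intervention lose QALYs at extra cost."""
        res = run_subgroup(SubgroupSpec("Female", 0.90, 2.11), model)
        assert res.delta_qaly < 0 < res.delta_cost
        assert res.icer < 0
        assert res.annotation == "dominated"

    def test_invalid_hr_rejected(self):
        with pytest.raises(ValueError):
            SubgroupSpec("bad", -0.5, 1.0)
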