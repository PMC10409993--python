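"""Drug costing, accrual arithmetic and incremental cost-effectiveness."""

import numpy as np
import pandas as pd
import pytest

from nsclc_cea import (
    ArmTotals,
    CohortTrace,
    EconomicInputs,
    ModelSettings,
    StrategyDefinition,
    accrue,
    build_trace,
    cemiplimab_price_by_parity,
    compute_icer,
    drug_cost_per_cycle,
)
from nsclc_cea.model import PCT_OS, PCT_PFS

CCT = StrategyDefinition("CCT")
PCT = StrategyDefinition("PCT")


class TestDrugCosts:
    def test_cemiplimab_cycle_cost(self):
        """350 mg flat dose at 1521.38 USD/100 mg costs 5324.83 per cycle."""
        inputs = EconomicInputs()
        assert inputs.drug_cost("cemiplimab") == pytest.approx(5324.83)

    def test_cemiplimab_price_parity_derivation(self):
        """Per-cycle parity with 200 mg pembrolizumab at 2662.41 USD/100 mg."""
        assert cemiplimab_price_by_parity() == pytest.approx(1521.38, abs=0.005)

    def test_pemetrexed_dose_cost(self):
        """500 mg/m2 at BSA 1.72 is 860 mg -> 8.6 x 6.51 = 55.99 USD."""
        inputs = EconomicInputs()
        assert inputs.dose_mg("pemetrexed") == pytest.approx(860.0)
        assert inputs.drug_cost("pemetrexed") == pytest.approx(55.99, abs=0.005)

    def test_carboplatin_calvert_dose(self):
        """AUC 5 x (CrCl 70 + 25) = 475 mg."""
        assert EconomicInputs().dose_mg("carboplatin") == pytest.approx(475.0)

    def test_cemiplimab_only_within_cap(self):
        inputs = EconomicInputs()
        within = drug_cost_per_cycle(CCT, inputs, 36)
        beyond = drug_cost_per_cycle(CCT, inputs, 37)
        assert within - beyond == pytest.approx(inputs.drug_cost("cemiplimab"))

    def test_maintenance_only_pemetrexed_fraction(self):
        """From cycle 5 the PCT arm pays only the pemetrexed-regimen fraction."""
        inputs = EconomicInputs()
        mix = inputs.regimen_mix["PCT"]
        pem_frac = mix["pem_carbo"] + mix["pem_cis"]
        assert drug_cost_per_cycle(PCT, inputs, 5) == pytest.approx(
            pem_frac * inputs.drug_cost("pemetrexed")
        )

    def test_chemo_cycles_cost_more_than_maintenance(self):
        inputs = EconomicInputs()
        assert drug_cost_per_cycle(PCT, inputs, 4) > drug_cost_per_cycle(PCT, inputs, 5)

    def test_cycle_index_starts_at_one(self):
        with pytest.raises(ValueError):
            drug_cost_per_cycle(PCT, EconomicInputs(), 0)

    def test_unknown_regimen_key_rejected(self):
        with pytest.raises(ValueError, match="regimen"):
            EconomicInputs(
                regimen_mix={"CCT": {"bogus": 1.0}, "PCT": {"pem_carbo": 1.0}}
            )

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EconomicInputs(
                regimen_mix={
                    "CCT": {"pem_carbo": 0.9},
                    "PCT": {"pem_carbo": 1.0},
                }
            )


def _one_cycle_trace(arm="PCT"):
    frame = pd.DataFrame(
        {
            "cycle": [0, 1],
            "t_months": [0.0, 21 / 30.4375],
            "pfs": [1.0, 1.0],
            "pd": [0.0, 0.0],
            "dead": [0.0, 0.0],
            "newly_dead": [0.0, 0.0],
        }
    )
    return CohortTrace(frame, arm)


class TestAccrue:
    def test_empty_trace_zero_totals(self):
        frame = pd.DataFrame(
            {"cycle": [0], "t_months": [0.0], "pfs": [1.0], "pd": [0.0],
             "dead": [0.0], "newly_dead": [0.0]}
        )
        totals = accrue(CohortTrace(frame, "PCT"), PCT, EconomicInputs(), ModelSettings())
        assert totals.total_cost == 0.0 and totals.total_qaly == 0.0

    def test_single_cycle_followup_and_utility(self):
        """One undiscounted cycle fully in PFS: cost = follow-up, QALY = u_pfs x 21/365.25."""
        inputs = EconomicInputs(
            unit_costs={k: 0.0 for k in EconomicInputs().unit_costs},
            care_costs={
                "followup_per_cycle": 92.69,
                "bsc_per_cycle": 0.0,
                "end_of_life": 0.0,
                "anemia": 0.0,
                "neutropenia": 0.0,
            },
            teae_incidence={"CCT": {}, "PCT": {}},
        )
        settings = ModelSettings(discount_rate_annual=0.0)
        totals = accrue(_one_cycle_trace(), PCT, inputs, settings)
        assert totals.total_cost == pytest.approx(92.69)
        assert totals.total_qaly == pytest.approx(0.804 * 21 / 365.25)

    def test_arm_mismatch_rejected(self):
        with pytest.raises(ValueError, match="arm"):
            accrue(_one_cycle_trace("PCT"), CCT, EconomicInputs(), ModelSettings())

    def test_zero_discount_equals_undiscounted(self):
        """With rate 0 the discounted and undiscounted life-years coincide."""
        settings = ModelSettings(discount_rate_annual=0.0)
        trace = build_trace(PCT_OS, PCT_PFS, settings, arm_label="PCT")
        totals = accrue(trace, PCT, EconomicInputs(), settings)
        assert totals.total_ly == pytest.approx(totals.total_ly_undisc, rel=1e-12)

    def test_cost_affine_in_unit_price(self):
        """Total cost is affine in each unit price (slope constant by finite differences)."""
        settings = ModelSettings()
        trace = build_trace(PCT_OS, PCT_PFS, settings, arm_label="CCT")
        base = EconomicInputs()
        for drug in ("cemiplimab", "pemetrexed", "paclitaxel"):
            costs = []
            for price in (0.0, 100.0, 200.0):
                uc = dict(base.unit_costs)
                uc[drug] = price
                totals = accrue(trace, CCT, base.with_(unit_costs=uc), settings)
                costs.append(totals.total_cost)
            slope1 = costs[1] - costs[0]
            slope2 = costs[2] - costs[1]
            assert slope1 == pytest.approx(slope2, rel=1e-9)
            assert slope1 > 0

    def test_raising_any_cost_never_decreases_total(self):
        settings = ModelSettings()
        trace = build_trace(PCT_OS, PCT_PFS, settings, arm_label="PCT")
        base_total = accrue(trace, PCT, EconomicInputs(), settings).total_cost
        inputs = EconomicInputs()
        for key in inputs.care_costs:
            cc = dict(inputs.care_costs)
            cc[key] *= 1.5
            bumped = accrue(trace, PCT, inputs.with_(care_costs=cc), settings).total_cost
            assert bumped >= base_total


class TestComputeICER:
    def _arm(self, label, cost, qaly):
        return ArmTotals(label, cost, 1.0, 1.0, qaly)

    def test_simple_ratio(self):
        res = compute_icer(self._arm("CCT", 200.0, 3.0), self._arm("PCT", 100.0, 1.0))
        assert res.icer == pytest.approx(50.0)
        assert res.annotation == ""

    def test_dominated_is_signed_negative(self):
        res = compute_icer(self._arm("CCT", 200.0, 1.0), self._arm("PCT", 100.0, 2.0))
        assert res.annotation == "dominated"
        assert res.icer == pytest.approx(-100.0)

    def test_dominant(self):
        res = compute_icer(self._arm("CCT", 50.0, 2.0), self._arm("PCT", 100.0, 1.0))
        assert res.annotation == "dominant"
        assert res.icer < 0

    def test_zero_delta_qaly_undefined(self):
        res = compute_icer(self._arm("CCT", 200.0, 1.0), self._arm("PCT", 100.0, 1.0))
        assert res.icer is None
        assert res.annotation == "undefined"
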