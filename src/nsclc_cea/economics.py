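"""Cost and QALY accrual over a cohort trace, and incremental results.

Costing perspective: direct medical costs only — drugs, routine follow-up
while progression-free, best supportive care (BSC) while progressed,
end-of-life care at death, and one-time management of grade >=3
treatment-emergent adverse events (TEAEs) with incidence above 5%
(anemia, neutropenia).  All monetary values are 2022 US dollars.

Dosing conventions: pemetrexed 500 mg/m2, paclitaxel 200 mg/m2 and
cisplatin 75 mg/m2 scale with body surface area; carboplatin uses the
Calvert formula, dose = AUC x (CrCl + 25) with AUC 5; cemiplimab is a
flat 350 mg per 3-weekly cycle.  Unit prices are per 100 mg with exact
per-mg pricing (no vial rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_engine import CohortTrace, ModelSettings, discount_factor

__all__ = [
    "EconomicInputs",
    "StrategyDefinition",
    "ArmTotals",
    "CEResult",
    "cemiplimab_price_by_parity",
    "drug_cost_per_cycle",
    "accrue",
    "compute_icer",
]

REGIMENS = ("pem_carbo", "pem_cis", "pac_carbo", "pac_cis")

#: Chinese national tender price of pembrolizumab, USD per 100 mg (2022)
PEMBROLIZUMAB_PRICE_PER_100MG = 2662.41


def cemiplimab_price_by_parity(
    pembrolizumab_price_per_100mg: float = PEMBROLIZUMAB_PRICE_PER_100MG,
    pembrolizumab_dose_mg: float = 200.0,
    cemiplimab_dose_mg: float = 350.0,
) -> float:
    """Cemiplimab unit price assuming per-cycle cost parity with pembrolizumab.

    Cemiplimab has no Chinese tender price, so its per-100 mg price is set
    such that one 350 mg cycle costs the same as one 200 mg pembrolizumab
    cycle: price = p_pembro * 200 / 350 = 1521.38 USD/100 mg.
    """
    return (
        pembrolizumab_price_per_100mg * pembrolizumab_dose_mg / cemiplimab_dose_mg
    )


def _default_unit_costs() -> dict:
    return {
        "carboplatin": 3.93,
        "cisplatin": 11.25,
        "cemiplimab": 1521.38,
        "pemetrexed": 6.51,
        "paclitaxel": 33.68,
    }


def _default_care_costs() -> dict:
    return {
        "followup_per_cycle": 92.69,
        "bsc_per_cycle": 365.51,
        "end_of_life": 2665.11,
        "anemia": 496.80,
        "neutropenia": 82.32,
    }


def _default_teae() -> dict:
    return {
        "CCT": {"anemia": 0.099, "neutropenia": 0.058},
        "PCT": {"anemia": 0.065, "neutropenia": 0.059},
    }


def _default_mix() -> dict:
    return {
        "CCT": {"pem_carbo": 0.369, "pem_cis": 0.083, "pac_carbo": 0.494, "pac_cis": 0.054},
        "PCT": {"pem_carbo": 0.299, "pem_cis": 0.104, "pac_carbo": 0.532, "pac_cis": 0.065},
    }


def _default_dosing() -> dict:
    return {
        "pemetrexed_mg_per_m2": 500.0,
        "paclitaxel_mg_per_m2": 200.0,
        "cisplatin_mg_per_m2": 75.0,
        "carboplatin_auc": 5.0,
        "cemiplimab_flat_mg": 350.0,
    }


@dataclass(frozen=True)
class EconomicInputs:
    """All cost, utility, incidence and dosing inputs of the base case.

    Defaults are the whole-population base-case values: national tender
    unit prices (USD per 100 mg), care costs per 21-day cycle, utilities
    0.804 (PFS) and 0.321 (PD), TEAE incidences per arm, body surface
    area 1.72 m2, creatinine clearance 70 ml/min, and the first-line
    chemotherapy regimen mix observed per arm.
    """

    unit_costs: dict = field(default_factory=_default_unit_costs)
    care_costs: dict = field(default_factory=_default_care_costs)
    utilities: dict = field(default_factory=lambda: {"pfs": 0.804, "pd": 0.321})
    disutilities: dict = field(default_factory=lambda: {"neutropenia": 0.20, "anemia": 0.073})
    teae_incidence: dict = field(default_factory=_default_teae)
    bsa_m2: float = 1.72
    crcl_ml_min: float = 70.0
    regimen_mix: dict = field(default_factory=_default_mix)
    dosing: dict = field(default_factory=_default_dosing)
    followup_while_alive: bool = False  # if True, follow-up also accrues in PD

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.unit_costs.values()):
            raise ValueError("unit costs must be >= 0")
        if any(c < 0 for c in self.care_costs.values()):
            raise ValueError("care costs must be >= 0")
        for u in self.utilities.values():
            if not (0.0 <= u <= 1.0):
                raise ValueError("utilities must lie in [0, 1]")
        for arm, mix in self.regimen_mix.items():
            unknown = set(mix) - set(REGIMENS)
            if unknown:
                raise ValueError(f"unknown regimen keys for {arm}: {sorted(unknown)}")
            if abs(sum(mix.values()) - 1.0) > 1e-3:
                raise ValueError(f"regimen mix for {arm} must sum to 1")

    def with_(self, **kw) -> "EconomicInputs":
        return replace(self, **kw)

    # -- per-administration drug quantities ------------------------------
    def dose_mg(self, drug: str) -> float:
        d = self.dosing
        if drug == "pemetrexed":
            return d["pemetrexed_mg_per_m2"] * self.bsa_m2
        if drug == "paclitaxel":
            return d["paclitaxel_mg_per_m2"] * self.bsa_m2
        if drug == "cisplatin":
            return d["cisplatin_mg_per_m2"] * self.bsa_m2
        if drug == "carboplatin":  # Calvert formula
            return d["carboplatin_auc"] * (self.crcl_ml_min + 25.0)
        if drug == "cemiplimab":
            return d["cemiplimab_flat_mg"]
        raise ValueError(f"unknown drug {drug!r}")

    def drug_cost(self, drug: str) -> float:
        """Cost of one administration: per-mg price x dose, no vial rounding."""
        return self.unit_costs[drug] / 100.0 * self.dose_mg(drug)


_REGIMEN_DRUGS = {
    "pem_carbo": ("pemetrexed", "carboplatin"),
    "pem_cis": ("pemetrexed", "cisplatin"),
    "pac_carbo": ("paclitaxel", "carboplatin"),
    "pac_cis": ("paclitaxel", "cisplatin"),
}


@dataclass(frozen=True)
class StrategyDefinition:
    """Treatment schedule of one arm.

    Both arms receive up to four 3-weekly cycles of histology-matched
    platinum doublets; the pemetrexed-regimen fraction continues
    pemetrexed maintenance while progression-free.  The CCT arm adds
    cemiplimab 350 mg every 3 weeks for at most 36 cycles (108 weeks).
    """

    arm_label: str  # "CCT" or "PCT"
    chemo_cycles: int = 4
    cemiplimab_max_cycles: int = 36
    maintenance_max_cycles: int | None = None  # None = until progression

    def __post_init__(self) -> None:
        if self.arm_label not in ("CCT", "PCT"):
            raise ValueError("arm_label must be 'CCT' or 'PCT'")
        if abs(self.cemiplimab_max_cycles * 21 - 108 * 7) > 21:
            raise ValueError("cemiplimab cap must correspond to 108 weeks +/- 1 cycle")

    @property
    def has_cemiplimab(self) -> bool:
        return self.arm_label == "CCT"


def drug_cost_per_cycle(
    strategy: StrategyDefinition, inputs: EconomicInputs, cycle_index: int
) -> float:
    """Drug cost of one on-treatment cycle for a patient still in PFS.

    Cycles 1-4: regimen-mix-weighted doublet cost (+ cemiplimab if CCT);
    cycles >= 5: pemetrexed maintenance for the pemetrexed-regimen
    fraction (+ cemiplimab if CCT and within the 108-week cap).
    """
    if cycle_index < 1:
        raise ValueError("cycle_index starts at 1")
    mix = inputs.regimen_mix[strategy.arm_label]
    cost = 0.0
    if cycle_index <= strategy.chemo_cycles:
        for regimen, frac in mix.items():
            cost += frac * sum(inputs.drug_cost(d) for d in _REGIMEN_DRUGS[regimen])
    else:
        within_cap = (
            strategy.maintenance_max_cycles is None
            or cycle_index <= strategy.maintenance_max_cycles
        )
        if within_cap:
            pem_frac = mix["pem_carbo"] + mix["pem_cis"]
            cost += pem_frac * inputs.drug_cost("pemetrexed")
    if strategy.has_cemiplimab and cycle_index <= strategy.cemiplimab_max_cycles:
        cost += inputs.drug_cost("cemiplimab")
    return cost


@dataclass(frozen=True)
class ArmTotals:
    """Discounted (and undiscounted-LY) totals for one strategy."""

    arm_label: str
    total_cost: float
    total_ly: float          # discounted life-years
    total_ly_undisc: float
    total_qaly: float

    def as_dict(self) -> dict:
        return {
            "arm": self.arm_label,
            "total_cost": self.total_cost,
            "total_ly_disc": self.total_ly,
            "total_ly_undisc": self.total_ly_undisc,
            "total_qaly": self.total_qaly,
        }


def accrue(
    trace: CohortTrace,
    strategy: StrategyDefinition,
    inputs: EconomicInputs,
    settings: ModelSettings,
) -> ArmTotals:
    """Accrue discounted costs, LYs and QALYs over a cohort trace.

    Per cycle: PFS occupancy pays drugs + routine follow-up and earns the
    PFS utility; PD occupancy pays BSC and earns the PD utility; newly
    dead pay end-of-life care.  TEAE costs and QALY decrements are
    one-time at model entry, incidence-weighted, charged at the first
    cycle.  Every flow is discounted at its cycle's end time.
    """
    if trace.arm_label and trace.arm_label != strategy.arm_label:
        raise ValueError(
            f"trace arm {trace.arm_label!r} does not match strategy {strategy.arm_label!r}"
        )
    f = trace.frame
    n_cycles = trace.n_cycles
    if n_cycles == 0:
        return ArmTotals(strategy.arm_label, 0.0, 0.0, 0.0, 0.0)

    pfs_end = f["pfs"].to_numpy()
    pd_end = f["pd"].to_numpy()
    newly_dead = f["newly_dead"].to_numpy()[1:]
    if settings.half_cycle:
        pfs_occ = 0.5 * (pfs_end[:-1] + pfs_end[1:])
        pd_occ = 0.5 * (pd_end[:-1] + pd_end[1:])
    else:
        pfs_occ = pfs_end[1:]
        pd_occ = pd_end[1:]

    cycles = np.arange(1, n_cycles + 1)
    t_days = cycles * settings.cycle_length_days
    disc = discount_factor(settings.discount_rate_annual, t_days)

    drug = np.array([drug_cost_per_cycle(strategy, inputs, int(k)) for k in cycles])
    followup = inputs.care_costs["followup_per_cycle"]
    bsc = inputs.care_costs["bsc_per_cycle"]
    pfs_cost = pfs_occ * (drug + followup)
    pd_cost = pd_occ * (bsc + (followup if inputs.followup_while_alive else 0.0))
    eol_cost = newly_dead * inputs.care_costs["end_of_life"]
    cost = float(np.sum(disc * (pfs_cost + pd_cost + eol_cost)))

    dt_years = settings.cycle_length_years
    u = inputs.utilities
    qaly = float(np.sum(disc * (pfs_occ * u["pfs"] + pd_occ * u["pd"]) * dt_years))
    ly_disc = float(np.sum(disc * (pfs_occ + pd_occ) * dt_years))
    ly_undisc = float(np.sum((pfs_occ + pd_occ) * dt_years))

    # one-time TEAE burden at model entry, discounted at the first cycle end
    inc = inputs.teae_incidence[strategy.arm_label]
    teae_cost = sum(inc[e] * inputs.care_costs[e] for e in inc)
    teae_dis = sum(inc[e] * inputs.disutilities[e] for e in inc)
    cost += float(disc[0]) * teae_cost
    qaly -= float(disc[0]) * teae_dis * dt_years

    return ArmTotals(strategy.arm_label, cost, ly_disc, ly_undisc, qaly)


@dataclass(frozen=True)
class CEResult:
    """Per-arm totals and the incremental comparison CCT vs PCT."""

    cct: ArmTotals
    pct: ArmTotals
    delta_cost: float
    delta_qaly: float
    icer: float | None
    annotation: str  # "", "dominant", "dominated", "undefined"

    def as_dict(self) -> dict:
        return {
            "CCT": self.cct.as_dict(),
            "PCT": self.pct.as_dict(),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "annotation": self.annotation,
        }


def compute_icer(cct: ArmTotals, pct: ArmTotals) -> CEResult:
    """Incremental cost-effectiveness ratio, sign-preserving.

    A higher-cost, lower-QALY intervention is flagged ``dominated`` and a
    cheaper, more-effective one ``dominant``; the signed ratio is still
    reported.  A zero QALY difference yields an undefined ICER (None).
    """
    d_cost = cct.total_cost - pct.total_cost
    d_qaly = cct.total_qaly - pct.total_qaly
    if d_qaly == 0.0:
        return CEResult(cct, pct, d_cost, d_qaly, None, "undefined")
    icer = d_cost / d_qaly
    annotation = ""
    if d_qaly < 0 and d_cost > 0:
        annotation = "dominated"
    elif d_qaly > 0 and d_cost < 0:
        annotation = "dominant"
    return CEResult(cct, pct, d_cost, d_qaly, icer, annotation)
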