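"""The assembled two-strategy decision model and its base-case inputs.

``DecisionModel`` bundles everything needed to evaluate the comparison of
cemiplimab + chemotherapy (CCT) against placebo + chemotherapy (PCT):
the fitted placebo-arm Weibull laws for overall survival (OS) and
progression-free survival (PFS), the trial hazard ratios that derive the
intervention arm under proportional hazards, the economic inputs and the
cohort-model settings.  ``evaluate`` accepts named parameter overrides so
the sensitivity analyses can perturb any input without mutating the model.

Base-case survival laws (monthly time scale, S(t) = exp(-lambda t^gamma)):

    PFS, PCT: lambda = 0.061800, gamma = 1.388300
    OS,  PCT: lambda = 0.030040, gamma = 1.213530
    HR (CCT vs PCT): PFS 0.56 (0.44-0.70), OS 0.71 (0.53-0.93)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .cohort_engine import ModelSettings, build_trace, horizon_cycles
from .economics import (
    CEResult,
    EconomicInputs,
    StrategyDefinition,
    accrue,
    compute_icer,
)
from .survival_models import HazardRatio, WeibullParams, scale_by_hr

__all__ = [
    "PCT_OS",
    "PCT_PFS",
    "HR_OS",
    "HR_PFS",
    "WTP_CHINA_2022",
    "SUBGROUP_HRS",
    "DecisionModel",
    "base_case_model",
]

PCT_OS = WeibullParams(scale_lambda=0.030040, shape_gamma=1.213530)
PCT_PFS = WeibullParams(scale_lambda=0.061800, shape_gamma=1.388300)
HR_OS = HazardRatio(0.71, 0.53, 0.93)
HR_PFS = HazardRatio(0.56, 0.44, 0.70)

#: 3x China's 2022 per-capita GDP, USD/QALY
WTP_CHINA_2022 = 38_201.0

#: subgroup label -> (HR_PFS, HR_OS), point estimates from the trial
SUBGROUP_HRS: dict[str, tuple[float, float]] = {
    "Age <65": (0.53, 0.57),
    "Age >=65": (0.56, 0.88),
    "Male": (0.48, 0.55),
    "Female": (0.90, 2.11),
    "White": (0.54, 0.67),
    "Non-white": (0.58, 0.79),
    "Squamous": (0.56, 0.56),
    "Non-squamous": (0.53, 0.79),
    "PD-L1 <1%": (0.76, 1.01),
    "PD-L1 1-49%": (0.47, 0.52),
    "PD-L1 >=50%": (0.47, 0.61),
    "ECOG PS 0": (0.20, 0.55),
    "ECOG PS 1": (0.60, 0.69),
    "Europe": (0.55, 0.67),
    "Asia": (0.52, 0.72),
    "Brain metastasis": (0.53, 0.42),
    "No brain metastasis": (0.54, 0.68),
    "Locally advanced": (0.34, 0.54),
    "Metastatic": (0.59, 0.69),
    "Smokers": (0.53, 0.61),
    "Never smokers": (0.65, 1.28),
}


@dataclass(frozen=True)
class DecisionModel:
    """Fully-specified CCT-vs-PCT comparison, evaluable under overrides."""

    pct_os: WeibullParams = PCT_OS
    pct_pfs: WeibullParams = PCT_PFS
    hr_os: float = HR_OS.value
    hr_pfs: float = HR_PFS.value
    econ: EconomicInputs = field(default_factory=EconomicInputs)
    settings: ModelSettings = field(default_factory=ModelSettings)
    cct_strategy: StrategyDefinition = field(
        default_factory=lambda: StrategyDefinition("CCT")
    )
    pct_strategy: StrategyDefinition = field(
        default_factory=lambda: StrategyDefinition("PCT")
    )

    # -- override plumbing -------------------------------------------------

    def with_overrides(self, overrides: dict[str, float]) -> "DecisionModel":
        """Return a copy with named scalar parameters replaced.

        Recognised names: ``hr_os``, ``hr_pfs``; ``cost_<drug>`` (unit
        prices per 100 mg), ``cost_<care item>``; ``teae_<ARM>_<event>``;
        ``utility_pfs``/``utility_pd``; ``disutility_<event>``; ``bsa``,
        ``crcl``, ``discount_rate``; ``mix_<ARM>_<regimen>``;
        ``pct_os_scale``/``pct_os_shape``/``pct_pfs_scale``/``pct_pfs_shape``.
        """
        model = self
        econ = self.econ
        unit_costs = dict(econ.unit_costs)
        care_costs = dict(econ.care_costs)
        utilities = dict(econ.utilities)
        disutilities = dict(econ.disutilities)
        teae = {arm: dict(d) for arm, d in econ.teae_incidence.items()}
        mix = {arm: dict(d) for arm, d in econ.regimen_mix.items()}
        bsa, crcl = econ.bsa_m2, econ.crcl_ml_min
        settings = self.settings
        pct_os, pct_pfs = self.pct_os, self.pct_pfs
        hr_os, hr_pfs = self.hr_os, self.hr_pfs

        for name, value in overrides.items():
            if name == "hr_os":
                hr_os = value
            elif name == "hr_pfs":
                hr_pfs = value
            elif name == "bsa":
                bsa = value
            elif name == "crcl":
                crcl = value
            elif name == "discount_rate":
                settings = settings.with_(discount_rate_annual=value)
            elif name == "pct_os_scale":
                pct_os = replace(pct_os, scale_lambda=value)
            elif name == "pct_os_shape":
                pct_os = replace(pct_os, shape_gamma=value)
            elif name == "pct_pfs_scale":
                pct_pfs = replace(pct_pfs, scale_lambda=value)
            elif name == "pct_pfs_shape":
                pct_pfs = replace(pct_pfs, shape_gamma=value)
            elif name.startswith("cost_"):
                key = name[5:]
                if key in unit_costs:
                    unit_costs[key] = value
                elif key in care_costs:
                    care_costs[key] = value
                else:
                    raise KeyError(f"unknown cost parameter {name!r}")
            elif name.startswith("utility_"):
                utilities[name[8:]] = value
            elif name.startswith("disutility_"):
                disutilities[name[11:]] = value
            elif name.startswith("teae_"):
                _, arm, event = name.split("_", 2)
                teae[arm][event] = value
            elif name.startswith("mix_"):
                _, arm, regimen = name.split("_", 2)
                mix[arm][regimen] = value
            else:
                raise KeyError(f"unknown model parameter {name!r}")

        # independently perturbed regimen proportions are renormalised so
        # each arm's mix stays a probability vector
        for arm in mix:
            total = sum(mix[arm].values())
            if total > 0:
                mix[arm] = {k: v / total for k, v in mix[arm].items()}

        econ = EconomicInputs(
            unit_costs=unit_costs,
            care_costs=care_costs,
            utilities=utilities,
            disutilities=disutilities,
            teae_incidence=teae,
            bsa_m2=bsa,
            crcl_ml_min=crcl,
            regimen_mix=mix,
            dosing=dict(econ.dosing),
            followup_while_alive=econ.followup_while_alive,
        )
        return replace(
            model,
            pct_os=pct_os,
            pct_pfs=pct_pfs,
            hr_os=hr_os,
            hr_pfs=hr_pfs,
            econ=econ,
            settings=settings,
        )

    # -- evaluation --------------------------------------------------------

    @property
    def cct_os(self) -> WeibullParams:
        return scale_by_hr(self.pct_os, self.hr_os)

    @property
    def cct_pfs(self) -> WeibullParams:
        return scale_by_hr(self.pct_pfs, self.hr_pfs)

    def horizon(self) -> int:
        """Common cycle grid for both arms: the slower-dying arm governs."""
        return max(
            horizon_cycles(self.cct_os, self.settings),
            horizon_cycles(self.pct_os, self.settings),
        )

    def evaluate(self, overrides: dict[str, float] | None = None) -> CEResult:
        model = self.with_overrides(overrides) if overrides else self
        n_cycles = model.horizon()
        # subgroup hazard ratios above 1 let the intervention's PFS curve
        # nose above its OS curve; tolerate and clamp rather than fail
        settings = model.settings.with_(crossing_tolerance=float("inf"))
        cct_trace = build_trace(
            model.cct_os, model.cct_pfs, settings, n_cycles, arm_label="CCT"
        )
        pct_trace = build_trace(
            model.pct_os, model.pct_pfs, settings, n_cycles, arm_label="PCT"
        )
        cct_tot = accrue(cct_trace, model.cct_strategy, model.econ, settings)
        pct_tot = accrue(pct_trace, model.pct_strategy, model.econ, settings)
        return compute_icer(cct_tot, pct_tot)


def base_case_model(**settings_overrides) -> DecisionModel:
    """The whole-population base case; keyword overrides adjust settings."""
    settings = ModelSettings(**settings_overrides) if settings_overrides else ModelSettings()
    return DecisionModel(settings=settings)
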