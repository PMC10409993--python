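"""Deterministic and probabilistic sensitivity analyses.

One-way sensitivity analysis (OWSA) sweeps each parameter to the ends of
its printed range (95% CI where available, otherwise +/-20% of base) with
everything else held at base, producing a tornado table.  Probabilistic
sensitivity analysis (PSA) draws all parameters jointly from assigned
distributions — gamma for costs and clearance, beta for probabilities and
utilities, normal (truncated at zero) for hazard ratios and body surface
area — with the standard deviation recovered from the printed range as
(high - low) / 3.92, i.e. treating it as a 95% interval.  The
cost-effectiveness acceptability curve (CEAC) and the 50%-acceptability
price search both reuse one fixed-seed PSA sample per evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import CEResult
from .model import SUBGROUP_HRS, DecisionModel

logger = logging.getLogger(__name__)

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "SubgroupSpec",
    "table_param_specs",
    "one_way_sa",
    "sample_psa_inputs",
    "run_psa",
    "ceac",
    "threshold_price",
    "run_subgroup",
    "run_all_subgroups",
]

#: a printed (low, high) range is read as a 95% interval: sd = span / 3.92
RANGE_TO_SD = 3.92


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str  # gamma | beta | normal | fixed

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.distribution not in ("gamma", "beta", "normal", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta-distributed values must lie in [0, 1]")
        if self.distribution == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma-distributed values must be >= 0")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / RANGE_TO_SD


def _pm20(name: str, base: float, dist: str = "gamma") -> ParamSpec:
    return ParamSpec(name, base, 0.8 * base, 1.2 * base, dist)


def table_param_specs(model: DecisionModel, include_weibull: bool = True) -> list[ParamSpec]:
    """The full uncertain-parameter table for the given model.

    Ranges follow the base-case table: trial 95% CIs for the hazard
    ratios and TEAE incidences, +/-20% of base elsewhere.  Weibull scale
    and shape parameters of the placebo-arm curves (+/-20%, OWSA only)
    are appended unless ``include_weibull`` is False; they are marked
    ``fixed`` so the PSA leaves them untouched.
    """
    econ = model.econ
    specs: list[ParamSpec] = [
        _pm20("cost_carboplatin", econ.unit_costs["carboplatin"]),
        _pm20("cost_cisplatin", econ.unit_costs["cisplatin"]),
        _pm20("cost_cemiplimab", econ.unit_costs["cemiplimab"]),
        _pm20("cost_pemetrexed", econ.unit_costs["pemetrexed"]),
        _pm20("cost_paclitaxel", econ.unit_costs["paclitaxel"]),
        _pm20("cost_neutropenia", econ.care_costs["neutropenia"]),
        _pm20("cost_anemia", econ.care_costs["anemia"]),
        _pm20("cost_followup_per_cycle", econ.care_costs["followup_per_cycle"]),
        _pm20("cost_end_of_life", econ.care_costs["end_of_life"]),
        _pm20("cost_bsc_per_cycle", econ.care_costs["bsc_per_cycle"]),
        _pm20("teae_CCT_anemia", econ.teae_incidence["CCT"]["anemia"], "beta"),
        _pm20("teae_CCT_neutropenia", econ.teae_incidence["CCT"]["neutropenia"], "beta"),
        _pm20("teae_PCT_anemia", econ.teae_incidence["PCT"]["anemia"], "beta"),
        _pm20("teae_PCT_neutropenia", econ.teae_incidence["PCT"]["neutropenia"], "beta"),
        ParamSpec("hr_os", model.hr_os, 0.53, 0.93, "normal"),
        ParamSpec("hr_pfs", model.hr_pfs, 0.44, 0.70, "normal"),
        _pm20("utility_pfs", econ.utilities["pfs"], "beta"),
        _pm20("utility_pd", econ.utilities["pd"], "beta"),
        _pm20("disutility_neutropenia", econ.disutilities["neutropenia"], "beta"),
        _pm20("disutility_anemia", econ.disutilities["anemia"], "beta"),
        _pm20("bsa", econ.bsa_m2, "normal"),
        _pm20("crcl", econ.crcl_ml_min),
        ParamSpec(
            "discount_rate", model.settings.discount_rate_annual, 0.0, 0.08, "fixed"
        ),
    ]
    for arm, mix in econ.regimen_mix.items():
        for regimen, frac in mix.items():
            specs.append(_pm20(f"mix_{arm}_{regimen}", frac, "beta"))
    if include_weibull:
        specs += [
            _pm20("pct_os_scale", model.pct_os.scale_lambda, "fixed"),
            _pm20("pct_os_shape", model.pct_os.shape_gamma, "fixed"),
            _pm20("pct_pfs_scale", model.pct_pfs.scale_lambda, "fixed"),
            _pm20("pct_pfs_shape", model.pct_pfs.shape_gamma, "fixed"),
        ]
    return specs


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_sa(model: DecisionModel, specs: list[ParamSpec]) -> list[TornadoEntry]:
    """Tornado analysis: each parameter to its low/high ends, others at base.

    Entries are sorted by descending ICER spread.
    """
    entries = []
    for spec in specs:
        lo = model.evaluate({spec.name: spec.low})
        hi = model.evaluate({spec.name: spec.high})
        entries.append(TornadoEntry(spec.name, lo.icer, hi.icer))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def _moment_matched_gamma(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0 or mean == 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return float(rng.gamma(shape, scale))


def _moment_matched_beta(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta moment match infeasible for mean {mean}")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError(f"beta moment match infeasible: variance too large (mean {mean})")
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def sample_psa_inputs(
    specs: list[ParamSpec], rng: np.random.Generator | int
) -> dict[str, float]:
    """Draw one joint parameter sample for a PSA iteration.

    Gamma and beta draws are moment-matched to (base, sd); normal draws
    are truncated at zero (hazard ratios and physical quantities cannot
    go negative); ``fixed`` parameters keep their base value.  Parameters
    are sampled independently.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    out: dict[str, float] = {}
    for spec in specs:
        if spec.distribution == "fixed" or spec.sd == 0:
            out[spec.name] = spec.base
        elif spec.distribution == "gamma":
            out[spec.name] = _moment_matched_gamma(spec.base, spec.sd, rng)
        elif spec.distribution == "beta":
            out[spec.name] = _moment_matched_beta(spec.base, spec.sd, rng)
        else:  # truncated normal
            for _ in range(100):
                draw = float(rng.normal(spec.base, spec.sd))
                if draw > 0:
                    out[spec.name] = draw
                    break
            else:  # pragma: no cover - needs sd >> base
                raise RuntimeError(f"could not draw a positive value for {spec.name}")
    return out


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo sample of incremental (cost, QALY) pairs."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_rejected: int = 0

    @property
    def n_iter(self) -> int:
        return int(self.delta_cost.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iter": np.arange(1, self.n_iter + 1),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def run_psa(
    model: DecisionModel,
    specs: list[ParamSpec] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n_iter`` joint redraws.

    Iterations violating model invariants are rejected and logged; the
    run fails if more than 1% of iterations are rejected.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if specs is None:
        specs = table_param_specs(model, include_weibull=False)
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_iter)
    d_qaly = np.empty(n_iter)
    rejected = 0
    i = 0
    while i < n_iter:
        sample = sample_psa_inputs(specs, rng)
        try:
            res = model.evaluate(sample)
        except (ValueError, KeyError) as err:
            rejected += 1
            logger.warning("PSA iteration rejected: %s", err)
            if rejected > max(10, 0.01 * n_iter):
                raise RuntimeError("more than 1% of PSA iterations failed") from err
            continue
        d_cost[i] = res.delta_cost
        d_qaly[i] = res.delta_qaly
        i += 1
    return PSAResult(d_cost, d_qaly, seed, rejected)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from one PSA sample.

    acceptability(wtp) = fraction of iterations with positive net
    monetary benefit, NMB = wtp * dQALY - dCost.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    nmb = wtp[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp, "probability": prob})


def acceptability_at(psa: PSAResult, wtp: float) -> float:
    nmb = wtp * psa.delta_qaly - psa.delta_cost
    return float((nmb > 0).mean())


def threshold_price(
    model: DecisionModel,
    wtp: float,
    mode: str = "psa50",
    n_iter: int = 1000,
    seed: int = 0,
    tol: float = 0.01,
) -> dict:
    """Cemiplimab price per 100 mg at which CCT becomes cost-effective.

    ``deterministic``: closed-form solve of the affine base-case equation
    ICER(price) = wtp, exploiting linearity of costs in unit prices.
    ``psa50``: bisection on price until probabilistic acceptability at
    ``wtp`` is within ``tol`` of 50% (fixed seed per evaluation).

    Returns a dict with the price, its fraction of the baseline price and
    a status; status ``no_crossing`` means CCT is not cost-effective at
    the threshold even with a free drug.
    """
    base_price = model.econ.unit_costs["cemiplimab"]
    base = model.evaluate()
    if base.icer is not None and base.delta_qaly > 0 and base.icer <= wtp:
        raise ValueError("ICER at the current price is already below the threshold")

    def _result(price: float, status: str = "ok") -> dict:
        return {
            "price_per_100mg": price,
            "fraction_of_baseline": price / base_price if base_price else float("nan"),
            "status": status,
            "mode": mode,
            "wtp": wtp,
        }

    if mode == "deterministic":
        # delta_cost is affine in the price: dC(p) = a + b p
        r0 = model.evaluate({"cost_cemiplimab": 0.0})
        b = (base.delta_cost - r0.delta_cost) / base_price
        a = r0.delta_cost
        d_qaly = base.delta_qaly
        if d_qaly <= 0 or a >= wtp * d_qaly:
            return _result(float("nan"), "no_crossing")
        price = (wtp * d_qaly - a) / b
        return _result(float(price))

    if mode != "psa50":
        raise ValueError(f"unknown mode {mode!r}")
    specs = table_param_specs(model, include_weibull=False)

    def acc(price: float) -> float:
        scaled = [
            ParamSpec(
                s.name,
                s.base * price / base_price,
                s.low * price / base_price,
                s.high * price / base_price,
                s.distribution,
            )
            if s.name == "cost_cemiplimab"
            else s
            for s in specs
        ]
        psa = run_psa(model.with_overrides({"cost_cemiplimab": price}), scaled, n_iter, seed)
        return acceptability_at(psa, wtp)

    lo, hi = 0.0, base_price
    if acc(lo) < 0.5:
        return _result(float("nan"), "no_crossing")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        a_mid = acc(mid)
        if abs(a_mid - 0.5) < tol:
            return _result(float(mid))
        if a_mid > 0.5:
            lo = mid
        else:
            hi = mid
    return _result(float(0.5 * (lo + hi)), "max_iterations")


@dataclass(frozen=True)
class SubgroupSpec:
    """A patient subgroup characterised only by its own hazard ratios."""

    label: str
    hr_pfs: float
    hr_os: float

    def __post_init__(self) -> None:
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError("subgroup hazard ratios must be positive")


def run_subgroup(spec: SubgroupSpec, model: DecisionModel) -> CEResult:
    """Evaluate one subgroup: swap in its hazard ratios, all else at base.

    The placebo-arm Weibull laws are unchanged; the intervention arm is
    re-derived from the subgroup hazard ratios under proportional hazards.
    """
    return model.evaluate({"hr_os": spec.hr_os, "hr_pfs": spec.hr_pfs})


def run_all_subgroups(model: DecisionModel) -> pd.DataFrame:
    """All trial-reported subgroups; mirrors the subgroup HR table."""
    rows = []
    for label, (hr_pfs, hr_os) in SUBGROUP_HRS.items():
        res = run_subgroup(SubgroupSpec(label, hr_pfs, hr_os), model)
        rows.append(
            {
                "subgroup": label,
                "hr_pfs": hr_pfs,
                "hr_os": hr_os,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
                "annotation": res.annotation,
            }
        )
    return pd.DataFrame(rows)
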