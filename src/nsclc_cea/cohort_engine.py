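"""Three-state cohort trace built from one arm's OS and PFS survival laws.

States are progression-free (PFS), progressed (PD) and dead.  Three
constructions are offered:

``markov`` (default)
    A progressive Markov chain: the per-cycle PFS exit probability
    ``1 - S_PFS(t)/S_PFS(t-dt)`` moves patients to PD, and PD occupants
    die at the per-cycle overall-survival probability
    ``1 - S_OS(t)/S_OS(t-dt)``.  Death is reached through progression,
    so cumulative death lags ``1 - S_OS``; this is the bookkeeping that
    reproduces the published per-arm life-years from the published
    Weibull parameters (see docs/methods.md).

``partitioned``
    Partitioned-survival reading: state membership is taken directly off
    the two curves, ``pfs(t) = S_PFS(t)``, ``dead(t) = 1 - S_OS(t)`` and
    ``pd(t) = max(0, S_OS(t) - S_PFS(t))``.  The unique structure fully
    determined by the two published curves.

``state_transition``
    Like ``markov`` but with death anchored to the OS curve: PFS exits
    split between PD and death and the PD -> Death probability is
    calibrated each cycle so cumulative death tracks ``1 - S_OS``
    exactly.  Its death column is identical to ``partitioned``.

The cycle grid is in days (default 21-day cycles, matching a once-every-
3-weeks schedule); survival laws are evaluated in months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .survival_models import DAYS_PER_MONTH, WeibullParams, survival_at

logger = logging.getLogger(__name__)

__all__ = ["ModelSettings", "CohortTrace", "build_trace", "horizon_cycles", "discount_factor"]


@dataclass(frozen=True)
class ModelSettings:
    """Cohort-model conventions.

    cycle_length_days : model cycle, days (21 = one 3-weekly treatment cycle)
    discount_rate_annual : annual discount rate on costs and QALYs
    fraction_dead : horizon rule — stop once this fraction of the cohort died
    max_cycles : hard cap on the number of cycles (~6.9 years at 21 days)
    structure : 'markov', 'partitioned' or 'state_transition'
    half_cycle : accrue on mid-cycle (average of start/end) occupancy
    crossing_tolerance : largest tolerated S_PFS - S_OS excess before erroring
    """

    cycle_length_days: float = 21.0
    discount_rate_annual: float = 0.05
    fraction_dead: float = 0.99
    max_cycles: int = 120
    structure: str = "markov"
    half_cycle: bool = False
    crossing_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if not (0 <= self.discount_rate_annual <= 0.08):
            raise ValueError("discount_rate_annual outside the supported 0-8% range")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.structure not in ("markov", "partitioned", "state_transition"):
            raise ValueError(f"unknown structure {self.structure!r}")

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / 365.25

    def with_(self, **kw) -> "ModelSettings":
        return replace(self, **kw)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy of the three states for one strategy."""

    frame: pd.DataFrame  # columns: cycle, t_months, pfs, pd, dead, newly_dead
    arm_label: str = ""

    def __post_init__(self) -> None:
        f = self.frame
        occ = f[["pfs", "pd", "dead"]].to_numpy()
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("state occupancies must sum to 1 each cycle")
        if np.any((occ < -1e-12) | (occ > 1 + 1e-12)):
            raise ValueError("state occupancies must lie in [0, 1]")
        if np.any(np.diff(f["dead"].to_numpy()) < -1e-12):
            raise ValueError("dead fraction must be non-decreasing")
        if np.any(np.diff(f["pfs"].to_numpy()) > 1e-12):
            raise ValueError("pfs fraction must be non-increasing")
        if abs(f["pfs"].iloc[0] - 1.0) > 1e-12:
            raise ValueError("cohort must start fully progression-free")

    @property
    def n_cycles(self) -> int:
        return len(self.frame) - 1

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def discount_factor(rate_annual: float, t_days) -> np.ndarray | float:
    """Continuous-time compound discount factor (1+r)^(-t/365.25)."""
    if rate_annual < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.asarray(t_days, dtype=float)
    out = (1.0 + rate_annual) ** (-t / 365.25)
    return float(out) if t.ndim == 0 else out


def horizon_cycles(os_params: WeibullParams, settings: ModelSettings) -> int:
    """Number of cycles until the dead-fraction rule fires (or the cap)."""
    t = np.arange(1, settings.max_cycles + 1) * settings.cycle_length_months
    dead = 1.0 - survival_at(os_params, t)
    hit = np.nonzero(dead >= settings.fraction_dead)[0]
    return int(hit[0]) + 1 if hit.size else settings.max_cycles


def build_trace(
    os_params: WeibullParams,
    pfs_params: WeibullParams,
    settings: ModelSettings,
    n_cycles: int | None = None,
    arm_label: str = "",
) -> CohortTrace:
    """Build the per-cycle cohort trace for one strategy.

    ``n_cycles`` overrides the horizon rule so that two arms can be run on
    a common grid (the slower-dying arm's horizon governs a comparison).
    Raises on curve-crossing: S_PFS exceeding S_OS by more than the
    configured tolerance; smaller excesses are clamped into the PD state.
    """
    if n_cycles is None:
        n_cycles = horizon_cycles(os_params, settings)
    t_months = np.arange(n_cycles + 1) * settings.cycle_length_months
    s_os = survival_at(os_params, t_months)
    s_pfs = survival_at(pfs_params, t_months)

    if settings.structure in ("partitioned", "state_transition"):
        # these structures read PD occupancy off S_OS - S_PFS, so the
        # curves must not cross beyond digitization tolerance
        excess = np.max(s_pfs - s_os)
        if excess > settings.crossing_tolerance:
            raise ValueError(
                f"PFS curve exceeds OS curve by {excess:.3g} (> tolerance "
                f"{settings.crossing_tolerance:g}); curves cross"
            )
        if excess > 0:
            logger.info("clamping PFS under OS (max excess %.3g)", excess)
        s_pfs = np.minimum(s_pfs, s_os)

    if settings.structure == "markov":
        pfs = s_pfs.copy()
        pd_state = np.empty(n_cycles + 1)
        dead = np.empty(n_cycles + 1)
        pd_state[0], dead[0] = 0.0, 0.0
        for k in range(1, n_cycles + 1):
            q_exit = 1.0 - (s_pfs[k] / s_pfs[k - 1] if s_pfs[k - 1] > 0 else 1.0)
            q_os = 1.0 - (s_os[k] / s_os[k - 1] if s_os[k - 1] > 0 else 1.0)
            pd_state[k] = pd_state[k - 1] * (1.0 - q_os) + pfs[k - 1] * q_exit
            dead[k] = 1.0 - pfs[k] - pd_state[k]
    elif settings.structure == "partitioned":
        pfs = s_pfs
        dead = 1.0 - s_os
        pd_state = np.maximum(0.0, s_os - s_pfs)
    else:
        pfs = np.empty(n_cycles + 1)
        pd_state = np.empty(n_cycles + 1)
        dead = 1.0 - s_os
        pfs[0], pd_state[0] = 1.0, 0.0
        for k in range(1, n_cycles + 1):
            # exit probability out of PFS over the cycle
            q_exit = 1.0 - (s_pfs[k] / s_pfs[k - 1] if s_pfs[k - 1] > 0 else 1.0)
            # PFS occupants face the OS hazard for the death share of the exit
            q_os = 1.0 - (s_os[k] / s_os[k - 1] if s_os[k - 1] > 0 else 1.0)
            p_pfs_death = min(q_os, q_exit)
            p_pfs_pd = q_exit - p_pfs_death
            deaths_needed = dead[k] - dead[k - 1]
            from_pfs = pfs[k - 1] * p_pfs_death
            if pd_state[k - 1] > 0:
                p_pd_death = np.clip((deaths_needed - from_pfs) / pd_state[k - 1], 0.0, 1.0)
            else:
                p_pd_death = 0.0
                from_pfs = deaths_needed  # all deaths must come from PFS
                p_pfs_death = from_pfs / pfs[k - 1] if pfs[k - 1] > 0 else 0.0
                p_pfs_pd = max(0.0, q_exit - p_pfs_death)
            pfs[k] = pfs[k - 1] * (1.0 - p_pfs_death - p_pfs_pd)
            pd_state[k] = pd_state[k - 1] * (1.0 - p_pd_death) + pfs[k - 1] * p_pfs_pd
        # keep the simplex exact despite clamping
        pd_state = np.maximum(0.0, 1.0 - pfs - dead)

    newly_dead = np.concatenate(([0.0], np.diff(dead)))
    frame = pd.DataFrame(
        {
            "cycle": np.arange(n_cycles + 1),
            "t_months": t_months,
            "pfs": pfs,
            "pd": pd_state,
            "dead": dead,
            "newly_dead": newly_dead,
        }
    )
    return CohortTrace(frame, arm_label)
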