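"""Pseudo-individual patient data from digitized Kaplan-Meier curves.

Published survival figures only show the curve and the numbers-at-risk row
underneath it.  To refit parametric models one needs per-patient
``(time, event)`` records.  This module implements the standard iterative
reconstruction algorithm (Guyot-type): within each numbers-at-risk interval,
censorings are assumed uniformly spread and the integer event counts are
solved so that both the digitized survival drops and the decline in the
at-risk counts are honoured.

Time is measured in months throughout (1 month = 30.4375 days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "PseudoIPD",
    "reconstruct_pseudo_ipd",
    "km_estimate",
]

#: digitized survival values further than this from monotone are suspicious
_CLAMP_WARN = 0.005


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered ``(time, survival)`` coordinates read off a published curve.

    Parameters
    ----------
    times : array of months, strictly increasing, first at >= 0
    survival : array of probabilities in [0, 1], non-increasing
    arm_label : free-text label of the treatment arm
    """

    times: np.ndarray
    survival: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("times and survival must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            idx = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(f"times must be strictly increasing (offending index {idx + 1})")
        if np.any((s < 0) | (s > 1)):
            idx = int(np.argmax((s < 0) | (s > 1)))
            raise ValueError(f"survival values must lie in [0, 1] (offending index {idx})")

    def monotone(self) -> "DigitizedCurve":
        """Return a copy with survival clamped non-increasing (running minimum).

        Digitization jitter can produce tiny upticks; a warning is logged if
        the repair moves any value by more than 0.005.
        """
        s = np.minimum.accumulate(self.survival)
        if np.max(self.survival - s) > _CLAMP_WARN:
            logger.warning(
                "digitized survival for %r clamped by up to %.4f",
                self.arm_label, float(np.max(self.survival - s)),
            )
        return DigitizedCurve(self.times.copy(), s, self.arm_label)

    def require_monotone(self) -> None:
        d = np.diff(self.survival)
        if np.any(d > 1e-12):
            idx = int(np.argmax(d > 1e-12)) + 1
            raise ValueError(f"survival increases at index {idx}; run .monotone() first")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})

    @classmethod
    def from_csv(cls, path, arm_label: str = "") -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["survival"].to_numpy(), arm_label)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RiskTable:
    """Numbers-at-risk row of a published Kaplan-Meier figure."""

    times: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_risk", n)
        if t.ndim != 1 or t.shape != n.shape or t.size == 0:
            raise ValueError("times and n_risk must be equal-length 1-d arrays")
        if t[0] != 0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise ValueError("n_at_risk must be non-negative and non-increasing")

    @property
    def n_initial(self) -> int:
        return int(self.n_risk[0])

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["n_risk"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "n_risk": self.n_risk}).to_csv(path, index=False)


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed per-patient ``(time, event)`` records.

    ``event`` is 1 for an observed event and 0 for a censoring.
    """

    times: np.ndarray
    events: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if np.any(t < 0):
            raise ValueError("event/censoring times must be >= 0")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})

    @classmethod
    def from_csv(cls, path, arm_label: str = "") -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), arm_label)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _spread_censor_times(t_lo: float, t_hi: float, n: int) -> np.ndarray:
    # censorings assumed uniform on the interval: n interior quantile points
    j = np.arange(1, n + 1)
    return t_lo + j * (t_hi - t_lo) / (n + 1)


def reconstruct_pseudo_ipd(curve: DigitizedCurve, risk: RiskTable) -> PseudoIPD:
    """Reconstruct per-patient records from a digitized curve and risk table.

    Within each risk-table interval the number of censorings is initialised
    from the KM identity ``n_{i+1} ≈ n_i * S(t_{i+1})/S(t_i) - events`` and
    refined iteratively until the implied number at risk at the start of the
    next interval matches the published one.  Event counts at each digitized
    time are the integer-rounded product-limit drops.  Deterministic for
    fixed inputs.

    Returns one record per initially-at-risk patient: events at digitized
    drop times, censorings spread uniformly within their interval, and all
    patients still at risk at the last digitized time censored there.
    """
    curve = curve.monotone()
    curve.require_monotone()
    if risk.times[0] != 0:
        raise ValueError("risk table must start at time 0")

    t_s = curve.times.copy()
    s = curve.survival.copy()
    if t_s[0] > 0:  # anchor the curve at (0, 1)
        t_s = np.insert(t_s, 0, 0.0)
        s = np.insert(s, 0, 1.0)

    # risk entries beyond the digitized span carry no usable information
    keep = risk.times <= t_s[-1] + 1e-12
    risk_times = risk.times[keep]
    n_risk = risk.n_risk[keep].astype(int).copy()

    # Interval i spans (risk_times[i], risk_times[i+1]]: a curve drop printed
    # exactly at a risk-table time represents events just before it, who are
    # no longer in the published at-risk count, so boundary points belong to
    # the interval they close.
    n_int = len(risk_times)
    n_t = len(t_s)
    limits = np.searchsorted(t_s, risk_times, side="right")
    ends = np.append(limits[1:], n_t)   # interval i covers limits[i] .. ends[i]-1

    d = np.zeros(n_t, dtype=int)        # events at each digitized time
    cen = np.zeros(n_t, dtype=int)      # censorings in (t_s[k-1], t_s[k]]
    km_hat = np.ones(n_t)
    n_censor = np.zeros(n_int, dtype=int)
    last_i = np.zeros(n_int, dtype=int)  # index of last event before interval i
    n_end = np.zeros(n_int, dtype=float)  # at-risk after processing interval i

    def _run_interval(i: int) -> int:
        """Propagate events/censorings through interval i; return last event idx."""
        cur = float(n_risk[i])
        last = last_i[i]
        for k in range(limits[i], ends[i]):
            ref = km_hat[last]
            d[k] = int(round(cur * (1.0 - s[k] / ref))) if ref > 0 and cur > 0 else 0
            d[k] = max(0, min(d[k], int(cur)))
            km_hat[k] = ref * (1.0 - d[k] / cur) if cur > 0 else 0.0
            cur -= d[k] + cen[k]
            if d[k] != 0:
                last = k
        n_end[i] = cur
        return last

    def _place_censorings(i: int, n_c: int) -> None:
        """Spread n_c censor times uniformly over interval i's time span."""
        t_lo = risk_times[i]
        t_hi = risk_times[i + 1] if i + 1 < n_int else t_s[-1]
        cen[limits[i]: ends[i]] = 0
        if n_c > 0 and ends[i] > limits[i]:
            ct = _spread_censor_times(t_lo, t_hi, n_c)
            # censorings in (t_s[k-1], t_s[k]] are booked at curve index k
            idx = np.searchsorted(t_s, ct, side="left")
            for j in np.clip(idx, limits[i], ends[i] - 1):
                cen[j] += 1

    for i in range(n_int - 1):
        s_start = s[limits[i] - 1]
        s_end = s[ends[i] - 1]
        guess = n_risk[i] * (s_end / s_start if s_start > 0 else 0.0) - n_risk[i + 1]
        n_censor[i] = max(0, int(round(guess)))
        while True:
            _place_censorings(i, n_censor[i])
            last = _run_interval(i)
            diff = int(round(n_end[i] - n_risk[i + 1]))
            if diff == 0 or (diff < 0 and n_censor[i] <= 0):
                break
            n_censor[i] += diff
            if n_censor[i] < 0:
                n_censor[i] = 0
        if n_end[i] < n_risk[i + 1]:
            n_risk[i + 1] = int(n_end[i])
        last_i[i + 1] = last

    # last interval: no at-risk anchor beyond the curve; assume the censoring
    # rate observed over the earlier intervals continues
    i = n_int - 1
    if n_int > 1 and risk_times[i] > risk_times[0]:
        rate = n_censor[:i].sum() / (risk_times[i] - risk_times[0])
        n_censor[i] = min(int(round(rate * (t_s[-1] - risk_times[i]))), int(n_risk[i]))
    else:
        n_censor[i] = 0
    _place_censorings(i, max(0, n_censor[i]))
    _run_interval(i)

    # assemble records; anyone still at risk after the last digitized time
    # is administratively censored there
    times, events = [], []
    for k in range(n_t):
        times.extend([t_s[k]] * d[k])
        events.extend([1] * d[k])
        if cen[k] > 0:
            t_lo = t_s[k - 1] if k > 0 else 0.0
            ct = _spread_censor_times(t_lo, t_s[k], cen[k])
            times.extend(ct.tolist())
            events.extend([0] * cen[k])
    n_left = risk.n_initial - len(times)
    if n_left < 0:
        raise RuntimeError("reconstruction produced more records than patients")
    times.extend([t_s[-1]] * n_left)
    events.extend([0] * n_left)

    order = np.argsort(times, kind="stable")
    return PseudoIPD(np.asarray(times)[order], np.asarray(events)[order], curve.arm_label)


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Product-limit estimate of a pseudo-IPD set, as a step curve.

    Returns the curve sampled at time 0 and at every distinct event time
    (the points where the step function drops).
    """
    if len(ipd) == 0:
        raise ValueError("cannot estimate a survival curve from zero records")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    event_times = np.unique(ipd.times[ipd.events == 1])
    grid = np.concatenate(([0.0], event_times))
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return DigitizedCurve(grid, surv, ipd.arm_label)
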