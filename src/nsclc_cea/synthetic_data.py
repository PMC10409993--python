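"""Trial-like synthetic survival data with known ground truth.

Simulates per-patient event times from a Weibull law (inverse-transform
sampling), applies independent exponential dropout and administrative
censoring, then emulates manual curve digitization: the Kaplan-Meier
estimate is extracted at its step corners (what an operator clicks) with
coordinates rounded to a fixed number of decimals, alongside a coarser
numbers-at-risk row.
Defaults mirror the placebo-chemotherapy arm of the trial the model is
built on: Weibull OS (lambda 0.030040, gamma 1.213530) and PFS
(lambda 0.061800, gamma 1.388300) on a monthly scale, 154 patients,
24 months of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .km_reconstruction import DigitizedCurve, PseudoIPD, RiskTable
from .model import PCT_OS, PCT_PFS
from .survival_models import WeibullParams

__all__ = ["SimSpec", "simulate_trial", "digitize"]


@dataclass(frozen=True)
class SimSpec:
    """Ground truth and digitization settings for one synthetic arm.

    dropout_rate is a per-month exponential censoring rate;
    admin_censor_time truncates follow-up; digitize_grid is the spacing
    (months) of the extracted curve coordinates; risk_interval is the
    coarser spacing of the numbers-at-risk row (published figures print
    at-risk counts every few months under a much denser curve);
    coord_decimals rounds the extracted survival probabilities.
    """

    true_os: WeibullParams = PCT_OS
    true_pfs: WeibullParams = PCT_PFS
    n_per_arm: int = 154
    admin_censor_time: float = 24.0
    dropout_rate: float = 0.01
    digitize_grid: float = 1.0
    risk_interval: float = 3.0
    coord_decimals: int = 3
    jitter: float = 0.0  # optional uniform digitization noise half-width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 10:
            raise ValueError("n_per_arm must be >= 10")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")
        if self.digitize_grid <= 0:
            raise ValueError("digitize_grid must be positive")
        if self.risk_interval < self.digitize_grid:
            raise ValueError("risk_interval must be at least the digitization grid")


def _draw_weibull(params: WeibullParams, n: int, rng: np.random.Generator) -> np.ndarray:
    # inverse transform: S(t) = u  =>  t = (-ln u / lambda)^(1/gamma)
    u = rng.uniform(size=n)
    return (-np.log(u) / params.scale_lambda) ** (1.0 / params.shape_gamma)


def simulate_trial(
    spec: SimSpec, endpoint: str = "os", arm_label: str = "PCT"
) -> PseudoIPD:
    """Simulate one arm's per-patient records for one endpoint.

    Event times are Weibull draws from the requested true law; censoring
    is the minimum of an exponential dropout time and the administrative
    cut-off.  Reproducible for a fixed ``spec.seed`` (the endpoint name
    enters the stream so OS and PFS are independent draws).
    """
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    params = spec.true_os if endpoint == "os" else spec.true_pfs
    rng = np.random.default_rng([spec.seed, 0 if endpoint == "os" else 1])
    t_event = _draw_weibull(params, spec.n_per_arm, rng)
    if spec.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / spec.dropout_rate, size=spec.n_per_arm)
    else:
        t_drop = np.full(spec.n_per_arm, np.inf)
    t_censor = np.minimum(t_drop, spec.admin_censor_time)
    times = np.minimum(t_event, t_censor)
    events = (t_event <= t_censor).astype(int)
    return PseudoIPD(times, events, arm_label)


def digitize(ipd: PseudoIPD, spec: SimSpec) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate manual extraction of a published Kaplan-Meier figure.

    An operator digitizing a published figure clicks every visible step
    corner, so the extracted time coordinates sit at the curve's drop
    times; anchor points every ``digitize_grid`` months mark flat
    stretches.  Both coordinates are rounded to ``coord_decimals``; the
    numbers-at-risk are counted at multiples of ``risk_interval``.
    Optional uniform jitter emulates imperfect pointing.
    """
    if spec.digitize_grid > spec.admin_censor_time:
        raise ValueError("digitization grid is coarser than the follow-up window")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    t_max = min(float(ipd.times.max()), spec.admin_censor_time)
    anchors = np.arange(0.0, t_max + 1e-9, spec.digitize_grid)
    drops = np.unique(ipd.times[(ipd.events == 1) & (ipd.times <= t_max)])
    ts = np.unique(np.concatenate([anchors, drops]))
    surv = kmf.survival_function_at_times(ts).to_numpy()
    # round the clicked coordinates; collisions keep the post-drop value
    grid = np.round(ts, spec.coord_decimals)
    keep = np.append(grid[1:] != grid[:-1], True)
    grid, surv = grid[keep], np.minimum.accumulate(surv)[keep]
    if spec.jitter > 0:
        rng = np.random.default_rng([spec.seed, 2])
        surv = np.clip(surv + rng.uniform(-spec.jitter, spec.jitter, surv.size), 0, 1)
        surv = np.minimum.accumulate(surv)
        surv[0] = 1.0
    surv = np.round(surv, spec.coord_decimals)
    curve = DigitizedCurve(grid, surv, ipd.arm_label)

    risk_times = np.arange(0.0, t_max + 1e-9, spec.risk_interval)
    n_risk = np.array([(ipd.times >= t - 1e-12).sum() for t in risk_times], dtype=int)
    risk = RiskTable(risk_times, n_risk)
    return curve, risk
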