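"""Synthetic single-arm trial data and fabricated expert consensus values.

The reference individual-patient dataset (a phase-2 CAR T trial in
relapsed/refractory multiple myeloma, N = 140, ~11-13 months median and 22.6
months maximum follow-up) is available only on request from its sponsor, so
everything here emulates its observable shape with a known ground truth:
staggered enrollment over an accrual window, administrative censoring at a
database-lock date, optional exponential loss to follow-up, and consensus
(LPL, MLV, UPL) triplets fabricated from the true survival curve at the 3/5/
10-year elicitation horizons.

All datasets produced here are synthetic stand-ins; no clinical values beyond
the published trial-design features (N, follow-up shape, elicited ranges) are
encoded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import families
from .elicitation import ElicitedTimePoint
from .families import ParameterVector, params
from .joint_model import IPDDataset

__all__ = [
    "TrialScenario",
    "ExpertScenario",
    "simulate_trial",
    "simulate_expert_consensus",
    "karmma_like_fixture",
    "KARMMA_N",
    "KARMMA_CUTOFF_YEARS",
]

#: Trial-design features of the emulated phase-2 study.
KARMMA_N = 140
KARMMA_ACCRUAL_YEARS = 1.0
KARMMA_CUTOFF_YEARS = 22.6 / 12.0


@dataclass(frozen=True)
class TrialScenario:
    """Design of one simulated single-arm trial (times in years).

    ``accrual`` chooses how enrollment times fill the accrual window:
    ``"random"`` draws them uniformly; ``"grid"`` spaces them evenly from 0
    to the window end, so the first subject's administrative censoring time
    equals the full data cutoff.
    """

    truth: ParameterVector
    n: int = KARMMA_N
    accrual_window: float = KARMMA_ACCRUAL_YEARS
    data_cutoff: float = KARMMA_CUTOFF_YEARS
    dropout_rate: float = 0.0
    seed: int = 0
    accrual: str = "random"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.accrual_window < 0:
            raise ValueError("accrual_window must be >= 0")
        if self.data_cutoff <= 0:
            raise ValueError("data_cutoff must be > 0")
        if self.data_cutoff <= self.accrual_window:
            raise ValueError("data_cutoff must exceed the accrual window")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")
        if self.accrual not in ("random", "grid"):
            raise ValueError("accrual must be 'random' or 'grid'")


@dataclass(frozen=True)
class ExpertScenario:
    """How to fabricate consensus triplets from a known survival curve.

    MLV = true S(t_E) plus ``bias``, rounded to the ``rounding`` grid and
    clipped to [0, 1]; the plausible interval has the per-horizon ``widths``,
    shifted (not shrunk) when clipping at 0 or 1 would otherwise narrow it,
    and repaired to a minimum width of 0.01.
    """

    horizons: tuple = (3.0, 5.0, 10.0)
    bias: float = 0.0
    widths: tuple = (0.10, 0.10, 0.05)
    rounding: float = 0.05

    def __post_init__(self):
        if len(self.widths) != len(self.horizons):
            raise ValueError("need one width per horizon")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if not 0 < self.rounding <= 0.5:
            raise ValueError("rounding grid must lie in (0, 0.5]")


def simulate_trial(scenario: TrialScenario) -> IPDDataset:
    """Simulate one single-arm trial under administrative censoring.

    Event times are drawn from the true family; each subject's censoring time
    is min(data_cutoff - enrollment, dropout draw); the observed time is
    min(event, censoring) with the event flag set accordingly.  Deterministic
    given ``scenario.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 9001]))
    n = scenario.n
    if scenario.accrual == "grid":
        enroll = (
            np.linspace(0.0, scenario.accrual_window, n)
            if n > 1
            else np.array([0.0])
        )
    else:
        enroll = rng.uniform(0.0, scenario.accrual_window, size=n)
    admin = scenario.data_cutoff - enroll
    event_times = families.sample_event_times(scenario.truth, n, rng)
    if scenario.dropout_rate > 0:
        dropout = rng.exponential(1.0 / scenario.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(admin, dropout)
    observed = np.minimum(event_times, censor)
    events = (event_times <= censor).astype(np.int64)
    if events.sum() == 0:
        warnings.warn(
            "scenario produced no observed events; the likelihood cannot "
            "identify the time scale",
            stacklevel=2,
        )
    return IPDDataset(
        times=observed, events=events, time_unit="years", require_events=False
    )


def _round_to_grid(x: float, grid: float) -> float:
    return float(np.clip(np.round(x / grid) * grid, 0.0, 1.0))


def simulate_expert_consensus(
    truth: ParameterVector, es: ExpertScenario = ExpertScenario()
) -> list:
    """Fabricate consensus (LPL, MLV, UPL) triplets from the true curve.

    The 10-year boundary case is preserved: a true survival that rounds to 0
    yields MLV = LPL = 0 with the interval extending upward.
    """
    points = []
    for t_E, width in zip(es.horizons, es.widths):
        s = float(families.survival(truth, t_E))
        mlv = _round_to_grid(s + es.bias, es.rounding)
        lpl = mlv - width / 2.0
        upl = mlv + width / 2.0
        # shift, don't shrink, when the interval spills out of [0, 1]
        if lpl < 0.0:
            upl = min(1.0, upl - lpl)
            lpl = 0.0
        if upl > 1.0:
            lpl = max(0.0, lpl - (upl - 1.0))
            upl = 1.0
        if upl - lpl < 0.01:
            upl = min(1.0, lpl + 0.01)
        points.append(ElicitedTimePoint(t_E=float(t_E), LPL=lpl, MLV=mlv, UPL=upl))
    return points


#: Ground truth used by the packaged fixture: near-exponential Weibull whose
#: 3/5/10-year survival (0.300, 0.137, 0.020) sits inside the published
#: consensus MLV ranges (25-35%, 5-20%, 0-5%).
_FIXTURE_TRUTH = ("weibull", 0.98, 0.41013)


def karmma_like_fixture(seed: int = 0, max_attempts: int = 50) -> dict:
    """A packaged trial + consensus scenario emulating the reference study.

    Returns ``{"data": IPDDataset, "elicited": [ElicitedTimePoint, ...],
    "truth": ParameterVector, "scenario": TrialScenario}`` where the realized
    dataset has exactly 140 subjects, maximum follow-up exactly 22.6 months
    (first-enrolled subject administratively censored), median follow-up in
    [10, 14] months, and an event fraction in [0.35, 0.65].  Sub-seeds are
    derived deterministically from ``seed``; scenario realizations violating
    the calibration targets are discarded and redrawn, up to ``max_attempts``.
    """
    truth = params(*_FIXTURE_TRUTH)
    for attempt in range(max_attempts):
        sub_seed = int(
            np.random.SeedSequence([int(seed), attempt]).generate_state(1)[0]
            % (2**31)
        )
        scenario = TrialScenario(truth=truth, seed=sub_seed, accrual="grid")
        data = simulate_trial(scenario)
        max_months = float(data.times.max()) * 12.0
        median_months = float(np.median(data.times)) * 12.0
        event_frac = data.n_events / len(data)
        if (
            len(data) == scenario.n
            and np.isclose(max_months, 22.6, atol=1e-9)
            and 10.0 <= median_months <= 14.0
            and 0.35 <= event_frac <= 0.65
        ):
            elicited = simulate_expert_consensus(truth)
            return {
                "data": data,
                "elicited": elicited,
                "truth": truth,
                "scenario": scenario,
            }
    raise RuntimeError(
        f"could not realize a calibrated fixture in {max_attempts} attempts "
        f"from seed {seed}"
    )
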