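"""Joint log posterior: censored-data likelihood, expert constraints, priors.

The model combines, up to a normalizing constant,

    log p(theta | T, delta, Y) = sum_i [ delta_i log f(T_i | theta)
                                       + (1 - delta_i) log S(T_i | theta) ]
                               + sum_j log d(Y_j | theta)
                               + log p(theta)

where the first sum is the right-censored individual-patient-data likelihood,
the second the truncated-normal expert-constraint density with mean tied to
model survival at each elicited horizon, and p(theta) the prior.  Priors
follow the by-domain rule: strictly positive parameters get a Gamma(shape,
rate) prior (default the approximately non-informative Gamma(1e-3, 1e-3));
real-valued parameters get a Normal(mean, precision) prior (default
Normal(0, tau = 1e-3)).
"""

from __future__ import annotations

import hashlib
from dataclasses import InitVar, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .elicitation import ElicitationSet, expert_log_likelihood
from .families import DomainError, ParameterVector, log_pdf, log_sf

__all__ = [
    "IPDRecord",
    "IPDDataset",
    "PriorSpec",
    "ipd_log_likelihood",
    "log_prior",
    "log_prior_values",
    "log_posterior",
]


@dataclass(frozen=True)
class IPDRecord:
    """One subject: positive follow-up time and event indicator (1 = death)."""

    time: float
    event: int

    def __post_init__(self):
        if not self.time > 0:
            raise ValueError(
                f"follow-up time must be > 0, got {self.time}; zero times should "
                "be offset by half the smallest recorded time resolution"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class IPDDataset:
    """Individual-patient survival data; times in years internally.

    ``require_events=False`` permits an all-censored table (useful for
    evaluating the likelihood on boundary cases); model fitting requires at
    least one observed event to identify the time scale.
    """

    times: np.ndarray
    events: np.ndarray
    time_unit: str = "years"
    require_events: InitVar[bool] = True

    def __post_init__(self, require_events: bool = True):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int64))
        if self.time_unit not in ("years", "months"):
            raise ValueError(f"unknown time_unit {self.time_unit!r}")
        if times.ndim != 1 or times.shape != events.shape:
            raise ValueError("times and events must be matching 1-d arrays")
        if times.size < 1:
            raise ValueError("dataset must contain at least one record")
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            bad = int(np.flatnonzero(~np.isfinite(times) | (times <= 0))[0])
            raise ValueError(
                f"row {bad}: follow-up time must be finite and > 0 "
                f"(got {times[bad]}); offset zero times by half the smallest "
                "time resolution"
            )
        if not np.isin(events, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(events, (0, 1)))[0])
            raise ValueError(f"row {bad}: event indicator must be 0 or 1, got {events[bad]}")
        if require_events and self.events.sum() < 1:
            raise ValueError("dataset must contain at least one observed event")

    def __len__(self):
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.events == 1]

    @property
    def censor_times(self) -> np.ndarray:
        return self.times[self.events == 0]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.times).tobytes())
        h.update(np.ascontiguousarray(self.events).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})

    @classmethod
    def from_records(cls, records, time_unit: str = "years") -> "IPDDataset":
        recs = list(records)
        times = np.array([r.time for r in recs], dtype=float)
        events = np.array([r.event for r in recs], dtype=np.int64)
        return cls(times=times, events=events, time_unit=time_unit)

    @classmethod
    def from_csv(cls, path, time_unit: str = "years") -> "IPDDataset":
        """Load a `time,event` CSV; months are converted to years on load."""
        path = Path(path)
        df = pd.read_csv(path, comment="#")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        times = df["time"].to_numpy(dtype=float)
        if time_unit == "months":
            times = times / 12.0
        elif time_unit != "years":
            raise ValueError(f"unknown time_unit {time_unit!r}")
        return cls(times=times, events=df["event"].to_numpy(), time_unit="years")


@dataclass(frozen=True)
class PriorSpec:
    """By-domain priors: Gamma(shape, rate) for positive parameters,
    Normal(mean, precision) for real-valued ones.

    ``overrides`` maps a parameter name to ``("gamma", shape, rate)`` or
    ``("normal", mean, precision)`` to replace the default for that parameter
    (e.g. to place the gamma prior on a lognormal precision rather than on
    sigma itself).
    """

    gamma_shape: float = 1e-3
    gamma_rate: float = 1e-3
    normal_mean: float = 0.0
    normal_precision: float = 1e-3
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma prior shape and rate must be > 0")
        if self.normal_precision <= 0:
            raise ValueError("normal prior precision must be > 0")

    def spec_for(self, name: str, domain: str) -> tuple:
        if name in self.overrides:
            return tuple(self.overrides[name])
        if domain == "positive":
            return ("gamma", self.gamma_shape, self.gamma_rate)
        return ("normal", self.normal_mean, self.normal_precision)


_LOG_2PI = float(np.log(2.0 * np.pi))


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -np.inf
    return (
        shape * np.log(rate)
        - float(special.gammaln(shape))
        + (shape - 1.0) * np.log(x)
        - rate * x
    )


def _log_normal_pdf(x: float, mean: float, precision: float) -> float:
    return 0.5 * (np.log(precision) - _LOG_2PI) - 0.5 * precision * (x - mean) ** 2


def ipd_log_likelihood(theta: ParameterVector, data: IPDDataset) -> float:
    """Right-censored log likelihood: events contribute log f, censored log S."""
    ll = 0.0
    ev = data.event_times
    ce = data.censor_times
    if ev.size:
        ll += float(np.sum(log_pdf(theta.family, theta.array, ev)))
    if ce.size:
        ll += float(np.sum(log_sf(theta.family, theta.array, ce)))
    return ll


def log_prior(theta: ParameterVector, priors: PriorSpec = PriorSpec()) -> float:
    """Sum of per-parameter log prior densities on the natural scale.

    A positive-domain value at or below zero yields -inf (a rejected state),
    not an exception, so samplers can treat it as a zero-probability proposal.
    """
    return log_prior_values(theta.family, theta.values, priors)


def log_prior_values(family, values, priors: PriorSpec = PriorSpec()) -> float:
    """Like :func:`log_prior` but on raw values, without domain validation:
    out-of-domain values return -inf rather than raising."""
    from .families import family_spec

    spec = family_spec(family)
    total = 0.0
    for name, domain, value in zip(spec.param_names, spec.param_domains, values):
        kind, p1, p2 = priors.spec_for(name, domain)
        if kind == "gamma":
            term = _log_gamma_pdf(value, p1, p2)
        elif kind == "normal":
            term = _log_normal_pdf(value, p1, p2)
        else:
            raise ValueError(f"unknown prior kind {kind!r} for parameter {name!r}")
        if term == -np.inf:
            return -np.inf
        total += term
    return float(total)


def log_posterior(
    theta: ParameterVector,
    data: IPDDataset,
    constraints: ElicitationSet = ElicitationSet(),
    priors: PriorSpec = PriorSpec(),
    include_truncation_constant: bool = True,
) -> float:
    """Unnormalized joint log posterior of the constrained survival model.

    With an empty constraint set this is exactly the standard right-censored
    posterior.  NaN in any component raises with the component named; -inf is
    a legitimate rejected state and propagates.
    """
    parts = {
        "ipd_log_likelihood": ipd_log_likelihood(theta, data),
        "expert_log_likelihood": expert_log_likelihood(
            theta, constraints, include_truncation_constant
        ),
        "log_prior": log_prior(theta, priors),
    }
    for name, value in parts.items():
        if np.isnan(value) or value == np.inf:
            raise DomainError(
                f"non-finite {name} ({value}) at theta = {theta.as_dict()}"
            )
    return float(sum(parts.values()))
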