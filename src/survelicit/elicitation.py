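"""Expert-elicited survival constraints as truncated-normal densities.

Structured elicitation (SHELF-style) yields, at each horizon t_E, a lower
plausible limit (LPL), most likely value (MLV) and upper plausible limit
(UPL) for the survival probability S(t_E).  These are converted into the
"observation" of a normal distribution truncated to [0, 1]:

    Y_j ~ N(mu_j, sigma_j^2) truncated to [0, 1],   y_j = MLV_j,

with the plausible limits read as the 1st and 99th percentiles of the
untruncated normal, so that

    sigma_j = (UPL_j - LPL_j) / (2 z_0.99),   z_0.99 = Phi^{-1}(0.99).

At fit time the mean mu_j is tied to the survival model, mu_j = S(t_Ej,
theta), so each elicited horizon contributes log d(y_j | theta) to the joint
log posterior.  The truncation is to the *closed* unit interval: an elicited
MLV of exactly 0 (e.g. 10-year survival judged implausible) retains positive
density.  The theta-dependent truncation normalization Phi((1-mu)/sigma) -
Phi((0-mu)/sigma) is included by default; ``include_truncation_constant=False``
exposes the unnormalized kernel for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import special

from .families import ParameterVector, log_sf

__all__ = [
    "Z99",
    "ElicitedTimePoint",
    "ExpertConstraint",
    "ElicitationSet",
    "constraint_from_elicitation",
    "truncnorm_log_density",
    "expert_log_likelihood",
    "load_elicitation",
]

#: 99th percentile of the standard normal; the elicited plausible limits are
#: read as the 1st/99th percentiles of the pre-truncation normal.
Z99 = float(special.ndtri(0.99))

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ElicitedTimePoint:
    """Raw elicited triplet at one horizon (all probabilities on [0, 1])."""

    t_E: float
    LPL: float
    MLV: float
    UPL: float
    label: str = "consensus"

    def __post_init__(self):
        if self.t_E <= 0:
            raise ValueError(f"horizon must be positive, got {self.t_E}")
        if not (0.0 <= self.LPL <= self.MLV <= self.UPL <= 1.0):
            raise ValueError(
                f"elicited quantiles out of order at t={self.t_E}: "
                f"need 0 <= LPL <= MLV <= UPL <= 1, got "
                f"LPL={self.LPL}, MLV={self.MLV}, UPL={self.UPL}"
            )
        if self.UPL == self.LPL:
            raise ValueError(
                f"zero-width plausible interval at t={self.t_E}: UPL must exceed LPL"
            )


@dataclass(frozen=True)
class ExpertConstraint:
    """One elicited horizon reduced to its (t_E, y, sigma) constraint form.

    ``y`` is the observed MLV; ``sigma`` the standard deviation of the
    pre-truncation normal.  The mean is not stored: it is S(t_E, theta).
    """

    t_E: float
    y: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0.0 <= self.y <= 1.0):
            raise ValueError(f"y must lie in [0, 1], got {self.y}")
        if self.t_E <= 0:
            raise ValueError(f"horizon must be positive, got {self.t_E}")


@dataclass(frozen=True)
class ElicitationSet:
    """Ordered collection of expert constraints; horizons strictly increasing."""

    constraints: tuple = ()

    def __post_init__(self):
        cs = tuple(self.constraints)
        object.__setattr__(self, "constraints", cs)
        horizons = [c.t_E for c in cs]
        if any(b <= a for a, b in zip(horizons, horizons[1:])):
            raise ValueError(f"horizons must be strictly increasing, got {horizons}")

    def __len__(self):
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    @property
    def horizons(self) -> np.ndarray:
        return np.array([c.t_E for c in self.constraints])

    @property
    def y(self) -> np.ndarray:
        return np.array([c.y for c in self.constraints])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([c.sigma for c in self.constraints])

    @classmethod
    def from_elicited(cls, points) -> "ElicitationSet":
        return cls(tuple(constraint_from_elicitation(p) for p in points))


def constraint_from_elicitation(e: ElicitedTimePoint) -> ExpertConstraint:
    """Map an (LPL, MLV, UPL) triplet to its truncated-normal constraint.

    The MLV is the mode of the consensus distribution, operationalized as the
    mean of the pre-truncation normal; the interval width spans the 1st to
    99th percentiles, giving sigma = (UPL - LPL) / (2 z_0.99).  Asymmetric
    triplets are accepted: only the width informs sigma.
    """
    sigma = (e.UPL - e.LPL) / (2.0 * Z99)
    return ExpertConstraint(t_E=e.t_E, y=e.MLV, sigma=sigma)


def _log_gauss_mass(a, b):
    """log(Phi(b) - Phi(a)) computed stably in the left tail."""
    a, b = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float))
    flip = a + b > 0.0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    log_hi = special.log_ndtr(hi)
    log_lo = special.log_ndtr(lo)
    with np.errstate(divide="ignore"):
        out = log_hi + np.log1p(-np.exp(log_lo - log_hi))
    return out


def truncnorm_log_density(y, mu, sigma, include_truncation_constant: bool = True):
    """Log density at y of N(mu, sigma^2) truncated to the unit interval.

    Vectorizes over ``mu`` (and ``y``/``sigma`` if arrays).  The truncation
    normalization depends on mu, hence on the survival parameters when mu is
    tied to S(t_E, theta); it is included unless switched off.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    if np.any((y < 0.0) | (y > 1.0)):
        raise ValueError("y must lie in the closed interval [0, 1]")
    z = (y - mu) / sigma
    out = -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI
    if include_truncation_constant:
        out = out - _log_gauss_mass((0.0 - mu) / sigma, (1.0 - mu) / sigma)
    return out if out.ndim else float(out)


def expert_log_likelihood(
    theta: ParameterVector,
    constraints: ElicitationSet,
    include_truncation_constant: bool = True,
) -> float:
    """Joint log density of the elicited MLVs given survival parameters theta.

    Sum over horizons of the truncated-normal log density with mean
    mu_j = S(t_Ej, theta).  An empty constraint set contributes 0, recovering
    the data-only model.
    """
    if len(constraints) == 0:
        return 0.0
    mu = np.exp(log_sf(theta.family, theta.array, constraints.horizons))
    vals = truncnorm_log_density(
        constraints.y, mu, constraints.sigma, include_truncation_constant
    )
    return float(np.sum(vals))


def _parse_point(entry: dict, index: int) -> ElicitedTimePoint:
    required = {"time", "lpl", "mlv", "upl"}
    missing = required - set(entry)
    if missing:
        raise ValueError(f"elicitation entry {index}: missing keys {sorted(missing)}")
    unit = entry.get("time_unit", "years")
    if unit not in ("years", "months"):
        raise ValueError(f"elicitation entry {index}: unknown time_unit {unit!r}")
    t = float(entry["time"])
    if unit == "months":
        t = t / 12.0
    try:
        return ElicitedTimePoint(
            t_E=t,
            LPL=float(entry["lpl"]),
            MLV=float(entry["mlv"]),
            UPL=float(entry["upl"]),
            label=str(entry.get("label", "consensus")),
        )
    except ValueError as exc:
        raise ValueError(f"elicitation entry {index}: {exc}") from exc


def load_elicitation(path) -> tuple:
    """Load elicited time points from a JSON or YAML file.

    The file holds a list of ``{time, time_unit, lpl, mlv, upl, label}``
    mappings (time_unit defaults to years).  Returns a tuple of
    :class:`ElicitedTimePoint`, validated entry by entry with the offending
    entry index in any error message.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if isinstance(raw, dict) and "elicitation" in raw:
        raw = raw["elicitation"]
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a list of elicited time points")
    points = tuple(_parse_point(entry, i) for i, entry in enumerate(raw))
    if any(b.t_E <= a.t_E for a, b in zip(points, points[1:])):
        raise ValueError(f"{path}: horizons must be strictly increasing")
    return points
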