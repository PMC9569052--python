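"""The seven parametric survival families used for extrapolation.

Each family is defined by its survival function S(t, theta) = 1 - F(t, theta)
and density f(t, theta), parameterized on the natural scale (canonical time
unit: years).  The parameterizations are:

=============  =========================  ============================================
family         parameters (domain)        survival function
=============  =========================  ============================================
exponential    rate λ (+)                 exp(-λ t)
weibull        shape v (+), rate λ (+)    exp(-λ t^v)
gompertz       shape a (R), rate b (+)    exp(-(b/a) (e^{a t} - 1))
lognormal      meanlog μ (R), sdlog σ(+)  1 - Φ((log t - μ) / σ)
loglogistic    shape β (+), scale α (+)   1 / (1 + (t/α)^β)
gamma          shape k (+), rate r (+)    Γ_u(k, r t) / Γ(k)
gengamma       shape r (+), rate λ (+),   Γ_u(r, (λ t)^b) / Γ(r)
               power b (+)
=============  =========================  ============================================

where Γ_u is the upper incomplete gamma function.  The generalized gamma is in
the Stacy form, which nests the gamma (b = 1), the Weibull (r = 1, with shape
b and rate λ^b), and the exponential (r = b = 1).  The Gompertz shape may be
negative, in which case survival plateaus at exp(b/a) (a cure fraction); the
a → 0 limit reduces to the exponential and is evaluated by series expansion
for |a| < 1e-6.

Low-level functions (``log_sf``, ``log_pdf``) broadcast over parameter draws:
``values`` may be a single vector of length ``n_params`` or an array of shape
``(n_draws, n_params)``, and ``t`` a scalar or 1-d grid, producing a
``(n_draws, n_times)`` surface.  This is the evaluation path used by both the
MCMC sampler and the posterior survival-curve summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "DomainError",
    "FamilySpec",
    "ParameterVector",
    "FAMILIES",
    "FAMILY_NAMES",
    "family_spec",
    "params",
    "log_sf",
    "log_pdf",
    "survival",
    "log_density",
    "hazard",
    "cure_fraction",
    "sample_event_times",
    "to_unconstrained",
    "from_unconstrained",
    "log_jacobian",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_GOMPERTZ_SMALL_SHAPE = 1e-6


class DomainError(ValueError):
    """A parameter or time argument lies outside its admissible domain."""


@dataclass(frozen=True)
class FamilySpec:
    """Static description of one parametric family.

    Attributes
    ----------
    name : str
        Family identifier, one of ``FAMILY_NAMES``.
    param_names : tuple of str
        Ordered parameter labels on the natural scale.
    param_domains : tuple of str
        Per-parameter domain flag, ``"positive"`` or ``"real"``.
    """

    name: str
    param_names: tuple
    param_domains: tuple

    def __post_init__(self):
        if len(self.param_names) != len(self.param_domains):
            raise ValueError("param_names and param_domains length mismatch")
        for d in self.param_domains:
            if d not in ("positive", "real"):
                raise ValueError(f"unknown domain flag {d!r}")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def positive_mask(self) -> np.ndarray:
        return np.array([d == "positive" for d in self.param_domains])


FAMILIES = {
    "exponential": FamilySpec("exponential", ("rate",), ("positive",)),
    "weibull": FamilySpec("weibull", ("shape", "rate"), ("positive", "positive")),
    "gompertz": FamilySpec("gompertz", ("shape", "rate"), ("real", "positive")),
    "lognormal": FamilySpec("lognormal", ("meanlog", "sdlog"), ("real", "positive")),
    "loglogistic": FamilySpec("loglogistic", ("shape", "scale"), ("positive", "positive")),
    "gamma": FamilySpec("gamma", ("shape", "rate"), ("positive", "positive")),
    "gengamma": FamilySpec(
        "gengamma", ("shape", "rate", "power"), ("positive", "positive", "positive")
    ),
}

#: Canonical ordering of the seven families.
FAMILY_NAMES = tuple(FAMILIES)


def family_spec(family) -> FamilySpec:
    """Resolve a family name or FamilySpec to a FamilySpec."""
    if isinstance(family, FamilySpec):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise DomainError(
            f"unknown family {family!r}; expected one of {sorted(FAMILIES)}"
        ) from None


@dataclass(frozen=True)
class ParameterVector:
    """One point theta in a family's parameter space, on the natural scale."""

    family: FamilySpec
    values: tuple = field(default=())

    def __post_init__(self):
        vals = tuple(float(v) for v in np.atleast_1d(np.asarray(self.values, dtype=float)))
        object.__setattr__(self, "values", vals)
        spec = self.family
        if len(vals) != spec.n_params:
            raise DomainError(
                f"{spec.name} expects {spec.n_params} parameters, got {len(vals)}"
            )
        for name, domain, v in zip(spec.param_names, spec.param_domains, vals):
            if not np.isfinite(v):
                raise DomainError(f"{spec.name} parameter {name!r} is not finite: {v}")
            if domain == "positive" and v <= 0.0:
                raise DomainError(
                    f"{spec.name} parameter {name!r} must be > 0, got {v}"
                )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_dict(self) -> dict:
        return dict(zip(self.family.param_names, self.values))


def params(family, *values) -> ParameterVector:
    """Convenience constructor: ``params("weibull", 1.2, 0.3)``."""
    return ParameterVector(family_spec(family), tuple(values))


# ---------------------------------------------------------------------------
# Low-level log survival / log density, broadcasting over parameter draws
# ---------------------------------------------------------------------------

def _unpack(values, k):
    """Split a (k,) or (n, k) parameter array into broadcastable columns."""
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        if v.shape[0] != k:
            raise DomainError(f"expected {k} parameters, got {v.shape[0]}")
        return [v[i] for i in range(k)]
    if v.shape[-1] != k:
        raise DomainError(f"expected trailing axis of length {k}, got {v.shape}")
    return [v[..., i : i + 1] for i in range(k)]


def _gompertz_cumhaz(a, b, t):
    # (b/a)(e^{at}-1); series in a below the small-shape cutoff to avoid 0/0
    at = a * t
    small = np.abs(a) < _GOMPERTZ_SMALL_SHAPE
    a_safe = np.where(small, 1.0, a)
    with np.errstate(over="ignore"):
        exact = np.expm1(at) / a_safe
    series = t * (1.0 + at / 2.0 + at * at / 6.0)
    return b * np.where(small, series, exact)


def _log_sf_cols(name, cols, t):
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if name == "exponential":
            (lam,) = cols
            return -lam * t
        if name == "weibull":
            v, lam = cols
            return -lam * np.power(t, v)
        if name == "gompertz":
            a, b = cols
            return -_gompertz_cumhaz(a, b, t)
        if name == "lognormal":
            mu, sig = cols
            z = (np.log(t) - mu) / sig
            return special.log_ndtr(-z)
        if name == "loglogistic":
            beta, alpha = cols
            return -np.log1p(np.power(t / alpha, beta))
        if name == "gamma":
            k, r = cols
            return np.log(special.gammaincc(k, r * t))
        if name == "gengamma":
            r, lam, b = cols
            log_x = b * np.log(lam * t)
            x = np.exp(log_x)
            direct = np.log(special.gammaincc(r, x))
            # when (lam t)^b underflows, gammaincc sees 0 and reports S = 1;
            # use the leading series term P(r, x) ~ x^r / Gamma(r+1) instead
            log_cdf = np.minimum(r * log_x - special.gammaln(r + 1.0), 0.0)
            series = np.log1p(-np.exp(log_cdf))
            return np.where(log_x < -34.0, series, direct)
    raise DomainError(f"unknown family {name!r}")


def _log_pdf_cols(name, cols, t):
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logt = np.log(t)
        if name == "exponential":
            (lam,) = cols
            return np.log(lam) - lam * t
        if name == "weibull":
            v, lam = cols
            return np.log(lam) + np.log(v) + (v - 1.0) * logt - lam * np.power(t, v)
        if name == "gompertz":
            a, b = cols
            return np.log(b) + a * t - _gompertz_cumhaz(a, b, t)
        if name == "lognormal":
            mu, sig = cols
            z = (logt - mu) / sig
            return -logt - np.log(sig) - _LOG_SQRT_2PI - 0.5 * z * z
        if name == "loglogistic":
            beta, alpha = cols
            u = np.power(t / alpha, beta)
            return (
                np.log(beta)
                - np.log(alpha)
                + (beta - 1.0) * (logt - np.log(alpha))
                - 2.0 * np.log1p(u)
            )
        if name == "gamma":
            k, r = cols
            return k * np.log(r) - special.gammaln(k) + (k - 1.0) * logt - r * t
        if name == "gengamma":
            r, lam, b = cols
            x = np.power(lam * t, b)
            return (
                np.log(b)
                + r * b * np.log(lam)
                + (r * b - 1.0) * logt
                - special.gammaln(r)
                - x
            )
    raise DomainError(f"unknown family {name!r}")


def log_sf(family, values, t):
    """Log survival function, broadcasting parameter draws against times.

    ``values``: (k,) or (n, k); ``t``: scalar or (m,).  Result broadcasts to
    (n, m) when both are batched.  ``t`` must be >= 0; ``t = 0`` yields 0
    (S(0) = 1) for every family.
    """
    spec = family_spec(family)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be nonnegative")
    cols = _unpack(values, spec.n_params)
    out = _log_sf_cols(spec.name, cols, t)
    # gammaincc underflow and log-of-zero produce -inf, which is correct;
    # 0 * inf at t=0 needs patching for a handful of families
    out = np.where(t == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def log_pdf(family, values, t):
    """Log density, same broadcasting rules as :func:`log_sf`; requires t > 0."""
    spec = family_spec(family)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("time must be strictly positive for the density")
    cols = _unpack(values, spec.n_params)
    out = _log_pdf_cols(spec.name, cols, t)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# ParameterVector-level operations
# ---------------------------------------------------------------------------

def survival(theta: ParameterVector, t):
    """S(t, theta) = P(T > t | theta) = 1 - F(t, theta)."""
    return np.exp(log_sf(theta.family, theta.array, t))


def log_density(theta: ParameterVector, t):
    """log f(t | theta); consistent with survival via f = -dS/dt."""
    return log_pdf(theta.family, theta.array, t)


def hazard(theta: ParameterVector, t):
    """Instantaneous hazard f(t)/S(t); raises where S(t) underflows to 0."""
    lsf = log_sf(theta.family, theta.array, t)
    if np.any(np.isneginf(lsf)):
        raise DomainError("hazard undefined where S(t) = 0")
    return np.exp(log_pdf(theta.family, theta.array, t) - lsf)


def cure_fraction(theta: ParameterVector) -> float:
    """S(infinity): exp(b/a) for Gompertz with negative shape, else 0."""
    if theta.family.name == "gompertz":
        a, b = theta.values
        if a < 0:
            return float(np.exp(b / a))
    return 0.0


def _inverse_survival(theta: ParameterVector, u: np.ndarray) -> np.ndarray:
    """Solve S(t) = u for t, elementwise; u in (0, 1]."""
    name = theta.family.name
    v = theta.values
    if name == "exponential":
        return -np.log(u) / v[0]
    if name == "weibull":
        return np.power(-np.log(u) / v[1], 1.0 / v[0])
    if name == "gompertz":
        a, b = v
        if abs(a) < _GOMPERTZ_SMALL_SHAPE:
            return -np.log(u) / b
        arg = 1.0 - (a / b) * np.log(u)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.log(arg) / a
        return np.where(arg <= 0.0, np.inf, t)
    if name == "lognormal":
        mu, sig = v
        return np.exp(mu + sig * special.ndtri(1.0 - u))
    if name == "loglogistic":
        beta, alpha = v
        return alpha * np.power((1.0 - u) / u, 1.0 / beta)
    if name == "gamma":
        k, r = v
        return special.gammainccinv(k, u) / r
    if name == "gengamma":
        r, lam, b = v
        return np.power(special.gammainccinv(r, u), 1.0 / b) / lam
    raise DomainError(f"unknown family {name!r}")


def sample_event_times(
    theta: ParameterVector, n: int, rng_seed, on_infinite: str = "inf"
) -> np.ndarray:
    """Draw n i.i.d. event times by inversion of the survival function.

    A Gompertz with negative shape has survival plateau exp(b/a): a draw may
    never experience the event.  ``on_infinite="inf"`` returns ``np.inf`` for
    such draws (the realistic choice under administrative censoring);
    ``on_infinite="condition"`` draws conditional on the event occurring.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if on_infinite not in ("inf", "condition"):
        raise DomainError("on_infinite must be 'inf' or 'condition'")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    u = rng.uniform(size=n)
    if on_infinite == "condition":
        s_inf = cure_fraction(theta)
        u = s_inf + u * (1.0 - s_inf)
    # guard u = 0 exactly (measure zero but possible in floating point)
    u = np.clip(u, np.finfo(float).tiny, 1.0)
    return _inverse_survival(theta, u)


# ---------------------------------------------------------------------------
# Transform between natural and unconstrained (sampler) scale
# ---------------------------------------------------------------------------

def to_unconstrained(theta: ParameterVector) -> np.ndarray:
    """Map positive-domain parameters through log; real parameters unchanged."""
    vals = theta.array
    mask = theta.family.positive_mask
    out = vals.copy()
    out[mask] = np.log(vals[mask])
    return out


def from_unconstrained(family, u) -> ParameterVector:
    """Inverse of :func:`to_unconstrained`."""
    spec = family_spec(family)
    u = np.asarray(u, dtype=float)
    if u.shape != (spec.n_params,):
        raise DomainError(f"expected vector of length {spec.n_params}, got {u.shape}")
    if not np.all(np.isfinite(u)):
        raise DomainError("non-finite unconstrained vector")
    mask = spec.positive_mask
    vals = u.copy()
    vals[mask] = np.exp(u[mask])
    return ParameterVector(spec, tuple(vals))


def natural_from_unconstrained(family, u: np.ndarray) -> np.ndarray:
    """Vectorized back-transform for arrays of draws shaped (..., n_params)."""
    spec = family_spec(family)
    u = np.asarray(u, dtype=float)
    mask = spec.positive_mask
    out = u.copy()
    out[..., mask] = np.exp(u[..., mask])
    return out


def log_jacobian(family, u) -> float:
    """Log |det| of the inverse transform: sum of u over log-mapped components."""
    spec = family_spec(family)
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise DomainError("non-finite unconstrained vector")
    return float(np.sum(u[spec.positive_mask]))
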