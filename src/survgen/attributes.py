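"""Outcome-independent random attributes.

Alongside the planted biomarkers, a generated data set carries purely
random attributes with no relationship to the survival outcome — noise
columns a detection tool must learn to ignore.  Six distribution families
are supported; nominal families return category labels, numeric families
return reals.  All sampling is inverse-CDF or generator-native and never
consults the outcome, so independence holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .distributions import (
    LogLogisticParams,
    WeibullParams,
    sample_survival_times,
)
from .errors import ParameterError

__all__ = ["DistributionSpec", "validate_spec", "sample_attribute", "FAMILIES"]

FAMILIES = (
    "uniform_nominal",
    "uniform_numeric",
    "binomial",
    "normal",
    "exponential",
    "weibull",
    "loglogistic",
)


@dataclass(frozen=True)
class DistributionSpec:
    """A named attribute with its distribution family and parameters.

    ``params`` keys per family:

    - ``uniform_nominal``: ``categories`` (list of >= 2 labels, equiprobable)
    - ``uniform_numeric``: ``lower``, ``upper`` (lower < upper)
    - ``binomial``: ``n`` (>= 1), ``p`` in [0, 1]; n = 1 is a Bernoulli
      shorthand that emits booleans
    - ``normal``: ``mean`` (default 0), ``sd`` (default 1, > 0) — omitting
      both yields the standard normal
    - ``exponential``: ``rate`` (> 0)
    - ``weibull`` / ``loglogistic``: ``scale``, ``shape`` (both > 0)
    """

    name: str
    family: str
    params: Mapping = field(default_factory=dict)


def validate_spec(spec: DistributionSpec) -> list:
    """Check a spec against its family's parameter domain.

    Returns a list of violation messages; an empty list means the spec is
    valid.  Every violated constraint is reported, not just the first.
    """
    errors = []
    p = dict(spec.params)
    if not spec.name:
        errors.append("name: must be a non-empty string")
    if spec.family not in FAMILIES:
        errors.append(
            f"family: {spec.family!r} is not one of {', '.join(FAMILIES)}"
        )
        return errors

    def require_positive(key, default=None):
        value = p.get(key, default)
        if value is None:
            errors.append(f"{key}: required for family {spec.family!r}")
        elif not value > 0:
            errors.append(f"{key}: must be > 0, got {value}")

    if spec.family == "uniform_nominal":
        categories = p.get("categories")
        if not isinstance(categories, (list, tuple)) or len(categories) < 2:
            errors.append("categories: need at least 2 category labels")
        elif len(set(map(str, categories))) != len(categories):
            errors.append("categories: labels must be distinct")
    elif spec.family == "uniform_numeric":
        lower, upper = p.get("lower"), p.get("upper")
        if lower is None or upper is None:
            errors.append("lower/upper: both bounds are required")
        elif not lower < upper:
            errors.append(f"lower: must be < upper, got [{lower}, {upper}]")
    elif spec.family == "binomial":
        n = p.get("n")
        prob = p.get("p")
        if n is None or int(n) != n or n < 1:
            errors.append(f"n: must be an integer >= 1, got {n}")
        if prob is None or not 0.0 <= prob <= 1.0:
            errors.append(f"p: must be in [0, 1], got {prob}")
    elif spec.family == "normal":
        sd = p.get("sd", 1.0)
        if not sd > 0:
            errors.append(f"sd: must be > 0, got {sd}")
    elif spec.family == "exponential":
        require_positive("rate")
    elif spec.family in ("weibull", "loglogistic"):
        require_positive("scale")
        require_positive("shape")
    return errors


def sample_attribute(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. values for one attribute.

    Raises :class:`ParameterError` naming every violated constraint if the
    spec is invalid.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    violations = validate_spec(spec)
    if violations:
        raise ParameterError(
            f"invalid attribute {spec.name!r}: " + "; ".join(violations)
        )
    p = dict(spec.params)
    if spec.family == "uniform_nominal":
        categories = np.asarray(p["categories"], dtype=object)
        return categories[rng.integers(len(categories), size=n)]
    if spec.family == "uniform_numeric":
        return rng.uniform(p["lower"], p["upper"], size=n)
    if spec.family == "binomial":
        draws = rng.binomial(int(p["n"]), p["p"], size=n)
        if int(p["n"]) == 1:  # Bernoulli shorthand: boolean domain
            return draws.astype(bool)
        return draws
    if spec.family == "normal":
        return rng.normal(p.get("mean", 0.0), p.get("sd", 1.0), size=n)
    if spec.family == "exponential":
        return rng.exponential(1.0 / p["rate"], size=n)
    if spec.family == "weibull":
        return sample_survival_times(
            WeibullParams(p["scale"], p["shape"]), n, rng
        )
    return sample_survival_times(
        LogLogisticParams(p["scale"], p["shape"]), n, rng
    )
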