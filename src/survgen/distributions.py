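"""Weibull and log-logistic survival laws with anchored scale inversion.

Rather than asking users for abstract scale parameters, a survival curve is
pinned to an *anchor point* ``(t, S(t))`` that it must pass through: the
scale parameter is solved in closed form from the anchor while the shape
parameter (which controls how steeply the curve falls) remains an explicit
user choice.  For the Weibull family

.. math:: S(t) = \\exp\\!\\left(-(t/\\lambda)^k\\right)

the anchored scale is :math:`\\lambda = 10^{\\log_{10} t - \\log_{10}(-\\ln S(t))\\, k^{-1}}`,
and for the log-logistic family

.. math:: S(t) = \\frac{1}{1 + (t/\\alpha)^\\beta}

it is :math:`\\alpha = t \\cdot 10^{-\\log_{10}(S(t)^{-1} - 1)\\, \\beta^{-1}}`.
Both solutions exist and are positive for every ``t > 0``, ``S(t) in (0, 1)``
and positive shape, so anchoring imposes no extra restrictions on the user.

Random survival times are drawn by inverse-CDF transformation, which is
exact and reproducible under a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ParameterError

__all__ = [
    "SurvivalAnchor",
    "WeibullParams",
    "LogLogisticParams",
    "weibull_survival",
    "loglogistic_survival",
    "weibull_scale_from_anchor",
    "loglogistic_scale_from_anchor",
    "sample_survival_times",
]


@dataclass(frozen=True)
class SurvivalAnchor:
    """A ``(time, survival)`` point a survival curve must pass through.

    ``time`` is in study-time units (months by convention); ``survival``
    is the target S(time) and must lie strictly inside (0, 1) — at the
    boundaries no finite scale parameter exists.
    """

    time: float
    survival: float

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ParameterError(f"anchor time must be > 0, got {self.time}")
        if not 0.0 < self.survival < 1.0:
            raise ParameterError(
                f"anchor survival must lie strictly in (0, 1), got {self.survival}"
            )


@dataclass(frozen=True)
class WeibullParams:
    """Weibull scale λ and shape k, both strictly positive."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ParameterError(f"Weibull scale must be > 0, got {self.scale}")
        if not self.shape > 0:
            raise ParameterError(f"Weibull shape must be > 0, got {self.shape}")


@dataclass(frozen=True)
class LogLogisticParams:
    """Log-logistic scale α (the median) and shape β, both strictly positive."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ParameterError(f"log-logistic scale must be > 0, got {self.scale}")
        if not self.shape > 0:
            raise ParameterError(f"log-logistic shape must be > 0, got {self.shape}")


SurvivalParams = Union[WeibullParams, LogLogisticParams]


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("survival function requires t >= 0")
    return t


def weibull_survival(t, params: WeibullParams):
    """Weibull survival function S(t) = exp(-(t/λ)^k).

    Accepts a scalar or array ``t >= 0``; S(0) = 1 and S is strictly
    decreasing in t.
    """
    t = _check_times(t)
    out = np.exp(-((t / params.scale) ** params.shape))
    return float(out) if out.ndim == 0 else out


def loglogistic_survival(t, params: LogLogisticParams):
    """Log-logistic survival function S(t) = 1 / (1 + (t/α)^β)."""
    t = _check_times(t)
    out = 1.0 / (1.0 + (t / params.scale) ** params.shape)
    return float(out) if out.ndim == 0 else out


def weibull_scale_from_anchor(anchor: SurvivalAnchor, shape: float) -> WeibullParams:
    """Solve the Weibull scale λ so the curve passes through ``anchor``.

    Uses the closed form λ = 10^(log10(t) - log10(-ln S(t)) / k).  The
    result is always positive on the valid domain.
    """
    if not shape > 0:
        raise ParameterError(f"shape must be > 0, got {shape}")
    scale = 10.0 ** (
        math.log10(anchor.time) - math.log10(-math.log(anchor.survival)) / shape
    )
    return WeibullParams(scale=scale, shape=shape)


def loglogistic_scale_from_anchor(
    anchor: SurvivalAnchor, shape: float
) -> LogLogisticParams:
    """Solve the log-logistic scale α so the curve passes through ``anchor``.

    Uses the closed form α = t · 10^(-log10(1/S(t) - 1) / β).
    """
    if not shape > 0:
        raise ParameterError(f"shape must be > 0, got {shape}")
    scale = anchor.time * 10.0 ** (
        -math.log10(1.0 / anchor.survival - 1.0) / shape
    )
    return LogLogisticParams(scale=scale, shape=shape)


def sample_survival_times(
    params: SurvivalParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. survival times by inverse-CDF transformation.

    Weibull: λ·(-ln U)^(1/k); log-logistic: α·(1/U - 1)^(-1/β), with U
    uniform on (0, 1).  Fully reproducible given the generator state.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    u = rng.random(n)
    # guard against the measure-zero U == 0 draw, which would map to +inf
    u = np.maximum(u, np.finfo(float).tiny)
    if isinstance(params, WeibullParams):
        return params.scale * (-np.log(u)) ** (1.0 / params.shape)
    if isinstance(params, LogLogisticParams):
        return params.scale * (1.0 / u - 1.0) ** (-1.0 / params.shape)
    raise ParameterError(f"unsupported parameter type: {type(params).__name__}")
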