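"""Arm-balanced, subgroup-enriched biomarkers.

A biomarker here is a planted, non-random attribute: its carrier count is
*exactly* equal in both study arms — so a naive arm-level comparison sees
nothing — while its carriers accumulate in outcome-defined subgroups of
one "enriched" arm, giving detection software a known ground truth to find.

For the enriched arm the nominal biomarker is a composite of three
binomial leaves of the cohort tree with probabilities

- ``p1`` = P(biomarker | enriched arm, LTS, survivors),
- ``p2`` = P(biomarker | enriched arm, LTS, non-survivors),
- ``p3`` = P(biomarker | enriched arm, STS), solved from the balance
  requirement below,

while the other arm carries the flat overall prevalence
``p4 = p_prevalence``.  Splitting the LTS leaf by survival status is what
makes the planted signal visible even in the inferior arm.  Balance fixes

    f1*p1 + f2*p2 + f3*p3 = prevalence,

with ``f_i`` the leaf shares of the enriched arm, which yields the
reconstructed closed form ``p3 = (prevalence - f1*p1 - f2*p2) / f3``.

The numeric biomarker reuses the same marking machinery with its own,
independent probabilities, then assigns values from two normal
distributions — N(mu_biomarker, sigma_biomarker^2) for marked subjects,
N(mu_non_biomarker, sigma_non_biomarker^2) otherwise.  The overlap of the
two normals is one measure of the biomarker's configurable intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cohort import Cohort, largest_remainder_round
from .errors import ConfigurationError, ParameterError

__all__ = [
    "NominalBiomarkerConfig",
    "NumericBiomarkerConfig",
    "compute_p3",
    "allocate_nominal_biomarker",
    "assign_numeric_biomarker",
]


@dataclass(frozen=True)
class NominalBiomarkerConfig:
    """Marking probabilities of the nominal (true/false) biomarker."""

    p1: float
    p2: float
    prevalence: float
    enriched_arm: Literal["A", "B"] = "A"

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "prevalence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {value}")
        if self.enriched_arm not in ("A", "B"):
            raise ParameterError(
                f"enriched_arm must be 'A' or 'B', got {self.enriched_arm!r}"
            )


@dataclass(frozen=True)
class NumericBiomarkerConfig:
    """Marking probabilities plus the two-normal value model."""

    marking: NominalBiomarkerConfig
    mu_biomarker: float
    sigma_biomarker: float
    mu_non_biomarker: float
    sigma_non_biomarker: float

    def __post_init__(self) -> None:
        for name in ("sigma_biomarker", "sigma_non_biomarker"):
            value = getattr(self, name)
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value}")


def compute_p3(
    p1: float, p2: float, prevalence: float, leaf_fractions: tuple
) -> float:
    """Solve the STS marking probability from the arm-balance identity.

    ``leaf_fractions`` are the enriched arm's shares ``(f1, f2, f3)`` of
    LTS survivors, LTS non-survivors and STS; they must sum to 1.  The
    returned p3 satisfies ``f1*p1 + f2*p2 + f3*p3 == prevalence``.  An
    infeasible combination (p3 outside [0, 1]) raises a configuration
    error reporting the feasible prevalence interval.
    """
    f1, f2, f3 = leaf_fractions
    if abs(f1 + f2 + f3 - 1.0) > 1e-9:
        raise ParameterError(
            f"leaf fractions must sum to 1, got {leaf_fractions}"
        )
    residual = prevalence - f1 * p1 - f2 * p2
    if f3 <= 0.0:
        if abs(residual) > 1e-12:
            raise ConfigurationError(
                "STS leaf is empty but the LTS leaves alone cannot meet the "
                f"requested prevalence {prevalence} (residual {residual:.4g})"
            )
        return 0.0
    p3 = residual / f3
    # boundary-feasible configurations may land a rounding error outside [0, 1]
    if -1e-9 <= p3 < 0.0 or 1.0 < p3 <= 1.0 + 1e-9:
        p3 = min(max(p3, 0.0), 1.0)
    if not 0.0 <= p3 <= 1.0:
        lo = f1 * p1 + f2 * p2
        raise ConfigurationError(
            f"infeasible biomarker configuration: p3 = {p3:.4g} lies outside "
            f"[0, 1]; with these leaf fractions and p1/p2 the prevalence must "
            f"lie in [{lo:.6g}, {lo + f3:.6g}]"
        )
    return p3


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _mark_subjects(cohort: Cohort, config: NominalBiomarkerConfig, rng) -> np.ndarray:
    """Boolean carrier mask implementing exact arm balance with enrichment.

    Exactly ``K = round(n_arm * prevalence)`` subjects are marked in each
    arm.  In the non-enriched arm the K carriers are drawn uniformly; in
    the enriched arm K is apportioned over the three leaves by
    largest-remainder rounding of the expected leaf counts ``n_i * p_i``
    (p3 solved from the realized leaf fractions), then drawn uniformly
    within each leaf.
    """
    subjects = cohort.subjects
    mask = np.zeros(len(subjects), dtype=bool)
    arms = {"A": [], "B": []}
    for i, s in enumerate(subjects):
        arms[s.arm].append(i)
    n_a, n_b = len(arms["A"]), len(arms["B"])
    if n_a != n_b:
        raise ConfigurationError(f"arms are unbalanced: {n_a} vs {n_b}")
    n_arm = n_a
    k_total = _round_half_up(n_arm * config.prevalence)

    other_arm = "B" if config.enriched_arm == "A" else "A"
    # flat arm: uniform choice of exactly K carriers
    flat_idx = np.array(arms[other_arm], dtype=int)
    if k_total > 0:
        mask[rng.choice(flat_idx, size=k_total, replace=False)] = True

    # enriched arm: leaf quotas from (p1, p2, p3)
    leaves = {"lts_surv": [], "lts_non": [], "sts": []}
    for i in arms[config.enriched_arm]:
        s = subjects[i]
        if s.group == "LTS":
            leaves["lts_surv" if s.survivor else "lts_non"].append(i)
        else:
            leaves["sts"].append(i)
    n1, n2, n3 = (len(leaves[k]) for k in ("lts_surv", "lts_non", "sts"))
    p3 = compute_p3(
        config.p1,
        config.p2,
        config.prevalence,
        (n1 / n_arm, n2 / n_arm, n3 / n_arm),
    )
    expected = [n1 * config.p1, n2 * config.p2, n3 * p3]
    quotas = largest_remainder_round(expected, k_total)
    for quota, (key, size) in zip(
        quotas, (("lts_surv", n1), ("lts_non", n2), ("sts", n3))
    ):
        if quota > size:
            raise ConfigurationError(
                f"biomarker quota {quota} exceeds leaf size {size} ({key}); "
                "lower the leaf probability or the prevalence"
            )
        if quota > 0:
            chosen = rng.choice(np.array(leaves[key], dtype=int), size=int(quota), replace=False)
            mask[chosen] = True
    return mask


def allocate_nominal_biomarker(
    cohort: Cohort, config: NominalBiomarkerConfig, rng: np.random.Generator
) -> Cohort:
    """Mark the nominal biomarker on every subject (in place) and return the cohort."""
    mask = _mark_subjects(cohort, config, rng)
    for i, s in enumerate(cohort.subjects):
        s.nominal_biomarker = bool(mask[i])
    return cohort


def assign_numeric_biomarker(
    cohort: Cohort, config: NumericBiomarkerConfig, rng: np.random.Generator
) -> Cohort:
    """Two-step numeric biomarker: mark like the nominal one, then draw values.

    Marked subjects receive N(mu_biomarker, sigma_biomarker^2) draws,
    unmarked ones N(mu_non_biomarker, sigma_non_biomarker^2); marking uses
    probabilities independent of the nominal biomarker's and its own
    random stream.
    """
    mask = _mark_subjects(cohort, config.marking, rng)
    n = len(cohort.subjects)
    values = np.where(
        mask,
        rng.normal(config.mu_biomarker, config.sigma_biomarker, size=n),
        rng.normal(config.mu_non_biomarker, config.sigma_non_biomarker, size=n),
    )
    for i, s in enumerate(cohort.subjects):
        s.numeric_biomarker_marked = bool(mask[i])
        s.numeric_biomarker = float(values[i])
    return cohort
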