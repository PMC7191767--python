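"""Two-arm cohort construction.

A simulated cohort mimics a randomized controlled trial on a therapeutic
comparison: two exactly balanced study arms (A = standard/placebo, B = new
therapy), each split into long-term survivors (LTS) and short-term
survivors (STS) — the two mixture components behind the bimodal
survival-time histograms commonly seen in longitudinal studies — and each
of those further into survivors (right-censored, event = 0) and
non-survivors (event = 1).  Every leaf of this arm x group x status tree
carries its own anchored survival law from which its subjects' times are
drawn.

Subgroup sizes are deterministic design quantities computed by
largest-remainder rounding of the exact expected counts, not multinomial
draws.  A configurable superiority delta shifts the anchor survivals of the
two arms half up / half down so that S_B(t) - S_A(t) at the anchor times
equals the requested difference; negative deltas make arm A superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .attributes import DistributionSpec, sample_attribute
from .distributions import (
    LogLogisticParams,
    SurvivalAnchor,
    WeibullParams,
    loglogistic_scale_from_anchor,
    sample_survival_times,
    weibull_scale_from_anchor,
)
from .errors import ConfigurationError, ParameterError

__all__ = [
    "SurvivalGroupConfig",
    "ArmConfig",
    "CohortConfig",
    "Subject",
    "Cohort",
    "allocate_subgroup_counts",
    "apply_superiority_correction",
    "build_cohort",
    "censor_subjects",
    "largest_remainder_round",
]

Family = Literal["weibull", "loglogistic"]


@dataclass(frozen=True)
class SurvivalGroupConfig:
    """Survival law of one LTS or STS subgroup.

    ``anchor`` is the (t, S(t)) point the subgroup's curve must touch,
    ``shape`` the explicitly chosen shape parameter, and
    ``survivor_fraction`` the share of the subgroup that remains event-free
    (right-censored) rather than experiencing the event.
    """

    family: Family
    anchor: SurvivalAnchor
    shape: float
    survivor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("weibull", "loglogistic"):
            raise ParameterError(f"unknown survival family: {self.family!r}")
        if not self.shape > 0:
            raise ParameterError(f"shape must be > 0, got {self.shape}")
        if not 0.0 <= self.survivor_fraction <= 1.0:
            raise ParameterError(
                f"survivor_fraction must be in [0, 1], got {self.survivor_fraction}"
            )

    def params(self, anchor: Optional[SurvivalAnchor] = None):
        """Anchored distribution parameters, optionally from a corrected anchor."""
        anchor = anchor if anchor is not None else self.anchor
        if self.family == "weibull":
            return weibull_scale_from_anchor(anchor, self.shape)
        return loglogistic_scale_from_anchor(anchor, self.shape)


@dataclass(frozen=True)
class ArmConfig:
    """One study arm: its LTS share and the two subgroup survival laws.

    Setting ``lts_fraction`` to 0 or 1 collapses the arm to a single
    survivor group when no LTS/STS distinction is needed.
    """

    label: Literal["A", "B"]
    lts_fraction: float
    lts: SurvivalGroupConfig
    sts: SurvivalGroupConfig

    def __post_init__(self) -> None:
        if self.label not in ("A", "B"):
            raise ParameterError(f"arm label must be 'A' or 'B', got {self.label!r}")
        if not 0.0 <= self.lts_fraction <= 1.0:
            raise ParameterError(
                f"lts_fraction must be in [0, 1], got {self.lts_fraction}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration for one simulated trial cohort."""

    n_total: int
    arm_a: ArmConfig
    arm_b: ArmConfig
    superiority_delta: float = 0.0
    followup_horizon: Optional[float] = None
    nominal_biomarker: Optional["NominalBiomarkerConfig"] = None  # noqa: F821
    numeric_biomarker: Optional["NumericBiomarkerConfig"] = None  # noqa: F821
    attributes: Sequence[DistributionSpec] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2 or self.n_total % 2 != 0:
            raise ConfigurationError(
                f"n_total must be a positive even integer (balanced arms), "
                f"got {self.n_total}"
            )
        if not -1.0 < self.superiority_delta < 1.0:
            raise ConfigurationError(
                f"superiority_delta must lie in (-1, 1), got {self.superiority_delta}"
            )
        if self.followup_horizon is not None and not self.followup_horizon > 0:
            raise ConfigurationError(
                f"followup_horizon must be > 0, got {self.followup_horizon}"
            )
        names = [spec.name for spec in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate attribute names in {names}")


@dataclass
class Subject:
    """One simulated patient.

    ``event`` is 1 when the event was observed and 0 when the observation
    is right-censored; by construction ``event == 0`` iff the subject is a
    survivor (or was truncated at the follow-up horizon).
    """

    id: int
    arm: str
    group: str
    survivor: bool
    time: float
    event: int
    nominal_biomarker: Optional[bool] = None
    numeric_biomarker: Optional[float] = None
    numeric_biomarker_marked: Optional[bool] = None
    attributes: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """An ordered list of subjects plus the configuration that produced it."""

    subjects: list
    config: CohortConfig

    def arm_indices(self, label: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.subjects) if s.arm == label], dtype=int
        )

    def to_frame(self, include_truth: bool = False) -> pd.DataFrame:
        """Flat table view: one row per subject.

        With ``include_truth`` the generating ground truth (LTS/STS group,
        survivor flag, biomarker marking flags) is exported too, so that
        software under test can be scored against the planted effects.
        """
        rows = []
        for s in self.subjects:
            row = {
                "id": s.id,
                "time": s.time,
                "event": s.event,
                "arm": s.arm,
            }
            if s.nominal_biomarker is not None:
                row["nominal_biomarker"] = s.nominal_biomarker
            if s.numeric_biomarker is not None:
                row["numeric_biomarker"] = s.numeric_biomarker
            row.update(s.attributes)
            if include_truth:
                row["group"] = s.group
                row["survivor"] = s.survivor
                if s.numeric_biomarker_marked is not None:
                    row["numeric_biomarker_marked"] = s.numeric_biomarker_marked
            rows.append(row)
        return pd.DataFrame(rows)


def largest_remainder_round(expected: Sequence[float], total: int) -> np.ndarray:
    """Round nonnegative expected counts to integers summing to ``total``.

    Classic largest-remainder (Hamilton) apportionment: floor everything,
    then hand the remaining units to the largest fractional parts.  Ties in
    the fractional part go to the earlier entry, making the result fully
    deterministic.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < -1e-9):
        raise ParameterError(f"expected counts must be nonnegative: {expected}")
    expected = np.clip(expected, 0.0, None)
    base = np.floor(expected).astype(int)
    short = total - int(base.sum())
    if short < 0:
        raise ParameterError(
            f"expected counts {expected} exceed total {total}"
        )
    if short > 0:
        remainders = expected - base
        # stable sort descending by remainder, ties to earlier entries
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def allocate_subgroup_counts(
    n_arm: int,
    lts_fraction: float,
    survivor_fractions: tuple,
) -> tuple:
    """Deterministic subject counts for the four leaves of one arm.

    Returns ``(lts_survivors, lts_nonsurvivors, sts_survivors,
    sts_nonsurvivors)`` summing exactly to ``n_arm``, obtained by
    largest-remainder rounding of the exact expected counts.
    """
    if n_arm < 0:
        raise ParameterError(f"n_arm must be nonnegative, got {n_arm}")
    if not 0.0 <= lts_fraction <= 1.0:
        raise ParameterError(f"lts_fraction must be in [0, 1], got {lts_fraction}")
    sf_lts, sf_sts = survivor_fractions
    for sf in (sf_lts, sf_sts):
        if not 0.0 <= sf <= 1.0:
            raise ParameterError(f"survivor fraction must be in [0, 1], got {sf}")
    expected = [
        n_arm * lts_fraction * sf_lts,
        n_arm * lts_fraction * (1.0 - sf_lts),
        n_arm * (1.0 - lts_fraction) * sf_sts,
        n_arm * (1.0 - lts_fraction) * (1.0 - sf_sts),
    ]
    counts = largest_remainder_round(expected, n_arm)
    return tuple(int(c) for c in counts)


def apply_superiority_correction(
    anchor_a: SurvivalAnchor, anchor_b: SurvivalAnchor, delta: float
) -> tuple:
    """Shift the arm anchors so S_B - S_A at the anchor times moves by ``delta``.

    Half of the correction is added to arm B's anchor survival and the
    other half subtracted from arm A's, so a positive delta makes the new
    therapy superior while leaving the pooled survival level unchanged.
    Negative deltas are allowed (arm A superior).
    """
    s_a = anchor_a.survival - delta / 2.0
    s_b = anchor_b.survival + delta / 2.0
    if not 0.0 < s_a < 1.0:
        raise ConfigurationError(
            f"superiority correction pushes arm A anchor survival to {s_a:.4g}, "
            f"outside (0, 1)"
        )
    if not 0.0 < s_b < 1.0:
        raise ConfigurationError(
            f"superiority correction pushes arm B anchor survival to {s_b:.4g}, "
            f"outside (0, 1)"
        )
    return (
        SurvivalAnchor(anchor_a.time, s_a),
        SurvivalAnchor(anchor_b.time, s_b),
    )


def corrected_anchors(config: CohortConfig) -> dict:
    """Superiority-corrected anchors per (arm, group) leaf.

    The half-up/half-down correction is applied to the LTS and STS anchors
    separately, each with the same delta/2.
    """
    out = {}
    for group in ("LTS", "STS"):
        ga = getattr(config.arm_a, group.lower())
        gb = getattr(config.arm_b, group.lower())
        try:
            a_corr, b_corr = apply_superiority_correction(
                ga.anchor, gb.anchor, config.superiority_delta
            )
        except ConfigurationError as err:
            raise ConfigurationError(f"{group} subgroup: {err}") from None
        out[("A", group)] = a_corr
        out[("B", group)] = b_corr
    return out


def achieved_weighted_delta(config: CohortConfig):
    """Cohort-weighted S_B - S_A difference implied by the corrected anchors.

    Because the correction is applied per subgroup, the arm-level
    difference depends on the subgroup sizes.  When both arms share common
    LTS and STS anchor times this returns the weighted difference at those
    times; otherwise anchor survivals are not comparable and ``None`` is
    returned.
    """
    if (
        config.arm_a.lts.anchor.time != config.arm_b.lts.anchor.time
        or config.arm_a.sts.anchor.time != config.arm_b.sts.anchor.time
    ):
        return None
    anchors = corrected_anchors(config)
    n_arm = config.n_total // 2
    diff = 0.0
    for arm_cfg, sign in ((config.arm_a, -1.0), (config.arm_b, +1.0)):
        counts = allocate_subgroup_counts(
            n_arm,
            arm_cfg.lts_fraction,
            (arm_cfg.lts.survivor_fraction, arm_cfg.sts.survivor_fraction),
        )
        n_lts = counts[0] + counts[1]
        n_sts = counts[2] + counts[3]
        s = (
            n_lts * anchors[(arm_cfg.label, "LTS")].survival
            + n_sts * anchors[(arm_cfg.label, "STS")].survival
        ) / n_arm
        diff += sign * s
    return diff


def build_cohort(config: CohortConfig) -> Cohort:
    """Construct the full cohort described by ``config``.

    Subjects are laid out arm A first then arm B, each arm in leaf order
    (LTS survivors, LTS non-survivors, STS survivors, STS non-survivors).
    Every subject's observation time — survivors included, see
    :func:`censor_subjects` — is drawn from their leaf's anchored,
    superiority-corrected law.  Identical configuration implies an
    identical cohort.
    """
    anchors = corrected_anchors(config)
    n_arm = config.n_total // 2
    rng_times = child_rng(config.seed, "times")

    subjects: list = []
    next_id = 0
    for arm_cfg in (config.arm_a, config.arm_b):
        counts = allocate_subgroup_counts(
            n_arm,
            arm_cfg.lts_fraction,
            (arm_cfg.lts.survivor_fraction, arm_cfg.sts.survivor_fraction),
        )
        leaves = [
            ("LTS", True, counts[0], arm_cfg.lts),
            ("LTS", False, counts[1], arm_cfg.lts),
            ("STS", True, counts[2], arm_cfg.sts),
            ("STS", False, counts[3], arm_cfg.sts),
        ]
        for group, survivor, n_leaf, group_cfg in leaves:
            if n_leaf == 0:
                continue
            params = group_cfg.params(anchors[(arm_cfg.label, group)])
            times = sample_survival_times(params, n_leaf, rng_times)
            for t in times:
                subjects.append(
                    Subject(
                        id=next_id,
                        arm=arm_cfg.label,
                        group=group,
                        survivor=survivor,
                        time=float(t),
                        event=0 if survivor else 1,
                    )
                )
                next_id += 1

    cohort = Cohort(subjects=subjects, config=config)

    # biomarkers and random attributes ride on their own child streams so
    # that the survival times above are insensitive to their presence
    from .biomarkers import allocate_nominal_biomarker, assign_numeric_biomarker

    if config.nominal_biomarker is not None:
        allocate_nominal_biomarker(
            cohort, config.nominal_biomarker, child_rng(config.seed, "nominal")
        )
    if config.numeric_biomarker is not None:
        assign_numeric_biomarker(
            cohort, config.numeric_biomarker, child_rng(config.seed, "numeric")
        )
    for spec in config.attributes:
        values = sample_attribute(
            spec, len(subjects), child_rng(config.seed, "attribute", spec.name)
        )
        for subject, value in zip(cohort.subjects, values):
            subject.attributes[spec.name] = value

    return censor_subjects(cohort, config.followup_horizon)


def censor_subjects(cohort: Cohort, horizon: Optional[float]) -> Cohort:
    """Apply the right-censoring rules to a built cohort.

    Survivors already carry an observation time drawn from their leaf's
    anchored law and event = 0 — a deliberately simple mechanism that keeps
    the observation-period histogram bimodal regardless of status.  If an
    administrative follow-up ``horizon`` is given, every time beyond it is
    truncated to the horizon and flagged censored.
    """
    if horizon is None:
        return cohort
    if not horizon > 0:
        raise ParameterError(f"horizon must be > 0, got {horizon}")
    for s in cohort.subjects:
        if s.time > horizon:
            s.time = horizon
            s.event = 0
    return cohort
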