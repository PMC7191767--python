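"""JSON configuration parsing and validation.

The whole generator is driven by a single JSON configuration file; every
data-generation parameter lives there.  Parsing is strict — unknown keys
are rejected to catch typos in scientific configs — and every schema
violation is reported at once with a JSON-pointer-style path.  After the
schema passes, cross-field feasibility is checked before any generation:
the superiority-corrected anchor survivals must stay in (0, 1), and each
biomarker's derived STS probability p3 must land in [0, 1] (otherwise the
error states the feasible prevalence interval).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .attributes import DistributionSpec, validate_spec
from .biomarkers import NominalBiomarkerConfig, NumericBiomarkerConfig, compute_p3
from .cohort import (
    ArmConfig,
    CohortConfig,
    SurvivalGroupConfig,
    achieved_weighted_delta,
    allocate_subgroup_counts,
    corrected_anchors,
)
from .distributions import SurvivalAnchor
from .errors import ConfigurationError, SurvgenError

__all__ = ["read_config", "read_config_file", "validate_config", "OutputOptions"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _AnchorModel(_Strict):
    time: float = Field(gt=0)
    survival: float = Field(gt=0, lt=1)


class _GroupModel(_Strict):
    family: Literal["weibull", "loglogistic"]
    anchor: _AnchorModel
    shape: float = Field(gt=0)
    survivor_fraction: float = Field(default=0.0, ge=0, le=1)


class _ArmModel(_Strict):
    lts_fraction: float = Field(ge=0, le=1)
    lts: _GroupModel
    sts: _GroupModel


class _NominalBiomarkerModel(_Strict):
    enriched_arm: Literal["A", "B"] = "A"
    p1: float = Field(ge=0, le=1)
    p2: float = Field(ge=0, le=1)
    prevalence: float = Field(ge=0, le=1)


class _NumericBiomarkerModel(_Strict):
    marking: _NominalBiomarkerModel
    mu_biomarker: float
    sigma_biomarker: float = Field(gt=0)
    mu_non_biomarker: float
    sigma_non_biomarker: float = Field(gt=0)


class _AttributeModel(_Strict):
    name: str = Field(min_length=1)
    family: str
    params: dict = Field(default_factory=dict)


class _ConfigFileModel(_Strict):
    """Schema of the generator configuration file."""

    n_total: int = Field(ge=2)
    seed: int = 0
    superiority_delta: float = Field(default=0.0, gt=-1, lt=1)
    followup_horizon: Optional[float] = Field(default=None, gt=0)
    arm_a: _ArmModel
    arm_b: _ArmModel
    nominal_biomarker: Optional[_NominalBiomarkerModel] = None
    numeric_biomarker: Optional[_NumericBiomarkerModel] = None
    attributes: List[_AttributeModel] = Field(default_factory=list)
    # output options (not part of the scientific configuration)
    include_truth: bool = False
    output: Optional[str] = None
    plot: Optional[str] = None


class OutputOptions(BaseModel):
    """Output-related keys of a configuration file."""

    include_truth: bool = False
    output: Optional[str] = None
    plot: Optional[str] = None


def _group(model: _GroupModel) -> SurvivalGroupConfig:
    return SurvivalGroupConfig(
        family=model.family,
        anchor=SurvivalAnchor(model.anchor.time, model.anchor.survival),
        shape=model.shape,
        survivor_fraction=model.survivor_fraction,
    )


def _to_core(model: _ConfigFileModel) -> CohortConfig:
    attr_errors = []
    specs = []
    for i, a in enumerate(model.attributes):
        spec = DistributionSpec(name=a.name, family=a.family, params=a.params)
        for violation in validate_spec(spec):
            attr_errors.append(f"/attributes/{i}: {violation}")
        specs.append(spec)
    if attr_errors:
        raise ConfigurationError(
            "invalid attribute specification:\n  " + "\n  ".join(attr_errors)
        )
    nominal = (
        NominalBiomarkerConfig(
            p1=model.nominal_biomarker.p1,
            p2=model.nominal_biomarker.p2,
            prevalence=model.nominal_biomarker.prevalence,
            enriched_arm=model.nominal_biomarker.enriched_arm,
        )
        if model.nominal_biomarker
        else None
    )
    numeric = (
        NumericBiomarkerConfig(
            marking=NominalBiomarkerConfig(
                p1=model.numeric_biomarker.marking.p1,
                p2=model.numeric_biomarker.marking.p2,
                prevalence=model.numeric_biomarker.marking.prevalence,
                enriched_arm=model.numeric_biomarker.marking.enriched_arm,
            ),
            mu_biomarker=model.numeric_biomarker.mu_biomarker,
            sigma_biomarker=model.numeric_biomarker.sigma_biomarker,
            mu_non_biomarker=model.numeric_biomarker.mu_non_biomarker,
            sigma_non_biomarker=model.numeric_biomarker.sigma_non_biomarker,
        )
        if model.numeric_biomarker
        else None
    )
    return CohortConfig(
        n_total=model.n_total,
        arm_a=ArmConfig(label="A", lts_fraction=model.arm_a.lts_fraction,
                        lts=_group(model.arm_a.lts), sts=_group(model.arm_a.sts)),
        arm_b=ArmConfig(label="B", lts_fraction=model.arm_b.lts_fraction,
                        lts=_group(model.arm_b.lts), sts=_group(model.arm_b.sts)),
        superiority_delta=model.superiority_delta,
        followup_horizon=model.followup_horizon,
        nominal_biomarker=nominal,
        numeric_biomarker=numeric,
        attributes=tuple(specs),
        seed=model.seed,
    )


def validate_config(config: CohortConfig) -> Optional[float]:
    """Cross-field feasibility checks; returns the achieved weighted delta.

    Verifies that the superiority-corrected anchors stay inside (0, 1) and
    that each configured biomarker's derived p3 is a probability for the
    deterministic leaf sizes the cohort will actually use.  Returns the
    cohort-weighted S_B - S_A difference at the common anchor times (or
    ``None`` when the arms use different anchor times).
    """
    corrected_anchors(config)  # raises ConfigurationError when out of (0, 1)
    n_arm = config.n_total // 2
    for label, bm in (
        ("nominal_biomarker", config.nominal_biomarker),
        ("numeric_biomarker", getattr(config.numeric_biomarker, "marking", None)),
    ):
        if bm is None:
            continue
        arm_cfg = config.arm_a if bm.enriched_arm == "A" else config.arm_b
        counts = allocate_subgroup_counts(
            n_arm,
            arm_cfg.lts_fraction,
            (arm_cfg.lts.survivor_fraction, arm_cfg.sts.survivor_fraction),
        )
        fractions = (
            counts[0] / n_arm,
            counts[1] / n_arm,
            (counts[2] + counts[3]) / n_arm,
        )
        try:
            compute_p3(bm.p1, bm.p2, bm.prevalence, fractions)
        except SurvgenError as err:
            raise ConfigurationError(f"{label}: {err}") from None
    return achieved_weighted_delta(config)


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for item in err.errors():
        pointer = "/" + "/".join(str(loc) for loc in item["loc"])
        lines.append(f"{pointer}: {item['msg']}")
    return "configuration schema violations:\n  " + "\n  ".join(lines)


def read_config_file(path) -> tuple:
    """Parse and fully validate a JSON configuration file.

    Returns ``(CohortConfig, OutputOptions)``.  Malformed JSON, schema
    violations (all listed), and infeasible scientific settings each raise
    :class:`ConfigurationError`.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ConfigurationError(f"malformed JSON in {path}: {err}") from None
    try:
        model = _ConfigFileModel.model_validate(raw)
    except ValidationError as err:
        raise ConfigurationError(_format_validation_error(err)) from None
    config = _to_core(model)
    validate_config(config)
    options = OutputOptions(
        include_truth=model.include_truth, output=model.output, plot=model.plot
    )
    return config, options


def read_config(path) -> CohortConfig:
    """Parse a JSON configuration file into a validated :class:`CohortConfig`."""
    config, _ = read_config_file(path)
    return config
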