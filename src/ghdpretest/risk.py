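"""The pre-test probability model and its risk-class stratification.

The published model estimates the probability of adult GH deficiency
before any stimulation test from two predictors:

    P = e^z / (1 + e^z),   z = β_D·D − |β_S|·S + β₀

with S the IGF-I standard-deviation score, D the other-pituitary-deficits
flag (yes = 1), and published coefficients β₀ = −1.77, β_S = −1.27,
β_D = +1.82. Because the model is linear on the log-odds scale, the IGF-I
SDS cut-off giving any target probability q has the closed form

    S*(q, D) = (logit(q) − β₀ − β_D·D) / β_S,

which reproduces the published 25% / 50% / 75% cut-off table. Risk classes
use strict boundaries: P < 0.25 is low, P > 0.75 is high, everything else
(including the boundary values exactly) is intermediate.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

from .clinical import PatientRecord, ReferenceRange, ValidationError

__all__ = [
    "LogisticRiskModel",
    "PUBLISHED_MODEL",
    "RiskClass",
    "RiskAssessment",
    "predict_probability",
    "invert_cutoff",
    "assess",
    "round_half_away",
]


class RiskClass(enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


LOW_BOUNDARY = 0.25
HIGH_BOUNDARY = 0.75


@dataclass(frozen=True)
class LogisticRiskModel:
    """Intercept and two log-odds coefficients, with a provenance tag."""

    intercept: float
    coef_igf_sds: float
    coef_deficits: float
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        for name in ("intercept", "coef_igf_sds", "coef_deficits"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def linear_predictor(self, igf_sds: float, other_deficits: bool) -> float:
        return (
            self.intercept
            + self.coef_igf_sds * igf_sds
            + self.coef_deficits * (1.0 if other_deficits else 0.0)
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_igf_sds": self.coef_igf_sds,
            "coef_deficits": self.coef_deficits,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "LogisticRiskModel":
        return cls(
            intercept=float(payload["intercept"]),
            coef_igf_sds=float(payload["coef_igf_sds"]),
            coef_deficits=float(payload["coef_deficits"]),
            provenance=str(payload.get("provenance", "fitted")),
        )


#: The published model, shipped as a versioned constant. Coefficients are the
#: printed two-decimal values; anything re-fitted carries provenance "fitted".
PUBLISHED_MODEL = LogisticRiskModel(
    intercept=-1.77,
    coef_igf_sds=-1.27,
    coef_deficits=1.82,
    provenance="published",
)


@dataclass(frozen=True)
class RiskAssessment:
    probability: float
    risk_class: RiskClass
    igf_sds: float
    other_deficits: bool

    def to_dict(self) -> dict:
        return {
            "probability": self.probability,
            "risk_class": self.risk_class.value,
            "igf_sds": self.igf_sds,
            "other_deficits": self.other_deficits,
        }


def predict_probability(
    model: LogisticRiskModel, igf_sds: float, other_deficits: bool
) -> float:
    """GHD probability logistic(β₀ + β_S·S + β_D·D) for one patient."""
    if not math.isfinite(igf_sds):
        raise ValidationError(f"igf_sds must be finite, got {igf_sds}")
    z = model.linear_predictor(igf_sds, other_deficits)
    return 1.0 / (1.0 + math.exp(-z))


def invert_cutoff(
    model: LogisticRiskModel, target_probability: float, other_deficits: bool
) -> float:
    """IGF-I SDS at which the model's probability equals the target.

    Solves logit(q) = β₀ + β_S·S + β_D·D for S. Unique whenever β_S ≠ 0.
    """
    if not (0.0 < target_probability < 1.0):
        raise ValidationError(
            f"target probability must be in (0, 1), got {target_probability}"
        )
    if model.coef_igf_sds == 0.0:
        raise ValidationError(
            "IGF-I SDS coefficient is zero; the cut-off is not uniquely defined"
        )
    logit_q = math.log(target_probability / (1.0 - target_probability))
    d = 1.0 if other_deficits else 0.0
    return (logit_q - model.intercept - model.coef_deficits * d) / model.coef_igf_sds


#: absolute tolerance when comparing a probability against a class boundary,
#: so that a cut-off recovered by floating-point inversion still classifies
#: as the boundary (intermediate) case
BOUNDARY_ATOL = 1e-12


def classify_probability(p: float) -> RiskClass:
    if p < LOW_BOUNDARY - BOUNDARY_ATOL:
        return RiskClass.LOW
    if p > HIGH_BOUNDARY + BOUNDARY_ATOL:
        return RiskClass.HIGH
    return RiskClass.INTERMEDIATE


def assess(
    model: LogisticRiskModel,
    record: PatientRecord,
    ref: ReferenceRange | None = None,
) -> RiskAssessment:
    """Pre-test probability and risk class for one patient record."""
    missing = []
    try:
        sds = record.resolve_igf_sds(ref)
    except ValidationError:
        missing.append("igf_i_sds (or igf_i + age reference)")
    if record.other_deficits is None:
        missing.append("other_deficits")
    if missing:
        raise ValidationError(
            f"patient {record.id}: missing required fields: {', '.join(missing)}"
        )
    p = predict_probability(model, sds, record.other_deficits)
    return RiskAssessment(
        probability=p,
        risk_class=classify_probability(p),
        igf_sds=sds,
        other_deficits=bool(record.other_deficits),
    )


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero, matching clinical-table presentation."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
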