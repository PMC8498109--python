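"""Clinical domain primitives for adult GH-deficiency work-up.

This module holds the deterministic clinical layer that everything else
builds on: the patient record schema, age-referenced IGF-I standard
deviation scores, BMI classes, the BMI-stratified peak-GH cut-offs for the
two stimulation tests (insulin tolerance test and GHRH + arginine), and the
two-test concordance rule that defines who counts as GH-deficient, normal,
or excluded from analysis.

Conventions
-----------
* A peak GH response is *normal* only when it strictly exceeds the
  BMI-class threshold; equality is classified deficient.
* BMI class boundaries are closed on the left: BMI 25.0 is overweight,
  BMI 30.0 is obese.
* Patients whose two stimulation tests disagree are *discordant* and are
  excluded from model development.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BmiClass",
    "ConcordanceStatus",
    "GhResponse",
    "GhdLabel",
    "PatientRecord",
    "ReferenceBracket",
    "ReferenceRange",
    "StimulationTest",
    "ValidationError",
    "AgeOutOfRangeError",
    "igf_sds",
    "bmi_class",
    "classify_gh_response",
    "concordance_status",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_reference_csv",
    "cohort_to_frame",
]


class ValidationError(ValueError):
    """An input violates a clinical-schema invariant."""


class AgeOutOfRangeError(ValidationError):
    """Age falls outside the supplied IGF-I reference coverage."""


class BmiClass(enum.Enum):
    LEAN = "lean"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class StimulationTest(enum.Enum):
    ITT = "ITT"
    GHRH_ARG = "GHRH_ARG"


class GhResponse(enum.Enum):
    NORMAL = "normal"
    DEFICIENT = "deficient"


class ConcordanceStatus(enum.Enum):
    CONCORDANT_DEFICIENT = "concordant_deficient"
    CONCORDANT_NORMAL = "concordant_normal"
    DISCORDANT = "discordant"


class GhdLabel(enum.Enum):
    GHD = "GHD"
    NORMAL = "normal"
    UNKNOWN = "unknown"


# Peak-GH thresholds (µg/l) above which the response is normal, by BMI class.
GHRH_ARG_THRESHOLDS = {
    BmiClass.LEAN: 11.0,
    BmiClass.OVERWEIGHT: 8.0,
    BmiClass.OBESE: 4.0,
}
ITT_THRESHOLDS = {
    BmiClass.LEAN: 3.5,
    BmiClass.OVERWEIGHT: 1.3,
    BmiClass.OBESE: 1.3,
}


@dataclass(frozen=True)
class ReferenceBracket:
    """One age bracket of an IGF-I normative table, half-open [age_min, age_max)."""

    age_min: float
    age_max: float
    igf_mean: float
    igf_sd: float

    def __post_init__(self) -> None:
        if not (self.age_min < self.age_max):
            raise ValidationError(
                f"reference bracket must have age_min < age_max, got [{self.age_min}, {self.age_max})"
            )
        if not (self.igf_sd > 0):
            raise ValidationError(f"reference bracket SD must be > 0, got {self.igf_sd}")

    def contains(self, age: float) -> bool:
        return self.age_min <= age < self.age_max


class ReferenceRange:
    """Ordered, non-overlapping age brackets with IGF-I mean and SD.

    The normative values are user-supplied (e.g. from a published healthy
    reference population); no default table is bundled.
    """

    def __init__(self, brackets: Sequence[ReferenceBracket]):
        if not brackets:
            raise ValidationError("reference range needs at least one bracket")
        ordered = sorted(brackets, key=lambda b: b.age_min)
        for lo, hi in zip(ordered, ordered[1:]):
            if hi.age_min < lo.age_max:
                raise ValidationError(
                    f"overlapping reference brackets: [{lo.age_min}, {lo.age_max}) and "
                    f"[{hi.age_min}, {hi.age_max})"
                )
        self.brackets: tuple[ReferenceBracket, ...] = tuple(ordered)

    def lookup(self, age: float) -> ReferenceBracket:
        for bracket in self.brackets:
            if bracket.contains(age):
                return bracket
        raise AgeOutOfRangeError(
            f"age {age} outside reference coverage "
            f"[{self.brackets[0].age_min}, {self.brackets[-1].age_max})"
        )


@dataclass
class PatientRecord:
    """One subject's clinical covariates, stimulation-test peaks, and label.

    ``igf_i_sds`` may be given directly, or derived from ``igf_i`` + ``age``
    and a :class:`ReferenceRange`. At least one route must be available.
    """

    id: str
    age: float
    sex: str
    bmi: float
    other_deficits: bool
    igf_i: float | None = None
    igf_i_sds: float | None = None
    itt_peak_gh: float | None = None
    ghrh_arg_peak_gh: float | None = None
    ghd_label: GhdLabel = GhdLabel.UNKNOWN

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"patient {self.id}: age must be > 0, got {self.age}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"patient {self.id}: sex must be female/male, got {self.sex!r}")
        if not (math.isfinite(self.bmi) and self.bmi > 0):
            raise ValidationError(f"patient {self.id}: bmi must be finite and > 0, got {self.bmi}")
        if self.igf_i is None and self.igf_i_sds is None:
            raise ValidationError(
                f"patient {self.id}: needs igf_i_sds or igf_i (with an age reference)"
            )
        for name in ("igf_i", "itt_peak_gh", "ghrh_arg_peak_gh"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"patient {self.id}: {name} must be >= 0, got {value}")
        if isinstance(self.ghd_label, str):
            self.ghd_label = GhdLabel(self.ghd_label)

    def resolve_igf_sds(self, ref: ReferenceRange | None = None) -> float:
        """Return the IGF-I SDS, preferring a supplied score over derivation.

        When both a supplied SDS and the raw-value route are available the
        supplied score wins (it may come from a reference table we do not
        have) and a warning is logged.
        """
        if self.igf_i_sds is not None:
            if self.igf_i is not None and ref is not None:
                logger.warning(
                    "patient %s: both igf_i_sds and (igf_i, reference) supplied; "
                    "using the supplied SDS",
                    self.id,
                )
            return self.igf_i_sds
        if ref is None:
            raise ValidationError(
                f"patient {self.id}: igf_i_sds absent and no reference range supplied"
            )
        return igf_sds(self.igf_i, self.age, ref)

    def bmi_class(self) -> BmiClass:
        return bmi_class(self.bmi)


def igf_sds(igf_i: float, age: float, ref: ReferenceRange) -> float:
    """IGF-I standard-deviation score: (value − age-specific mean) / age-specific SD."""
    if igf_i is None or igf_i < 0:
        raise ValidationError(f"igf_i must be >= 0, got {igf_i}")
    bracket = ref.lookup(age)
    return (igf_i - bracket.igf_mean) / bracket.igf_sd


def bmi_class(bmi: float) -> BmiClass:
    """Lean below 25 kg/m², overweight in [25, 30), obese at or above 30."""
    if not (isinstance(bmi, (int, float)) and math.isfinite(bmi) and bmi > 0):
        raise ValidationError(f"bmi must be finite and > 0, got {bmi}")
    if bmi < 25.0:
        return BmiClass.LEAN
    if bmi < 30.0:
        return BmiClass.OVERWEIGHT
    return BmiClass.OBESE


def classify_gh_response(
    test: StimulationTest | str,
    peak_gh: float,
    bmi_cls: BmiClass,
) -> GhResponse:
    """Classify a stimulation-test peak against its BMI-class threshold.

    Normal requires the peak to strictly exceed the threshold; a peak equal
    to the threshold is deficient.
    """
    if isinstance(test, str):
        try:
            test = StimulationTest(test)
        except ValueError:
            raise ValidationError(f"unknown stimulation test {test!r}") from None
    if peak_gh is None or peak_gh < 0:
        raise ValidationError(f"peak_gh must be >= 0, got {peak_gh}")
    thresholds = ITT_THRESHOLDS if test is StimulationTest.ITT else GHRH_ARG_THRESHOLDS
    return GhResponse.NORMAL if peak_gh > thresholds[bmi_cls] else GhResponse.DEFICIENT


def concordance_status(itt_result: GhResponse, ghrh_result: GhResponse) -> ConcordanceStatus:
    """Combine the two test results into the analysis-population rule."""
    if itt_result is GhResponse.DEFICIENT and ghrh_result is GhResponse.DEFICIENT:
        return ConcordanceStatus.CONCORDANT_DEFICIENT
    if itt_result is GhResponse.NORMAL and ghrh_result is GhResponse.NORMAL:
        return ConcordanceStatus.CONCORDANT_NORMAL
    return ConcordanceStatus.DISCORDANT


# ---------------------------------------------------------------------------
# File I/O

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "bmi",
    "igf_i",
    "igf_i_sds",
    "other_deficits",
    "itt_peak_gh",
    "ghrh_arg_peak_gh",
    "ghd_label",
]


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort file (comma-delimited, header row, booleans as 0/1)."""
    frame = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in ("id", "age", "sex", "bmi", "other_deficits") if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort file missing required columns: {missing}")
    records = []
    for row_number, row in enumerate(frame.to_dict("records"), start=2):
        try:
            records.append(
                PatientRecord(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    bmi=float(row["bmi"]),
                    other_deficits=bool(int(row["other_deficits"])),
                    igf_i=_optional_float(row.get("igf_i")),
                    igf_i_sds=_optional_float(row.get("igf_i_sds")),
                    itt_peak_gh=_optional_float(row.get("itt_peak_gh")),
                    ghrh_arg_peak_gh=_optional_float(row.get("ghrh_arg_peak_gh")),
                    ghd_label=GhdLabel(row.get("ghd_label", "unknown"))
                    if isinstance(row.get("ghd_label"), str)
                    else GhdLabel.UNKNOWN,
                )
            )
        except (ValidationError, KeyError, TypeError) as exc:
            raise ValidationError(f"cohort file row {row_number}: {exc}") from exc
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "bmi": r.bmi,
                "igf_i": r.igf_i,
                "igf_i_sds": r.igf_i_sds,
                "other_deficits": int(r.other_deficits),
                "itt_peak_gh": r.itt_peak_gh,
                "ghrh_arg_peak_gh": r.ghrh_arg_peak_gh,
                "ghd_label": r.ghd_label.value,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_reference_csv(path) -> ReferenceRange:
    """Read a reference-range table with columns age_min, age_max, igf_mean, igf_sd."""
    frame = pd.read_csv(path)
    required = ["age_min", "age_max", "igf_mean", "igf_sd"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"reference file missing columns: {missing}")
    brackets = [
        ReferenceBracket(row.age_min, row.age_max, row.igf_mean, row.igf_sd)
        for row in frame.itertuples()
    ]
    return ReferenceRange(brackets)
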