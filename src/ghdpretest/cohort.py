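"""Synthetic patient cohorts with the statistical structure of the study population.

The generator emulates a tertiary-centre adult cohort worked up for
suspected GH deficiency: a high GHD prevalence (54/80), group-conditional
Gaussian IGF-I SDS (GHD −1.03 ± 0.90, non-GHD −0.16 ± 0.89),
group-conditional prevalence of other pituitary deficits (72.2% vs 30.8%),
and group-conditional age and BMI marginals. Covariates are conditionally
independent given the GHD label, because only marginal group statistics are
available for the real cohort.

Because the generative model is an equal-variance Gaussian discriminant
plus an independent binary covariate, the true posterior log-odds of GHD
are exactly linear in the covariates, with closed-form coefficients
(:func:`implied_coefficients`) — which makes the generator a
parameter-recovery oracle for the fitting pipeline.

Optional simulation of the two stimulation-test outcomes at configurable
sensitivity/specificity reconstructs the concordant/discordant exclusion
flow of the analysis population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .clinical import (
    GHRH_ARG_THRESHOLDS,
    ITT_THRESHOLDS,
    GhdLabel,
    PatientRecord,
    ValidationError,
    bmi_class,
)

__all__ = [
    "CohortParams",
    "GenerativeTruth",
    "generate_cohort",
    "implied_coefficients",
    "simulate_test_outcomes",
]

AGE_RANGE = (18.0, 90.0)
BMI_RANGE = (15.0, 60.0)


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters; defaults reproduce the study's group statistics."""

    n: int = 80
    ghd_prevalence: float = 54.0 / 80.0
    igf_sds_mean_ghd: float = -1.03
    igf_sds_sd_ghd: float = 0.90
    igf_sds_mean_normal: float = -0.16
    igf_sds_sd_normal: float = 0.89
    deficit_prev_ghd: float = 0.722
    deficit_prev_normal: float = 0.308
    age_mean_ghd: float = 49.9
    age_sd_ghd: float = 11.8
    age_mean_normal: float = 43.3
    age_sd_normal: float = 14.8
    bmi_mean_ghd: float = 26.7
    bmi_sd_ghd: float = 5.2
    bmi_mean_normal: float = 25.1
    bmi_sd_normal: float = 5.8
    female_prev_ghd: float = 0.37
    female_prev_normal: float = 0.50
    test_sensitivity: float | None = None
    test_specificity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        for name in (
            "ghd_prevalence",
            "deficit_prev_ghd",
            "deficit_prev_normal",
            "female_prev_ghd",
            "female_prev_normal",
        ):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {value}")
        for name in (
            "igf_sds_sd_ghd",
            "igf_sds_sd_normal",
            "age_sd_ghd",
            "age_sd_normal",
            "bmi_sd_ghd",
            "bmi_sd_normal",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("test_sensitivity", "test_specificity"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {value}")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class GenerativeTruth:
    """The exact posterior log-odds coefficients implied by the generator.

    For equal-variance (pooled) group Gaussians and a conditionally
    independent binary covariate, Bayes' rule gives log-odds linear in the
    covariates:

        slope_igf_sds  = (μ_GHD − μ_normal) / σ̄²
        slope_deficits = logit(p_GHD) − logit(p_normal)
        intercept      = logit(π) − (μ_GHD² − μ_normal²) / (2σ̄²)
                         + ln((1 − p_GHD) / (1 − p_normal))

    with σ̄² the prevalence-weighted pooled variance and π the GHD prevalence.
    """

    intercept: float
    coef_igf_sds: float
    coef_deficits: float
    pooled_variance: float

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_igf_sds": self.coef_igf_sds,
            "coef_deficits": self.coef_deficits,
            "pooled_variance": self.pooled_variance,
        }


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def implied_coefficients(params: CohortParams) -> GenerativeTruth:
    """Closed-form logistic coefficients of the generative posterior."""
    pi = params.ghd_prevalence
    pooled = pi * params.igf_sds_sd_ghd**2 + (1.0 - pi) * params.igf_sds_sd_normal**2
    if pooled <= 0.0:
        raise ValidationError("pooled variance must be positive")
    slope_s = (params.igf_sds_mean_ghd - params.igf_sds_mean_normal) / pooled
    slope_d = _logit(params.deficit_prev_ghd) - _logit(params.deficit_prev_normal)
    intercept = (
        _logit(pi)
        - (params.igf_sds_mean_ghd**2 - params.igf_sds_mean_normal**2) / (2.0 * pooled)
        + math.log((1.0 - params.deficit_prev_ghd) / (1.0 - params.deficit_prev_normal))
    )
    return GenerativeTruth(
        intercept=intercept,
        coef_igf_sds=slope_s,
        coef_deficits=slope_d,
        pooled_variance=pooled,
    )


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a labeled synthetic cohort, deterministic for a given seed.

    Labels are Bernoulli(prevalence); within each label, IGF-I SDS, age and
    BMI are Gaussian (age and BMI clipped to plausible adult ranges) and the
    other-deficits flag is Bernoulli, all mutually independent given the
    label. When the params carry test error rates, peak-GH values for both
    stimulation tests are simulated as well.
    """
    rng = np.random.default_rng(params.seed)
    ghd = rng.random(params.n) < params.ghd_prevalence

    def by_group(mean_ghd, sd_ghd, mean_norm, sd_norm):
        mean = np.where(ghd, mean_ghd, mean_norm)
        sd = np.where(ghd, sd_ghd, sd_norm)
        return rng.normal(mean, sd)

    igf_sds = by_group(
        params.igf_sds_mean_ghd,
        params.igf_sds_sd_ghd,
        params.igf_sds_mean_normal,
        params.igf_sds_sd_normal,
    )
    age = np.clip(
        by_group(params.age_mean_ghd, params.age_sd_ghd, params.age_mean_normal, params.age_sd_normal),
        *AGE_RANGE,
    )
    bmi = np.clip(
        by_group(params.bmi_mean_ghd, params.bmi_sd_ghd, params.bmi_mean_normal, params.bmi_sd_normal),
        *BMI_RANGE,
    )
    deficit_p = np.where(ghd, params.deficit_prev_ghd, params.deficit_prev_normal)
    deficits = rng.random(params.n) < deficit_p
    female_p = np.where(ghd, params.female_prev_ghd, params.female_prev_normal)
    female = rng.random(params.n) < female_p

    width = len(str(params.n))
    records = [
        PatientRecord(
            id=f"P{i + 1:0{width}d}",
            age=float(age[i]),
            sex="female" if female[i] else "male",
            bmi=float(bmi[i]),
            other_deficits=bool(deficits[i]),
            igf_i_sds=float(igf_sds[i]),
            ghd_label=GhdLabel.GHD if ghd[i] else GhdLabel.NORMAL,
        )
        for i in range(params.n)
    ]
    if params.test_sensitivity is not None and params.test_specificity is not None:
        records = simulate_test_outcomes(
            records,
            params.test_sensitivity,
            params.test_specificity,
            seed=params.seed + 1,
        )
    return records


def _peak_for_result(rng, threshold: float, deficient: bool) -> float:
    # a peak value consistent with the intended classification: deficient
    # peaks land in [0, threshold], normal peaks strictly above it
    if deficient:
        return float(rng.uniform(0.0, threshold))
    return float(rng.uniform(threshold + 1e-6, threshold + 10.0))


def simulate_test_outcomes(
    cohort: list[PatientRecord],
    sens: float,
    spec: float,
    seed: int,
) -> list[PatientRecord]:
    """Simulate peak-GH outcomes of both stimulation tests, independently.

    For a GHD patient each test is deficient with probability ``sens``; for
    a non-GHD patient with probability ``1 − spec``. The simulated peak GH
    values are drawn to be consistent with the patient's BMI-class
    threshold, so re-classifying them reproduces the intended results and
    the concordant/discordant exclusion flow can be reconstructed.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValidationError("sens and spec must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for record in cohort:
        is_ghd = record.ghd_label is GhdLabel.GHD
        p_deficient = sens if is_ghd else 1.0 - spec
        cls = bmi_class(record.bmi)
        itt_deficient = rng.random() < p_deficient
        ghrh_deficient = rng.random() < p_deficient
        out.append(
            replace(
                record,
                itt_peak_gh=_peak_for_result(rng, ITT_THRESHOLDS[cls], itt_deficient),
                ghrh_arg_peak_gh=_peak_for_result(
                    rng, GHRH_ARG_THRESHOLDS[cls], ghrh_deficient
                ),
            )
        )
    return out
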