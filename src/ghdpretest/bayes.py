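"""Bayesian pre-/post-test probability calculus for GH stimulation tests.

A stimulation test with sensitivity ``sens`` and specificity ``spec``
updates a pre-test probability ``pre`` by Bayes' theorem:

    positive (deficient GH response):
        post = sens·pre / (sens·pre + (1 − spec)·(1 − pre))
    negative (normal GH response):
        post = (1 − sens)·pre / ((1 − sens)·pre + spec·(1 − pre))

Here a *positive* result means a deficient GH response — the test is a test
FOR GH deficiency — which is the sign convention used throughout.

With sensitivity = specificity = 0.90 (the conventional working values for
these tests; literature ranges run 87–96% sensitivity and 79–92%
specificity), a pre-test probability below 25% cannot be pushed above 75%
by a single positive result, and a pre-test probability above 75% cannot be
pushed below 25% by a single negative result. The flow-chart logic turns
that observation into a recommendation: when a single test result
contradicts a confident prior, advise a second stimulation test rather than
concluding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .risk import HIGH_BOUNDARY, LOW_BOUNDARY

__all__ = [
    "TestCharacteristics",
    "TestResult",
    "Decision",
    "Recommendation",
    "DEFAULT_TEST",
    "SENSITIVITY_RANGE",
    "SPECIFICITY_RANGE",
    "post_test_probability",
    "flowchart_decision",
]


class DegeneratePriorError(ValueError):
    """Prior of exactly 0 or 1 cannot be updated (posterior equals prior)."""


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity and specificity of a stimulation test, both in (0, 1)."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must be strictly inside (0, 1), got {value}")

    @property
    def informative(self) -> bool:
        return self.sensitivity + self.specificity > 1.0

    @property
    def positive_likelihood_ratio(self) -> float:
        return self.sensitivity / (1.0 - self.specificity)

    @property
    def negative_likelihood_ratio(self) -> float:
        return (1.0 - self.sensitivity) / self.specificity


#: Working assumption for both stimulation tests.
DEFAULT_TEST = TestCharacteristics(sensitivity=0.90, specificity=0.90)
#: Literature ranges, offered as named presets.
SENSITIVITY_RANGE = (0.87, 0.96)
SPECIFICITY_RANGE = (0.79, 0.92)


class TestResult(enum.Enum):
    # "deficient"/"normal" are the clinical spellings; positive == deficient.
    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def parse(cls, value) -> "TestResult":
        if isinstance(value, cls):
            return value
        aliases = {
            "positive": cls.POSITIVE,
            "deficient": cls.POSITIVE,
            "negative": cls.NEGATIVE,
            "normal": cls.NEGATIVE,
        }
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ValueError(f"unknown test result {value!r}") from None


class Decision(enum.Enum):
    GHD_CONFIRMED = "GHD_confirmed"
    GHD_EXCLUDED = "GHD_excluded"
    SECOND_TEST_ADVISED = "second_test_advised"


@dataclass(frozen=True)
class Recommendation:
    decision: Decision
    post_test_probability: float
    rationale: str

    def to_dict(self) -> dict:
        return {
            "decision": self.decision.value,
            "post_test_probability": self.post_test_probability,
            "rationale": self.rationale,
        }


def post_test_probability(
    pre: float, test: TestCharacteristics, result: TestResult | str
) -> float:
    """Posterior disease probability after one test result, by Bayes' theorem."""
    if pre <= 0.0 or pre >= 1.0:
        raise DegeneratePriorError(
            f"pre-test probability must be strictly inside (0, 1), got {pre}"
        )
    result = TestResult.parse(result)
    if result is TestResult.POSITIVE:
        num = test.sensitivity * pre
        denom = num + (1.0 - test.specificity) * (1.0 - pre)
    else:
        num = (1.0 - test.sensitivity) * pre
        denom = num + test.specificity * (1.0 - pre)
    return num / denom


def flowchart_decision(
    pre: float,
    result: TestResult | str,
    test: TestCharacteristics = DEFAULT_TEST,
) -> Recommendation:
    """Integrated diagnostic recommendation from prior and one test result.

    A confident prior contradicted by the test result (low prior with a
    deficient response, or high prior with a normal response) yields advice
    to run a second stimulation test. A confident prior confirmed by the
    result concludes the work-up. For intermediate priors the
    recommendation follows the test result, always annotated with the
    posterior probability.
    """
    result = TestResult.parse(result)
    post = post_test_probability(pre, test, result)
    deficient = result is TestResult.POSITIVE
    if pre < LOW_BOUNDARY:
        if deficient:
            return Recommendation(
                Decision.SECOND_TEST_ADVISED,
                post,
                "low pre-test probability with a deficient GH response: a single "
                "positive test cannot confirm GHD; a second stimulation test is advised",
            )
        return Recommendation(
            Decision.GHD_EXCLUDED,
            post,
            "low pre-test probability with a normal GH response: GHD excluded",
        )
    if pre > HIGH_BOUNDARY:
        if deficient:
            return Recommendation(
                Decision.GHD_CONFIRMED,
                post,
                "high pre-test probability with a deficient GH response: GHD confirmed",
            )
        return Recommendation(
            Decision.SECOND_TEST_ADVISED,
            post,
            "high pre-test probability with a normal GH response: a single "
            "negative test cannot exclude GHD; a second stimulation test is advised",
        )
    if deficient:
        return Recommendation(
            Decision.GHD_CONFIRMED,
            post,
            "intermediate pre-test probability: following the deficient GH response",
        )
    return Recommendation(
        Decision.GHD_EXCLUDED,
        post,
        "intermediate pre-test probability: following the normal GH response",
    )
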