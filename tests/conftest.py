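import numpy as np
import pytest

from ghdpretest import CohortParams, ReferenceBracket, ReferenceRange, generate_cohort


@pytest.fixture
def reference_range():
    """A small adult IGF-I normative table spanning ages 20–80."""
    return ReferenceRange(
        [
            ReferenceBracket(20, 40, 200.0, 60.0),
            ReferenceBracket(40, 60, 150.0, 50.0),
            ReferenceBracket(60, 80, 100.0, 25.0),
        ]
    )


@pytest.fixture
def study_cohort():
    """An 80-patient synthetic cohort at the study's generative defaults."""
    return generate_cohort(CohortParams(n=80, seed=42))


@pytest.fixture
def large_cohort():
    """A large cohort for parameter-recovery checks."""
    return generate_cohort(CohortParams(n=20_000, seed=7))


def grid_search_logistic(x, y, lo=-8.0, hi=8.0, points=201, refinements=6):
    """Brute-force 2-D grid maximizer of the logistic log-likelihood.

    Independent oracle for one-predictor fits: iteratively refines a
    (intercept, slope) grid around the running maximum. Accurate to well
    below 1e-3 after six refinements.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def loglik(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    b0_range, b1_range = (lo, hi), (lo, hi)
    for _ in range(refinements):
        g0 = np.linspace(*b0_range, points)
        g1 = np.linspace(*b1_range, points)
        surface = np.array([[loglik(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(surface.argmax(), surface.shape)
        w0 = 2.0 * (b0_range[1] - b0_range[0]) / (points - 1)
        w1 = 2.0 * (b1_range[1] - b1_range[0]) / (points - 1)
        b0_range = (g0[i] - w0, g0[i] + w0)
        b1_range = (g1[j] - w1, g1[j] + w1)
    return (b0_range[0] + b0_range[1]) / 2.0, (b1_range[0] + b1_range[1]) / 2.0


def exhaustive_auc(scores, y):
    """Pairwise-enumeration ROC AUC oracle: ties count one-half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for s1 in pos:
        for s0 in neg:
            if s1 > s0:
                total += 1.0
            elif s1 == s0:
                total += 0.5
    return total / (pos.size * neg.size)
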