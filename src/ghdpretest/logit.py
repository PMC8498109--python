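"""Binary logistic regression with Wald inference, calibration, and discrimination.

These are the statistical primitives the model-development pipeline
composes. The maximum-likelihood fit is computed from scratch by
iteratively reweighted least squares (IRLS); the Hosmer–Lemeshow statistic
and the Mann–Whitney formulation of the ROC AUC are likewise implemented
here rather than delegated, so that each can be cross-checked against an
independent library in the test suite.

Model: P(y=1 | x) = 1 / (1 + exp(−(β₀ + xᵀβ))). Wald standard errors come
from the inverse observed information (XᵀWX)⁻¹ at the MLE; 95% confidence
intervals for odds ratios are exp(β ± 1.96·SE).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "FitResult",
    "CalibrationResult",
    "SeparationError",
    "ConvergenceError",
    "DegenerateGroupsError",
    "fit_logistic",
    "hosmer_lemeshow",
    "roc_auc",
]

Z_95 = 1.959963984540054  # normal 97.5th percentile, the conventional "1.96"


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration cap."""


class DegenerateGroupsError(ValueError):
    """Calibration grouping collapsed below a usable number of groups."""


@dataclass
class FitResult:
    """MLE coefficients (intercept first) with Wald inference."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    n_obs: int = 0

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + Z_95 * self.se)

    @property
    def z_values(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coefficients": self.coef.tolist(),
            "standard_errors": self.se.tolist(),
            "odds_ratios": self.odds_ratios.tolist(),
            "ci_95_lower": self.ci_lower.tolist(),
            "ci_95_upper": self.ci_upper.tolist(),
            "p_values": self.p_values.tolist(),
            "log_likelihood": self.log_likelihood,
            "iterations": self.iterations,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class CalibrationResult:
    """Hosmer–Lemeshow goodness-of-fit summary."""

    statistic: float
    n_groups: int
    df: int
    p_value: float
    observed: np.ndarray = field(repr=False, default=None)
    expected: np.ndarray = field(repr=False, default=None)
    group_sizes: np.ndarray = field(repr=False, default=None)


def _validate_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        X = X.T
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("outcome contains a single class; logistic fit undefined")
    return X, y


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    ll_rtol: float = 1e-10,
    grad_tol: float = 1e-8,
    separation_bound: float = 15.0,
) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    X : (n, p) design matrix WITHOUT an intercept column (added internally).
    y : (n,) outcome in {0, 1}.
    names : predictor names (intercept is prepended).
    max_iter : IRLS iteration cap; exceeding it raises ConvergenceError.
    ll_rtol, grad_tol : convergence declared when the relative log-likelihood
        change drops below ``ll_rtol`` or the score max-norm below ``grad_tol``.
    separation_bound : any |coefficient| beyond this (log-odds scale) with a
        still-improving likelihood raises SeparationError rather than
        returning a silently huge estimate.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    names = ["intercept", *names]

    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise ValueError("design matrix columns are collinear (rank deficient)")

    beta = np.zeros(p + 1)
    ll_old = -n * math.log(2.0)  # log-likelihood at beta = 0
    for iteration in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        info = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular (probable separation or collinearity)"
            ) from exc
        beta_new = beta + step
        eta_new = Xd @ beta_new
        # numerically stable log-likelihood: Σ yη − log(1 + e^η)
        ll_new = float(np.sum(y * eta_new - np.logaddexp(0.0, eta_new)))
        if np.abs(beta_new).max() > separation_bound and ll_new >= ll_old:
            raise SeparationError(
                f"coefficient magnitude exceeded {separation_bound} on the log-odds "
                "scale with still-improving likelihood: data are (quasi-)separated"
            )
        converged = (
            abs(ll_new - ll_old) <= ll_rtol * (abs(ll_old) + 1e-300)
            or np.abs(grad).max() < grad_tol
        )
        beta, ll_old = beta_new, ll_new
        if converged:
            mu = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
            w = mu * (1.0 - mu)
            info = Xd.T @ (Xd * w[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return FitResult(
                names=names,
                coef=beta,
                se=se,
                log_likelihood=ll_old,
                iterations=iteration,
                converged=True,
                n_obs=n,
            )
    raise ConvergenceError(f"IRLS did not converge within {max_iter} iterations")


def hosmer_lemeshow(
    predicted: np.ndarray,
    y: np.ndarray,
    groups: int = 10,
) -> CalibrationResult:
    """Hosmer–Lemeshow chi-squared calibration test on risk-ordered groups.

    Subjects are ranked by predicted probability and split into ``groups``
    near-equal groups; tied probabilities are kept in the same group (which
    can reduce the effective group count). The statistic is

        Σ_g (O_g − E_g)² / (E_g (1 − E_g / m_g))

    with O observed events, E the sum of predicted probabilities, and m the
    group size; the p-value uses a chi-squared with g − 2 degrees of
    freedom. With exactly 2 effective groups the statistic is still
    returned but the p-value is NaN (zero degrees of freedom).
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = predicted.shape[0]
    if y.shape[0] != n:
        raise ValueError("predicted and y differ in length")
    if groups < 2:
        raise ValueError(f"need at least 2 groups, got {groups}")
    if n < groups:
        raise ValueError(f"n={n} smaller than the requested {groups} groups")
    if predicted.min() <= 0.0 or predicted.max() >= 1.0:
        raise ValueError("predicted probabilities must lie strictly inside (0, 1)")

    order = np.argsort(predicted, kind="stable")
    p_sorted = predicted[order]
    y_sorted = y[order]
    # nominal decile-style assignment, then merge ties across boundaries
    nominal = np.floor(np.arange(n) * groups / n).astype(int)
    group_id = nominal.copy()
    for i in range(1, n):
        if p_sorted[i] == p_sorted[i - 1]:
            group_id[i] = group_id[i - 1]

    labels = np.unique(group_id)
    g = labels.size
    if g < 2:
        raise DegenerateGroupsError(
            f"tie-merging left {g} group(s); calibration test undefined"
        )
    observed = np.array([y_sorted[group_id == k].sum() for k in labels])
    expected = np.array([p_sorted[group_id == k].sum() for k in labels])
    sizes = np.array([(group_id == k).sum() for k in labels])

    denom = expected * (1.0 - expected / sizes)
    if np.any(denom <= 0.0):
        raise DegenerateGroupsError(
            "a group has E(1 - E/m) = 0; statistic undefined for that group"
        )
    statistic = float(np.sum((observed - expected) ** 2 / denom))
    df = g - 2
    p_value = float(stats.chi2.sf(statistic, df)) if df >= 1 else float("nan")
    return CalibrationResult(
        statistic=statistic,
        n_groups=int(g),
        df=int(df),
        p_value=p_value,
        observed=observed,
        expected=expected,
        group_sizes=sizes,
    )


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC area via the Mann–Whitney identity, ties counted one-half.

    Over all (event, non-event) pairs, the fraction where the event's score
    is higher, plus half the fraction of exact ties. Computed from midranks
    so it is O(n log n) and exactly equals exhaustive pair enumeration.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and y differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    n1 = int(y.sum())
    n0 = int(y.shape[0] - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    rank_sum_events = float(ranks[y == 1].sum())
    u = rank_sum_events - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)
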