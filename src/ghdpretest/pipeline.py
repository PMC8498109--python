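"""Imbalance-corrected model development and internal validation.

The development procedure fits a two-predictor logistic model (IGF-I SDS,
other-pituitary-deficits flag) for GH deficiency on a cohort whose classes
are unbalanced, correcting the imbalance by random undersampling of the
majority class to a 1:1 ratio, repeating the undersample-and-fit step a
fixed number of times (ten by default) and averaging the coefficient
vectors on the log-odds scale. Calibration is checked per iteration with
the Hosmer–Lemeshow test on the balanced subset; discrimination of the
averaged model is the apparent ROC AUC on the original unbalanced cohort.

Internal validation repeats the *entire* procedure inside each training
split of a stratified k-fold partition (ten folds by default) and averages
the held-out AUCs, estimating performance on unseen data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import GhdLabel, PatientRecord
from .logit import CalibrationResult, FitResult, fit_logistic, hosmer_lemeshow, roc_auc

__all__ = [
    "PipelineConfig",
    "AveragedModelResult",
    "ValidationResult",
    "PipelineError",
    "design_from_cohort",
    "undersample_majority",
    "fit_averaged_model",
    "cross_validate",
]

PREDICTOR_NAMES = ["igf_i_sds", "other_deficits"]


class PipelineError(RuntimeError):
    """A pipeline iteration failed (e.g. separation in a balanced subset)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the development procedure.

    Defaults reproduce the published settings: ten undersampling iterations,
    ten stratified cross-validation folds, deciles of risk for calibration.
    """

    n_undersample_iterations: int = 10
    cv_folds: int = 10
    base_seed: int = 0
    hl_groups: int = 10

    def __post_init__(self) -> None:
        if self.n_undersample_iterations < 1:
            raise ValueError("n_undersample_iterations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class AveragedModelResult:
    """Averaged coefficients plus per-iteration detail and apparent AUC."""

    names: list[str]
    coef: np.ndarray                       # averaged, intercept first
    iteration_coefs: np.ndarray            # (n_iter, p+1)
    iteration_hl: list[CalibrationResult]
    iteration_fits: list[FitResult] = field(repr=False, default_factory=list)
    apparent_auc: float = float("nan")
    base_seed: int = 0

    @property
    def hl_p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.iteration_hl])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coefficients": self.coef.tolist(),
            "iteration_coefficients": self.iteration_coefs.tolist(),
            "iteration_hl_p_values": self.hl_p_values.tolist(),
            "apparent_auc": self.apparent_auc,
            "base_seed": self.base_seed,
        }


@dataclass
class ValidationResult:
    """Stratified k-fold cross-validation of the whole development procedure."""

    fold_aucs: np.ndarray
    fold_assignment: np.ndarray            # fold index per cohort record
    base_seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_dict(self) -> dict:
        return {
            "fold_aucs": self.fold_aucs.tolist(),
            "mean_auc": self.mean_auc,
            "fold_assignment": self.fold_assignment.tolist(),
            "base_seed": self.base_seed,
        }


def design_from_cohort(cohort) -> tuple[np.ndarray, np.ndarray]:
    """Extract (X, y) from a cohort given as records, a DataFrame, or (X, y).

    X columns are IGF-I SDS (continuous) and other-deficits (0/1);
    y is 1 for GH deficiency.
    """
    if isinstance(cohort, tuple) and len(cohort) == 2:
        X = np.asarray(cohort[0], dtype=float)
        y = np.asarray(cohort[1], dtype=float)
        return X, y
    if isinstance(cohort, pd.DataFrame):
        missing = [c for c in ("igf_i_sds", "other_deficits", "ghd_label") if c not in cohort]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")
        X = cohort[["igf_i_sds", "other_deficits"]].to_numpy(dtype=float)
        labels = cohort["ghd_label"]
        y = (labels == "GHD").to_numpy(dtype=float) if labels.dtype == object else labels.to_numpy(dtype=float)
        return X, y
    if len(cohort) > 0 and isinstance(cohort[0], PatientRecord):
        X = np.array(
            [[r.resolve_igf_sds(), float(r.other_deficits)] for r in cohort], dtype=float
        )
        y = np.array([1.0 if r.ghd_label is GhdLabel.GHD else 0.0 for r in cohort])
        return X, y
    raise TypeError("cohort must be PatientRecords, a DataFrame, or an (X, y) tuple")


def undersample_majority(y: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a 1:1 balanced subsample: all minority records plus a
    uniform without-replacement draw of the majority class of equal size.

    Deterministic for a given seed; the returned indices are sorted so the
    subset is order-independent of the draw.
    """
    y = np.asarray(y, dtype=float).ravel()
    idx1 = np.flatnonzero(y == 1.0)
    idx0 = np.flatnonzero(y == 0.0)
    if idx1.size == 0 or idx0.size == 0:
        raise ValueError("undersampling needs both classes present")
    minority, majority = (idx1, idx0) if idx1.size <= idx0.size else (idx0, idx1)
    rng = np.random.default_rng(seed)
    sampled = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, sampled]))


def fit_averaged_model(cohort, config: PipelineConfig) -> AveragedModelResult:
    """Run the iterated undersample-fit-average procedure on a cohort.

    Iteration ``i`` (0-based) uses seed ``base_seed + i + 1`` for the
    majority draw. The averaged coefficients are the arithmetic mean of the
    per-iteration vectors on the log-odds scale; the apparent AUC scores the
    ORIGINAL (unbalanced) cohort with the averaged model.
    """
    X, y = design_from_cohort(cohort)
    coefs, fits, hls = [], [], []
    for i in range(config.n_undersample_iterations):
        seed = config.base_seed + i + 1
        idx = undersample_majority(y, seed)
        try:
            fit = fit_logistic(X[idx], y[idx], names=PREDICTOR_NAMES)
        except Exception as exc:
            raise PipelineError(
                f"undersampling iteration {i} (seed {seed}) failed: {exc}"
            ) from exc
        coefs.append(fit.coef)
        fits.append(fit)
        hls.append(hosmer_lemeshow(fit.predict(X[idx]), y[idx], groups=config.hl_groups))
    iteration_coefs = np.vstack(coefs)
    averaged = iteration_coefs.mean(axis=0)
    result = AveragedModelResult(
        names=["intercept", *PREDICTOR_NAMES],
        coef=averaged,
        iteration_coefs=iteration_coefs,
        iteration_hl=hls,
        iteration_fits=fits,
        base_seed=config.base_seed,
    )
    result.apparent_auc = roc_auc(result.predict(X), y)
    return result


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each record to one of k folds, stratified by outcome.

    Within each class, records are shuffled (seeded) and dealt round-robin,
    so per-fold class proportions differ from the overall by at most one
    record.
    """
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.shape[0], dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {int(cls)} has {idx.size} records, fewer than {k} folds"
            )
        shuffled = rng.permutation(idx)
        assignment[shuffled] = np.arange(shuffled.size) % k
    return assignment


def cross_validate(cohort, config: PipelineConfig) -> ValidationResult:
    """Stratified k-fold cross-validation of the full development procedure.

    For each fold, the iterated undersample-and-average fit is re-run on the
    training records only, and the held-out fold is scored with the averaged
    model; the summary is the unweighted mean of the per-fold AUCs.
    """
    X, y = design_from_cohort(cohort)
    assignment = stratified_folds(y, config.cv_folds, config.base_seed)
    fold_aucs = []
    for fold in range(config.cv_folds):
        test_mask = assignment == fold
        if y[test_mask].min() == y[test_mask].max():
            raise PipelineError(f"validation fold {fold} contains a single class")
        train_config = PipelineConfig(
            n_undersample_iterations=config.n_undersample_iterations,
            cv_folds=config.cv_folds,
            base_seed=config.base_seed + 100_000 * (fold + 1),
            hl_groups=config.hl_groups,
        )
        model = fit_averaged_model((X[~test_mask], y[~test_mask]), train_config)
        fold_aucs.append(roc_auc(model.predict(X[test_mask]), y[test_mask]))
    return ValidationResult(
        fold_aucs=np.array(fold_aucs),
        fold_assignment=assignment,
        base_seed=config.base_seed,
    )
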