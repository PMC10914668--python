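"""Predictive validity of a categorization via leave-one-drug-out PLS.

Any predictor set — the full receptor fingerprint matrix or a one-hot encoded
categorical grouping — is scored by how well it predicts the drug x effect
clinical table out of sample.  For each drug in turn, a partial least squares
(PLS) regression is fitted on the remaining drugs (with missing clinical
values PPCA-imputed within the training fold only), the held-out drug's
effect scores are predicted, and the median absolute error over that drug's
*observed* effects is recorded.  The summary statistic is the median of the
per-drug medians.  Significance comes from a permutation null: shuffling the
drug-to-predictor alignment within the training data breaks the receptor ->
clinical link while preserving both marginals.

Centering and unit-scaling of predictors and targets are computed on each
training fold and applied to the held-out drug, so no statistic of the
held-out drug ever leaks into training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from .ingest import ClinicalProfile, GroupingScheme
from .ppca import fit_ppca, impute
from .preprocess import AdjustedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorMatrix",
    "PLSModel",
    "PredictionReport",
    "encode_predictors",
    "impute_clinical_training",
    "fit_pls",
    "loo_median_error",
    "permutation_test",
]


@dataclass
class PredictorMatrix:
    drugs: list[str]
    X: np.ndarray
    source: str  # "receptor_profile" or "one_hot:<scheme>"

    @property
    def D(self) -> int:
        return self.X.shape[1]


@dataclass
class PLSModel:
    """A fitted multi-target PLS with the fold's standardization baked in."""

    n_components: int
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    estimator: PLSRegression | None  # None when X is degenerate (no variance)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_center) / self.x_scale
        if self.estimator is None:
            Ys = np.zeros((X.shape[0], self.y_center.shape[0]))
        else:
            Ys = self.estimator.predict(Xs)
        return Ys * self.y_scale + self.y_center


@dataclass
class PredictionReport:
    scheme: str
    D: int
    per_drug_errors: dict[str, float]
    observed_median_error: float
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    null_median_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    p_value: float = float("nan")
    n_perm: int = 0
    seed: int | None = None
    n_components: int = 2


def encode_predictors(source: GroupingScheme | AdjustedMatrix) -> PredictorMatrix:
    """One-hot encode a grouping, or pass the completed fingerprint matrix through."""
    if isinstance(source, GroupingScheme):
        cats = source.categories()
        if len(cats) == 1:
            logger.warning(
                "grouping %r has a single category; predictions reduce to the "
                "training mean", source.name,
            )
        drugs = source.drugs
        X = np.zeros((len(drugs), len(cats)))
        for i, d in enumerate(drugs):
            X[i, cats.index(source.assignment[d])] = 1.0
        return PredictorMatrix(drugs=list(drugs), X=X, source=f"one_hot:{source.name}")
    if isinstance(source, AdjustedMatrix):
        if not source.observed.all():
            raise ValueError("fingerprint predictors must be complete; impute first")
        return PredictorMatrix(
            drugs=list(source.drugs), X=source.values.copy(), source="receptor_profile"
        )
    raise TypeError(f"cannot encode predictors from {type(source).__name__}")


def impute_clinical_training(
    training: ClinicalProfile, q: int = 2, seed: int | None = None
) -> np.ndarray:
    """PPCA-complete the training clinical matrix; observed cells unchanged.

    Identity when nothing is missing.  Raises if an effect column has no
    observed training value (nothing to anchor the imputation).
    """
    scores_mat, obs = training.scores, training.observed
    if obs.all():
        return scores_mat.copy()
    empty = [training.effects[j] for j in range(obs.shape[1]) if not obs[:, j].any()]
    if empty:
        raise ValueError(f"effect columns fully missing in training data: {empty}")
    q_eff = min(q, min(scores_mat.shape) - 1)
    model = fit_ppca(scores_mat, q=q_eff, mask=obs, seed=seed)
    return impute(model, scores_mat, obs)


def _standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = A.mean(axis=0)
    scale = A.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through as zeros
    return (A - center) / scale, center, scale


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSModel:
    """Multi-target PLS (NIPALS) on column-standardized X and Y."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training rows")
    if not (1 <= n_components <= min(X.shape[1], n - 1)):
        raise ValueError(
            f"n_components must be in [1, min(D, n-1)] = [1, {min(X.shape[1], n - 1)}]"
        )
    Xs, x_center, x_scale = _standardize(X)
    Ys, y_center, y_scale = _standardize(Y)
    rank = np.linalg.matrix_rank(Xs) if Xs.any() else 0
    est = None  # fallback: no usable predictor variance -> training-mean model
    # NIPALS can exhaust the target residual before the requested number of
    # components (exactly collinear or degenerate folds); retry with fewer
    for k in range(min(n_components, rank), 0, -1):
        cand = PLSRegression(n_components=k, scale=False)
        try:
            with warnings.catch_warnings():
                # candidate fits on exhausted residuals legitimately emit
                # max_iter / constant-residual / 0-division noise; non-finite
                # results are rejected below
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                cand.fit(Xs, Ys)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if np.all(np.isfinite(cand.coef_)):
            est = cand
            break
    return PLSModel(
        n_components=n_components,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        estimator=est,
    )


@dataclass
class _Fold:
    test_idx: int
    train_idx: np.ndarray
    Y_train: np.ndarray          # imputed, original scale
    y_test_obs: np.ndarray       # held-out drug's observed effect values
    obs_cols: np.ndarray         # which effect columns those are


def _make_folds(
    clinical: ClinicalProfile, q_impute: int, seed: int | None
) -> list[_Fold]:
    n = len(clinical.drugs)
    folds = []
    for i in range(n):
        obs_cols = clinical.observed[i]
        if not obs_cols.any():
            logger.warning(
                "drug %r has no observed clinical effects; excluded from LOO",
                clinical.drugs[i],
            )
            continue
        train_idx = np.array([j for j in range(n) if j != i])
        training = ClinicalProfile(
            drugs=[clinical.drugs[j] for j in train_idx],
            effects=list(clinical.effects),
            scores=clinical.scores[train_idx].copy(),
            observed=clinical.observed[train_idx].copy(),
            effect_kind=list(clinical.effect_kind),
        )
        Y_train = impute_clinical_training(training, q=q_impute, seed=seed)
        folds.append(
            _Fold(
                test_idx=i,
                train_idx=train_idx,
                Y_train=Y_train,
                y_test_obs=clinical.scores[i, obs_cols].copy(),
                obs_cols=obs_cols,
            )
        )
    return folds


def _loo_summary(
    X: np.ndarray,
    folds: list[_Fold],
    n_components: int,
    perm_rng: np.random.Generator | None = None,
    shuffle: str = "per_fold",
) -> tuple[float, list[float], list[np.ndarray]]:
    per_drug: list[float] = []
    predictions: list[np.ndarray] = []
    global_perm = None
    if perm_rng is not None and shuffle == "per_replicate":
        global_perm = perm_rng.permutation(X.shape[0])
    for fold in folds:
        Xtr = X[fold.train_idx]
        if perm_rng is not None:
            if shuffle == "per_fold":
                Xtr = Xtr[perm_rng.permutation(Xtr.shape[0])]
            else:
                Xtr = X[global_perm[fold.train_idx]]
        n_comp = min(n_components, Xtr.shape[1], Xtr.shape[0] - 1)
        model = fit_pls(Xtr, fold.Y_train, n_components=n_comp)
        pred = model.predict(X[fold.test_idx])[0]
        predictions.append(pred)
        err = np.abs(pred[fold.obs_cols] - fold.y_test_obs)
        per_drug.append(float(np.median(err)))
    return float(np.median(per_drug)), per_drug, predictions


def loo_median_error(
    predictors: PredictorMatrix,
    clinical: ClinicalProfile,
    n_components: int = 2,
    q_impute: int = 2,
    seed: int | None = None,
) -> PredictionReport:
    """Leave-one-drug-out median absolute prediction error for one scheme.

    Errors are taken only over the held-out drug's observed effects; imputed
    training values are never scored against.
    """
    drugs = [d for d in predictors.drugs if d in clinical.drugs]
    if len(drugs) < 3:
        raise ValueError("need at least 3 drugs shared by predictors and clinical table")
    X = predictors.X[[predictors.drugs.index(d) for d in drugs]]
    clin = clinical.subset(drugs)
    folds = _make_folds(clin, q_impute=q_impute, seed=seed)
    observed, per_drug, preds = _loo_summary(X, folds, n_components)
    return PredictionReport(
        scheme=predictors.source,
        D=predictors.D,
        per_drug_errors={clin.drugs[f.test_idx]: e for f, e in zip(folds, per_drug)},
        observed_median_error=observed,
        predictions={clin.drugs[f.test_idx]: p for f, p in zip(folds, preds)},
        n_components=n_components,
        seed=seed,
    )


def permutation_test(
    predictors: PredictorMatrix,
    clinical: ClinicalProfile,
    n_perm: int = 500,
    seed: int = 0,
    n_components: int = 2,
    q_impute: int = 2,
    shuffle: str = "per_fold",
) -> PredictionReport:
    """Permutation significance of the LOO median error.

    Each null replicate shuffles the drug-to-predictor alignment within the
    training data (fresh permutation per fold under ``shuffle="per_fold"``,
    one shared permutation under ``"per_replicate"``) and recomputes the full
    LOO summary.  p = (1 + #{null <= observed}) / (1 + n_perm): smaller error
    means better prediction, and the add-one rule keeps p strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if shuffle not in ("per_fold", "per_replicate"):
        raise ValueError(f"unknown shuffle mode {shuffle!r}")
    report = loo_median_error(
        predictors, clinical, n_components=n_components, q_impute=q_impute, seed=seed
    )
    drugs = [d for d in predictors.drugs if d in clinical.drugs]
    X = predictors.X[[predictors.drugs.index(d) for d in drugs]]
    clin = clinical.subset(drugs)
    folds = _make_folds(clin, q_impute=q_impute, seed=seed)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        nulls[b], _, _ = _loo_summary(
            X, folds, n_components, perm_rng=rng, shuffle=shuffle
        )
    report.null_median_errors = nulls
    report.n_perm = n_perm
    report.p_value = float(
        (1 + np.sum(nulls <= report.observed_median_error)) / (1 + n_perm)
    )
    return report
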