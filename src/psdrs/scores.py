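"""Propensity-score and disease-risk-score estimation.

A small learner registry wraps scikit-learn probabilistic classifiers:

``reference``
    unpenalized additive logistic regression, no tuning;
``lasso``
    L1-penalized logistic regression, inverse penalty strength C tuned on
    a logarithmic grid;
``gbdt`` (alias ``xgboost``)
    histogram-based gradient-boosted trees;
``mlp``
    multilayer perceptron with one or two hidden layers.

All tuned learners use stratified k-fold cross-validation (default 10
folds) scored by Brier loss, the grid point with the lowest mean held-out
loss winning (ties broken by grid order).  Every learner sees the 56 raw
baseline covariates only — the engineered nonlinear truth terms are never
offered as features, so model misspecification under the nonlinear data
structure is part of the experiment.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import Cohort, NonEstimableError

logger = logging.getLogger(__name__)

SCORE_KINDS = ("PS", "DRS_full_cohort", "DRS_unexposed")

#: probabilities are clipped into this open interval before any logit
CLIP = 1e-6


def brier_loss(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared difference between predicted probabilities and 0/1 outcomes."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    return float(np.mean((predicted - observed) ** 2))


def _reference_factory():
    # tight tolerance so in-sample predictions agree with a direct
    # maximum-likelihood fit to ~1e-6 on well-conditioned cohorts
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10_000, tol=1e-10)


def _lasso_factory():
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "model",
                LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=5000),
            ),
        ]
    )


def _gbdt_factory():
    return HistGradientBoostingClassifier(early_stopping=False)


def _mlp_factory():
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("model", MLPClassifier(max_iter=200, early_stopping=False)),
        ]
    )


#: name -> (estimator factory, default hyperparameter grid)
REGISTRY: dict[str, tuple[Any, dict[str, list]]] = {
    "reference": (_reference_factory, {}),
    "lasso": (_lasso_factory, {"model__C": list(np.logspace(-2, 2, 10))}),
    "gbdt": (
        _gbdt_factory,
        {
            "max_depth": [2, 3, 4],
            "learning_rate": [0.05, 0.1, 0.3],
            "max_iter": [100, 300],
        },
    ),
    "mlp": (
        _mlp_factory,
        {
            "model__hidden_layer_sizes": [(16,), (64,), (16, 16), (64, 64)],
            "model__alpha": [1e-4, 1e-2],
        },
    ),
}

_ALIASES = {"xgboost": "gbdt"}

LEARNER_NAMES = tuple(REGISTRY)


@dataclass
class LearnerSpec:
    """A learner choice plus its tuning protocol."""

    name: str
    hyperparameter_grid: dict[str, list] | None = None
    cv_folds: int = 10
    scoring: str = "brier"

    def __post_init__(self) -> None:
        self.name = _ALIASES.get(self.name, self.name)
        if self.name not in REGISTRY:
            raise ValueError(f"unknown learner {self.name!r}; known: {LEARNER_NAMES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.scoring != "brier":
            raise ValueError("only Brier-loss scoring is supported")
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = {k: list(v) for k, v in REGISTRY[self.name][1].items()}
        if self.name == "reference" and self.hyperparameter_grid:
            raise ValueError("the reference learner takes no hyperparameter grid")

    def make_estimator(self):
        return REGISTRY[self.name][0]()


@dataclass
class ScoreVector:
    """Per-subject PS or DRS values with fit provenance."""

    values: np.ndarray
    kind: str
    learner: LearnerSpec
    tuning_record: dict
    clipped_count: int = 0


def _grid_points(grid: dict[str, list]) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _set_seed(estimator, seed: int):
    for param in ("random_state", "model__random_state"):
        if param in estimator.get_params():
            estimator.set_params(**{param: int(seed)})
    return estimator


def tune_learner(
    features: np.ndarray,
    target: np.ndarray,
    spec: LearnerSpec,
    rng_seed: int,
):
    """Grid-search a learner by stratified k-fold CV on Brier loss and refit.

    Returns ``(fitted_model, tuning_record)``.  The grid point with the
    strictly lowest mean held-out Brier loss wins; ties keep the earlier
    grid point.  If the minority class has fewer cases than ``cv_folds``
    the fold count is reduced to the minority count (with a logged
    warning); with a minority count below 2 tuning degenerates to the
    first grid point.
    """
    features = np.asarray(features, dtype=float)
    target = np.asarray(target, dtype=int)
    if features.shape[0] != target.shape[0]:
        raise ValueError("features and target must have equal length")
    classes, counts = np.unique(target, return_counts=True)
    if len(classes) < 2:
        raise NonEstimableError("single-class target: score model not estimable")

    points = _grid_points(spec.hyperparameter_grid)
    record: dict[str, Any] = {"learner": spec.name, "cv_folds": None, "grid_size": len(points)}

    minority = int(counts.min())
    if len(points) == 1:
        best_point, best_loss = points[0], None
    else:
        folds = spec.cv_folds
        if minority < folds:
            folds = minority
            logger.warning(
                "minority class has %d cases < %d folds; reducing folds to %d",
                minority,
                spec.cv_folds,
                folds,
            )
        if folds < 2:
            logger.warning("cannot cross-validate with minority count %d; using first grid point", minority)
            best_point, best_loss = points[0], None
        else:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng_seed))
            splits = list(cv.split(features, target))
            record["cv_folds"] = folds
            best_point, best_loss = None, np.inf
            for point in points:
                losses = []
                for train_idx, test_idx in splits:
                    est = _set_seed(spec.make_estimator().set_params(**point), rng_seed)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        est.fit(features[train_idx], target[train_idx])
                        pred = est.predict_proba(features[test_idx])[:, 1]
                    losses.append(brier_loss(pred, target[test_idx]))
                mean_loss = float(np.mean(losses))
                if mean_loss < best_loss:
                    best_loss, best_point = mean_loss, point

    model = _set_seed(spec.make_estimator().set_params(**best_point), rng_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(features, target)
    record["chosen"] = {k: (v if np.isscalar(v) else repr(v)) for k, v in best_point.items()}
    record["cv_brier"] = best_loss
    return model, record


def _clip(values: np.ndarray) -> tuple[np.ndarray, int]:
    clipped = np.clip(values, CLIP, 1.0 - CLIP)
    return clipped, int(np.sum(clipped != values))


def fit_propensity(cohort: Cohort, spec: LearnerSpec, rng_seed: int) -> ScoreVector:
    """Estimate P(T=1 | X) in-sample from the 56 raw covariates."""
    features = cohort.X.to_numpy()
    model, record = tune_learner(features, cohort.T, spec, rng_seed)
    values, n_clip = _clip(model.predict_proba(features)[:, 1])
    return ScoreVector(values=values, kind="PS", learner=spec, tuning_record=record, clipped_count=n_clip)


def fit_drs_full_cohort(cohort: Cohort, spec: LearnerSpec, rng_seed: int) -> ScoreVector:
    """Estimate P(Y=1 | T=0, X): fit Y ~ [X, T] on everyone, predict at T=0."""
    features = np.column_stack([cohort.X.to_numpy(), cohort.T.astype(float)])
    model, record = tune_learner(features, cohort.Y, spec, rng_seed)
    at_untreated = features.copy()
    at_untreated[:, -1] = 0.0
    values, n_clip = _clip(model.predict_proba(at_untreated)[:, 1])
    return ScoreVector(
        values=values, kind="DRS_full_cohort", learner=spec, tuning_record=record, clipped_count=n_clip
    )


def fit_drs_unexposed(cohort: Cohort, spec: LearnerSpec, rng_seed: int) -> ScoreVector:
    """Estimate P(Y=1 | X) on the untreated subset, predict for everyone."""
    mask = cohort.T == 0
    features = cohort.X.to_numpy()
    model, record = tune_learner(features[mask], cohort.Y[mask], spec, rng_seed)
    values, n_clip = _clip(model.predict_proba(features)[:, 1])
    return ScoreVector(
        values=values, kind="DRS_unexposed", learner=spec, tuning_record=record, clipped_count=n_clip
    )


_FITTERS = {
    "PS": fit_propensity,
    "DRS_full_cohort": fit_drs_full_cohort,
    "DRS_unexposed": fit_drs_unexposed,
}


def fit_score(cohort: Cohort, kind: str, spec: LearnerSpec, rng_seed: int) -> ScoreVector:
    """Dispatch to the PS or DRS fitter by score kind."""
    try:
        fitter = _FITTERS[kind]
    except KeyError:
        raise ValueError(f"unknown score kind {kind!r}; known: {SCORE_KINDS}") from None
    return fitter(cohort, spec, rng_seed)
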