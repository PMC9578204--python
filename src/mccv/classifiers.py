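"""Pluggable binary-classifier registry with nested inner-CV tuning.

Each registry entry pairs a scikit-learn estimator factory with a small
tuning grid.  ``fit_predict`` tunes the grid by an inner 10-fold CV run on
the training rows only (selection by inner accuracy, ties to the smallest
grid index), refits on the full training rows, and predicts the test rows —
so no information from the test rows ever reaches fitting.

Core methods: lda, glm, bayes, knn, tree, rf, svm_linear, sgb.
Extras: cart (bagged trees), svm_poly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import DegenerateSplitError, InvalidArgumentError, MethodNotFoundError
from .metrics import accuracy, confusion
from .resampling import make_folds
from .rng import as_rng


@dataclass(frozen=True)
class ClassifierSpec:
    """Registry entry: estimator factory plus tuning grid.

    ``tuning_grid`` is an ordered list of parameter dicts; an empty list
    means the estimator is used as-is (no inner CV).
    """

    name: str
    factory: object  # callable(seed: int | None) -> estimator
    tuning_grid: tuple[dict, ...] = ()
    inner_folds: int = 10
    stochastic: bool = False

    def __post_init__(self):
        if self.inner_folds < 2:
            raise InvalidArgumentError("inner_folds must be >= 2")


@dataclass
class PredictionResult:
    """Aligned truth/prediction vectors over the test rows plus chosen parameters."""

    y_true: np.ndarray
    y_pred: np.ndarray
    chosen_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.y_pred = np.asarray(self.y_pred, dtype=int)
        if self.y_true.shape != self.y_pred.shape:
            raise InvalidArgumentError("y_true and y_pred lengths differ")


def _make_lda(seed):
    return LinearDiscriminantAnalysis()


def _make_glm(seed):
    # C=inf: plain unpenalized logistic regression
    return LogisticRegression(C=np.inf, max_iter=1000)


def _make_bayes(seed):
    return GaussianNB()


def _make_knn(seed):
    return KNeighborsClassifier()


def _make_tree(seed):
    return DecisionTreeClassifier(random_state=seed)


def _make_rf(seed):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def _make_svm_linear(seed):
    return SVC(kernel="linear", random_state=seed)


def _make_svm_poly(seed):
    return SVC(kernel="poly", random_state=seed)


def _make_sgb(seed):
    return GradientBoostingClassifier(subsample=0.8, random_state=seed)


def _make_cart(seed):
    return BaggingClassifier(
        DecisionTreeClassifier(), n_estimators=25, random_state=seed
    )


_REGISTRY: dict[str, ClassifierSpec] = {}


def _register(name, factory, grid=(), stochastic=False):
    _REGISTRY[name] = ClassifierSpec(
        name=name, factory=factory, tuning_grid=tuple(grid), stochastic=stochastic
    )


_register("lda", _make_lda)
_register("glm", _make_glm)
_register("bayes", _make_bayes)
_register(
    "knn",
    _make_knn,
    grid=[{"n_neighbors": n} for n in (5, 7, 9)],
)
_register(
    "tree",
    _make_tree,
    grid=[{"ccp_alpha": a} for a in (0.0, 0.01, 0.05)],
)
_register("rf", _make_rf, stochastic=True)
_register(
    "svm_linear",
    _make_svm_linear,
    grid=[{"C": c} for c in (0.25, 0.5, 1.0)],
)
_register(
    "svm_poly",
    _make_svm_poly,
    grid=[{"degree": d, "C": 1.0} for d in (2, 3)],
)
_register(
    "sgb",
    _make_sgb,
    grid=[{"n_estimators": n, "max_depth": d} for n in (50, 100) for d in (1, 2)],
    stochastic=True,
)
_register("cart", _make_cart, stochastic=True)


def list_methods() -> list[ClassifierSpec]:
    """The available registry, in registration order."""
    return list(_REGISTRY.values())


def get_method(name: str) -> ClassifierSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise MethodNotFoundError(name, list(_REGISTRY)) from None


def _inner_cv_select(spec, X_train, y_train, seed) -> dict:
    """Pick the grid entry with the best inner-CV accuracy (ties: first entry)."""
    n_train = len(y_train)
    k = min(spec.inner_folds, n_train)
    if k < 2:
        return dict(spec.tuning_grid[0])
    partition = make_folds(n_train, k, seed=as_rng(seed))
    folds = [partition.fold_indices(label) for label in range(k)]
    scores = np.zeros(len(spec.tuning_grid))
    counts = np.zeros(len(spec.tuning_grid))
    for fold in folds:
        mask = np.ones(n_train, dtype=bool)
        mask[fold] = False
        y_fit, y_val = y_train[mask], y_train[fold]
        if len(np.unique(y_fit)) < 2:
            continue  # unusable inner fold; score on the rest
        for gi, params in enumerate(spec.tuning_grid):
            est = clone_with_params(spec, params, seed)
            est.fit(X_train[mask], y_fit)
            pred = est.predict(X_train[fold])
            scores[gi] += accuracy(confusion(y_val, pred))
            counts[gi] += 1
    if counts.max() == 0:
        return dict(spec.tuning_grid[0])
    mean_scores = scores / np.maximum(counts, 1)
    return dict(spec.tuning_grid[int(np.argmax(mean_scores))])


def clone_with_params(spec: ClassifierSpec, params: dict, seed) -> object:
    est = spec.factory(seed)
    if params:
        est.set_params(**params)
    return est


def fit_predict(
    spec: ClassifierSpec | str,
    table,
    train_indices,
    test_indices,
    seed: int | None = None,
) -> PredictionResult:
    """Tune (inner 10-fold CV on training rows), refit, predict the test rows.

    Raises ``DegenerateSplitError`` when the training outcome has a single
    class.  Deterministic given (spec, table, indices, seed); stochastic
    estimators are seeded through ``seed``.
    """
    if isinstance(spec, str):
        spec = get_method(spec)
    train_indices = np.asarray(train_indices, dtype=int)
    test_indices = np.asarray(test_indices, dtype=int)
    if np.intersect1d(train_indices, test_indices).size:
        raise InvalidArgumentError("train and test indices overlap")
    X_train = table.X[train_indices]
    y_train = table.y[train_indices]
    if len(np.unique(y_train)) < 2:
        raise DegenerateSplitError(
            f"training outcome has a single class ({spec.name})"
        )
    if spec.tuning_grid:
        chosen = _inner_cv_select(spec, X_train, y_train, seed)
    else:
        chosen = {}
    est = clone_with_params(spec, chosen, seed)
    est.fit(X_train, y_train)
    # copy test features so later caller-side mutation cannot alias into results
    y_pred = est.predict(np.array(table.X[test_indices], copy=True))
    return PredictionResult(table.y[test_indices], y_pred, chosen)
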