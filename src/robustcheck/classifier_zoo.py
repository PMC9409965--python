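"""Uniform adapters for the six evaluated classification algorithms.

LDA, linear SVM, random forest (16 trees), one-component PLS-DA, logistic
regression (SAGA) and a 32->16 multilayer perceptron, all behind a common
fit / predict / extract-parameters contract so the Monte Carlo engines can
track test accuracy, LOOCV accuracy and feature-aligned parameter values
without caring which algorithm is underneath.

Parameter extraction returns signed coefficients for the linear models
(LDA, SVM, PLS-DA, LOG) and normalized mean-Gini-decrease importances for
the random forest; the MLP exposes no per-feature parameters and is tracked
for accuracy only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .dataset_core import OmicsTable, make_split, standardize

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "ParamVector",
    "FitResult",
    "fit_classifier",
    "predict",
    "extract_params",
    "loocv_accuracy",
    "wrapper_select_features",
    "prevalence_rank_features",
    "grid_search_hyperparams",
]

ALGORITHMS = ("LDA", "SVM", "RF", "PLSDA", "LOG", "MLP")


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """One-component PLS regression on {0,1} labels, thresholded at 0.5.

    The continuous latent-variable output is compared against a fixed
    decision threshold; outputs exactly at the threshold go to class 1.
    """

    def __init__(self, n_components: int = 1, threshold: float = 0.5):
        self.n_components = n_components
        self.threshold = threshold

    def fit(self, X, y):
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X, np.asarray(y, dtype=float))
        self.coef_ = np.asarray(self.pls_.coef_).reshape(-1)
        return self

    def decision_function(self, X):
        return np.asarray(self.pls_.predict(X)).reshape(-1)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        return (self.decision_function(X) >= self.threshold).astype(int)


@dataclass(frozen=True)
class ClassifierSpec:
    """Which algorithm to run, on which features, with which hyperparameters."""

    algorithm: str
    feature_subset: tuple = ()
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        object.__setattr__(self, "feature_subset", tuple(self.feature_subset))


@dataclass(frozen=True)
class ParamVector:
    """Feature-aligned classifier parameters tracked across corruptions."""

    kind: str  # "coefficient" | "importance" | "none"
    entries: dict  # feature name -> value; empty for kind "none"

    def __post_init__(self):
        if self.kind not in ("coefficient", "importance", "none"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "importance":
            vals = np.array(list(self.entries.values()))
            if (vals < 0).any() or abs(vals.sum() - 1) > 1e-8:
                raise ValueError("importances must be non-negative and sum to 1")

    def as_array(self, feature_order=None) -> np.ndarray:
        names = list(self.entries) if feature_order is None else list(feature_order)
        return np.array([self.entries[n] for n in names], dtype=float)


@dataclass(frozen=True)
class FitResult:
    model: object
    spec: ClassifierSpec
    params: ParamVector
    seed: int


def _build_estimator(spec: ClassifierSpec, seed: int):
    hp = dict(spec.hyperparameters)
    alg = spec.algorithm
    if alg == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if alg == "SVM":
        hp.setdefault("kernel", "linear")
        hp.setdefault("C", 1.0)
        return SVC(random_state=seed, **hp)
    if alg == "RF":
        hp.setdefault("n_estimators", 16)
        hp.setdefault("criterion", "gini")
        return RandomForestClassifier(random_state=seed, **hp)
    if alg == "PLSDA":
        return PLSDAClassifier(**hp)
    if alg == "LOG":
        hp.setdefault("solver", "saga")  # L2 penalty is the default
        hp.setdefault("max_iter", 5000)
        return LogisticRegression(random_state=seed, **hp)
    if alg == "MLP":
        hp.setdefault("hidden_layer_sizes", (32, 16))
        hp.setdefault("activation", "relu")
        hp.setdefault("solver", "adam")
        hp.setdefault("max_iter", 1000)
        return MLPClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {alg!r}")


def fit_classifier(spec: ClassifierSpec, X_train, y_train, seed: int = 0) -> FitResult:
    """Fit the spec'd algorithm on (already standardized) training data.

    ``X_train`` columns must follow ``spec.feature_subset`` order when a
    subset is given.  Fitting is deterministic for a fixed seed.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    if spec.feature_subset and X_train.shape[1] != len(spec.feature_subset):
        raise ValueError(
            f"X_train has {X_train.shape[1]} columns but the spec names "
            f"{len(spec.feature_subset)} features"
        )
    model = _build_estimator(spec, seed)
    model.fit(X_train, y_train)
    result = FitResult(model=model, spec=spec, params=None, seed=seed)
    return replace(result, params=extract_params(result))


def predict(fit: FitResult, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    return np.asarray(fit.model.predict(X), dtype=int)


def extract_params(fit: FitResult) -> ParamVector:
    """Feature-aligned parameters of a fitted model.

    Linear models yield one signed coefficient per feature; the random
    forest yields normalized mean-decrease-in-Gini importances; the MLP has
    no interpretable per-feature weights and yields kind ``"none"``.
    """
    model = fit.model
    names = fit.spec.feature_subset or tuple(
        f"x{i}" for i in range(getattr(model, "n_features_in_", 0))
    )
    if fit.spec.algorithm in ("LDA", "SVM", "LOG"):
        coef = np.asarray(model.coef_).reshape(-1)
        return ParamVector(kind="coefficient", entries=dict(zip(names, coef)))
    if fit.spec.algorithm == "PLSDA":
        return ParamVector(kind="coefficient", entries=dict(zip(names, model.coef_)))
    if fit.spec.algorithm == "RF":
        imp = np.asarray(model.feature_importances_, dtype=float)
        if imp.sum() > 0:
            imp = imp / imp.sum()
        else:  # degenerate forest with no splits: uniform attribution
            imp = np.full(imp.size, 1.0 / imp.size)
        return ParamVector(kind="importance", entries=dict(zip(names, imp)))
    return ParamVector(kind="none", entries={})


def loocv_accuracy(spec: ClassifierSpec, X, y, seed: int = 0) -> float:
    """Leave-one-out cross-validation accuracy: N fits, one held-out each."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    template = _build_estimator(spec, seed)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            continue  # fold lost a class; held-out sample counted as wrong
        model = clone(template)
        model.fit(X[mask], y[mask])
        correct += int(model.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def _subset_matrix(table: OmicsTable, subset):
    return table.select_features(subset)


def wrapper_select_features(
    table: OmicsTable,
    algorithm: str,
    k: int,
    split,
    seed: int = 0,
    max_combinations: int = 200_000,
    hyperparameters: dict | None = None,
) -> ClassifierSpec:
    """Exhaustive wrapper selection of the best k-feature subset.

    Every size-k combination of the table's features is scored by the LOOCV
    accuracy of a model trained on the (standardized) training partition of
    the fixed split; the best subset wins, ties broken by lexicographic
    feature order.
    """
    names = list(table.feature_names)
    if k > len(names):
        raise ValueError("subset size exceeds the feature count")
    from math import comb

    if comb(len(names), k) > max_combinations:
        raise ValueError(
            f"C({len(names)}, {k}) exceeds the {max_combinations}-combination cap; "
            "use prevalence ranking or a smaller k"
        )
    train = table.select_samples(split.train_indices)
    best_subset, best_acc = None, -1.0
    # enumerate name-sorted so ties break lexicographically, independent of
    # the table's column order
    for subset in combinations(sorted(names), k):
        sub = _subset_matrix(train, subset)
        z, _ = standardize(sub)
        spec = ClassifierSpec(
            algorithm=algorithm, feature_subset=subset,
            hyperparameters=hyperparameters or {},
        )
        acc = loocv_accuracy(spec, z.values, z.labels, seed=seed)
        if acc > best_acc:
            best_subset, best_acc = subset, acc
    ordered = tuple(n for n in names if n in best_subset)
    return ClassifierSpec(
        algorithm=algorithm, feature_subset=ordered,
        hyperparameters=hyperparameters or {},
    )


def prevalence_rank_features(
    table: OmicsTable,
    algorithm: str,
    k: int,
    n_splits: int = 1000,
    seed: int = 0,
    ratio: float = 0.7,
    max_combinations: int = 200_000,
    hyperparameters: dict | None = None,
):
    """Validate subset selection by prevalence across many random splits.

    For each of ``n_splits`` seeded 70/30 splits, every k-subset is scored by
    test-partition accuracy and the winner recorded; ``prevalence(f)`` is the
    fraction of winning subsets containing feature f.  The recommended spec
    is the most frequent winning subset whose members all sit in the top
    third of the prevalence ranking, falling back to the overall most
    frequent winner when none qualifies.  Returns ``(prevalence dict,
    recommended ClassifierSpec)``.
    """
    if n_splits < 2:
        raise ValueError("need at least 2 splits")
    names = list(table.feature_names)
    from math import comb

    if comb(len(names), k) > max_combinations:
        raise ValueError("combination cap exceeded; use a smaller k")
    subsets = list(combinations(names, k))
    win_counts: dict[tuple, int] = {}
    feature_counts = dict.fromkeys(names, 0)
    for i in range(n_splits):
        split = make_split(table, ratio=ratio, seed=seed + i, stratified=True)
        train = table.select_samples(split.train_indices)
        test = table.select_samples(split.test_indices)
        best_subset, best_acc = None, -1.0
        for subset in subsets:
            tr = _subset_matrix(train, subset)
            te = _subset_matrix(test, subset)
            z_tr, params = standardize(tr)
            z_te, _ = standardize(te, params)
            spec = ClassifierSpec(
                algorithm=algorithm, feature_subset=subset,
                hyperparameters=hyperparameters or {},
            )
            fit = fit_classifier(spec, z_tr.values, z_tr.labels, seed=seed + i)
            acc = float(np.mean(predict(fit, z_te.values) == z_te.labels))
            if acc > best_acc:
                best_subset, best_acc = subset, acc
        win_counts[best_subset] = win_counts.get(best_subset, 0) + 1
        for f in best_subset:
            feature_counts[f] += 1
    prevalence = {f: c / n_splits for f, c in feature_counts.items()}

    ranked = sorted(names, key=lambda f: -prevalence[f])
    top_third = set(ranked[: max(1, len(names) // 3)])
    candidates = sorted(win_counts.items(), key=lambda kv: -kv[1])
    recommended = candidates[0][0]
    for subset, _ in candidates:
        if set(subset) <= top_third:
            recommended = subset
            break
    spec = ClassifierSpec(
        algorithm=algorithm, feature_subset=recommended,
        hyperparameters=hyperparameters or {},
    )
    return prevalence, spec


def grid_search_hyperparams(
    table: OmicsTable,
    algorithm: str,
    grid: dict,
    split,
    seed: int = 0,
    feature_subset=None,
) -> dict:
    """Exhaustive grid search scored by LOOCV accuracy on the training partition.

    ``grid`` maps hyperparameter names to candidate value lists; the first
    combination (in grid order) achieving the best LOOCV accuracy wins.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    from itertools import product

    names = list(grid)
    train = table.select_samples(split.train_indices)
    if feature_subset is not None:
        train = train.select_features(feature_subset)
    z, _ = standardize(train)
    best_combo, best_acc = None, -1.0
    for values in product(*(grid[n] for n in names)):
        combo = dict(zip(names, values))
        spec = ClassifierSpec(
            algorithm=algorithm,
            feature_subset=train.feature_names,
            hyperparameters=combo,
        )
        acc = loocv_accuracy(spec, z.values, z.labels, seed=seed)
        if acc > best_acc:
            best_combo, best_acc = combo, acc
    return best_combo
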