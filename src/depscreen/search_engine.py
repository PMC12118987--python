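"""Exhaustive wrapper feature-subset × hyperparameter search.

Model choice is treated as a search problem: every size-k subset of a
feature pool is crossed with every hyperparameter setting of each estimator
family, each candidate is trained on the fixed training split and scored on
the held-out test split, and the best model is picked afterwards under an
F1-constrained accuracy criterion (see :mod:`depscreen.metrics_report`).

Default experiment geometry, with a 17-feature pool:

* random forest — k = 5, parameters fixed: C(17, 5) = 6,188 candidates;
* gradient-boosted trees (XGBoost) — k = 4, n_estimators ∈ {100, 300, 500}:
  C(17, 4) × 3 = 2,380 × 3 = 7,140 candidates;
* SVM — k = 4, gamma ∈ {1, 0.1, 0.01, 0.001} × C ∈ {1, 10, 100, 1000} ×
  kernel ∈ {rbf, linear}: 2,380 × 32 = 76,160 candidates.

Estimator adapters wrap scikit-learn / xgboost classifiers behind a plain
fit/predict contract and receive the spec's seed as their randomness
control, so a search is fully deterministic given its configuration.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .corpus_io import SplitResult
from .metrics_report import ConfusionMatrix, MetricsTable, confusion, summarize

__all__ = [
    "FeaturePool",
    "EstimatorSpec",
    "ModelResult",
    "DEFAULT_POOL",
    "rf_spec",
    "xgb_spec",
    "svm_spec",
    "enumerate_feature_subsets",
    "build_param_grid",
    "search_space_size",
    "make_estimator",
    "run_search",
    "constant_class_baseline",
]

logger = logging.getLogger(__name__)

LABEL_COLUMN = "PHQ8_Binary"

#: Default 17-feature experimental pool: the nine pool questions attested in
#: published top-feature tables plus eight of the eleven global features.
DEFAULT_POOL_NAMES: tuple[str, ...] = (
    "what's your dream job",
    "do you consider yourself an introvert",
    "how are you at controlling your temper",
    "when was the last time you argued with someone and what was it about",
    "what do you do to relax",
    "how close are you to your family",
    "is there anything you regret",
    "what's one of your most memorable experiences",
    "when was the last time you felt really happy",
    "avg_sentiment",
    "avg_response_time",
    "speech_speed",
    "avg_characters",
    "avg_nouns",
    "avg_verbs",
    "adj_freq",
    "fp_avg",
)


@dataclass(frozen=True)
class FeaturePool:
    """Ordered feature names over which subsets are enumerated."""

    names: tuple[str, ...] = DEFAULT_POOL_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature pool contains duplicate names")

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_POOL = FeaturePool()


@dataclass(frozen=True)
class EstimatorSpec:
    """One estimator family with its fixed parameters and search grid."""

    family: str  # random_forest | gradient_boosted_trees | svm
    fixed_params: dict[str, Any] = field(default_factory=dict)
    grid_params: dict[str, tuple] = field(default_factory=dict)
    subset_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown estimator family {self.family!r}")
        for name, values in self.grid_params.items():
            if not values:
                raise ValueError(f"grid for {name!r} is empty")


def rf_spec(seed: int = 0, subset_size: int = 5,
            max_depth: int = 12) -> EstimatorSpec:
    """Random forest: parameters fixed (non-default max depth), k = 5."""
    return EstimatorSpec("random_forest", {"max_depth": max_depth}, {},
                         subset_size, seed)


def xgb_spec(seed: int = 0, subset_size: int = 4) -> EstimatorSpec:
    """Gradient-boosted trees: n_estimators grid over {100, 300, 500}."""
    return EstimatorSpec(
        "gradient_boosted_trees",
        {"eval_metric": "auc", "learning_rate": 0.01, "max_depth": 12},
        {"n_estimators": (100, 300, 500)},
        subset_size, seed)


def svm_spec(seed: int = 0, subset_size: int = 4) -> EstimatorSpec:
    """SVM: gamma × C × kernel grid (4 × 4 × 2 = 32 settings)."""
    return EstimatorSpec(
        "svm", {},
        {"gamma": (1, 0.1, 0.01, 0.001),
         "C": (1, 10, 100, 1000),
         "kernel": ("rbf", "linear")},
        subset_size, seed)


@dataclass
class ModelResult:
    family: str
    params: dict[str, Any]
    feature_subset: tuple[str, ...]
    confusion: ConfusionMatrix | None
    metrics: MetricsTable | None
    n_train: int
    n_test: int
    error: str | None = None


def enumerate_feature_subsets(pool: FeaturePool,
                              k: int) -> list[tuple[str, ...]]:
    """All C(|pool|, k) unordered subsets, each in pool order, enumerated in
    lexicographic index order."""
    if not 1 <= k <= len(pool):
        raise ValueError(f"k must lie in [1, {len(pool)}], got {k}")
    return list(itertools.combinations(pool.names, k))


def build_param_grid(spec: EstimatorSpec) -> list[dict[str, Any]]:
    """Cartesian product of the grid axes merged over the fixed parameters.

    Deterministic order: axes sorted by name, values in declared order.  An
    empty grid yields the single fixed setting.
    """
    axes = sorted(spec.grid_params)
    settings = []
    for combo in itertools.product(*(spec.grid_params[a] for a in axes)):
        setting = dict(spec.fixed_params)
        setting.update(zip(axes, combo))
        settings.append(setting)
    return settings


def search_space_size(n_subsets: int, n_settings: int) -> int:
    """Number of candidate models: subsets × parameter settings."""
    return n_subsets * n_settings


_FAMILIES = ("random_forest", "gradient_boosted_trees", "svm")


def make_estimator(family: str, params: dict[str, Any], seed: int):
    """Instantiate the scikit-learn / xgboost adapter for one candidate."""
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "gradient_boosted_trees":
        return XGBClassifier(random_state=seed, **params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    raise ValueError(f"unknown estimator family {family!r}")


def run_search(
    features: pd.DataFrame,
    split: SplitResult,
    pool: FeaturePool,
    specs: Sequence[EstimatorSpec],
    label_column: str = LABEL_COLUMN,
) -> list[ModelResult]:
    """Train and evaluate every (family × subset × setting) candidate.

    Each candidate fits on the training rows restricted to its subset
    columns and is scored on the held-out test rows only.  A failing
    candidate is recorded with its error and the search continues.
    """
    missing = [c for c in pool.names if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix lacks pool column(s) {missing}")
    if label_column not in features.columns:
        raise ValueError(f"feature matrix lacks label column {label_column!r}")
    absent = [i for i in (*split.train_ids, *split.test_ids)
              if i not in features.index]
    if absent:
        raise ValueError(f"split ids missing from feature matrix: {absent[:5]}")

    train = features.loc[list(split.train_ids)]
    test = features.loc[list(split.test_ids)]
    y_train = train[label_column].to_numpy(dtype=int)
    y_test = test[label_column].to_numpy(dtype=int)

    results: list[ModelResult] = []
    for spec in specs:
        subsets = enumerate_feature_subsets(pool, spec.subset_size)
        settings = build_param_grid(spec)
        logger.info("%s: %d subsets × %d settings = %d candidates",
                    spec.family, len(subsets), len(settings),
                    search_space_size(len(subsets), len(settings)))
        for subset in subsets:
            X_train = train[list(subset)].to_numpy(dtype=float)
            X_test = test[list(subset)].to_numpy(dtype=float)
            for setting in settings:
                try:
                    est = make_estimator(spec.family, setting, spec.seed)
                    est.fit(X_train, y_train)
                    y_pred = np.asarray(est.predict(X_test), dtype=int)
                    cm = confusion(y_test, y_pred)
                    results.append(ModelResult(
                        spec.family, dict(setting), subset, cm,
                        summarize(cm), len(y_train), len(y_test)))
                except Exception as exc:
                    logger.warning("candidate %s %s %s failed: %s",
                                   spec.family, setting, subset, exc)
                    results.append(ModelResult(
                        spec.family, dict(setting), subset, None, None,
                        len(y_train), len(y_test), error=str(exc)))
    return results


def constant_class_baseline(test_labels: Sequence[int],
                            class_value: int) -> float:
    """Accuracy of predicting ``class_value`` for every test instance —
    i.e. that class's prevalence in the test labels."""
    labels = np.asarray(test_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty test labels")
    return float(np.mean(labels == class_value))


def n_choose_k(n: int, k: int) -> int:
    """Binomial coefficient convenience used when sizing search spaces."""
    return math.comb(n, k)
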