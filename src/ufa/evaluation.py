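"""Evaluation harness: cross-validation, repeated holdout, robustness sweeps.

The harness treats every classifier — flag-based or conventional — as a
fit/predict object over :class:`~ufa.dataset.Dataset` splits, and is
strict about leakage: thresholds are re-detected, boundaries re-fitted
and imputation means re-learned inside each training split only; the
test split is never touched by model fitting.

Flag-based models:

* ``nufa`` — threshold detection, flag counting, Fisher-LDA boundary on
  (n_high, n_low); ``nufa_exhaustive`` swaps in the exact 0-1-loss
  boundary.
* ``rf_ufa`` — threshold detection, binary flag matrix, random forest on
  the dummy features.

Conventional baselines (``logistic``, ``random_forest``, ``svm``,
``knn``, ``tree``) are thin adapters around scikit-learn estimators with
their default hyperparameters, run on mean-imputed continuous data —
they are reference points, not contributions.

Accuracy is reported in percent, AUROC on [0, 1]; intervals are
mean +/- 1.96 standard errors over folds or runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import synthetic
from .core import ThresholdSet, UfaConfig, detect_thresholds
from .dataset import Dataset, DataError
from .flagging import (
    LinearBoundary,
    apply_flags,
    classify_nufa,
    count_flags,
    fit_nufa,
    flag_feature_matrix,
)

__all__ = [
    "EvalResult",
    "NUfaClassifier",
    "RfUfaClassifier",
    "SklearnAdapter",
    "make_classifier",
    "CLASSIFIER_NAMES",
    "mean_impute",
    "cross_validate",
    "repeated_holdout",
    "robustness_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    """Summary of one classifier/metric over folds or runs."""

    classifier: str
    metric: str  # 'accuracy' (percent) or 'auroc'
    mean: float
    lower: float
    upper: float
    n_runs: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lower <= self.mean <= self.upper:
            raise ValueError("interval must contain the mean")


def mean_impute(dataset: Dataset, means: Optional[pd.Series] = None) -> Dataset:
    """Replace missing cells by column means.

    ``means`` supplies externally learned means (pass the training
    column means when imputing a test split — imputation must never see
    test data); when omitted, the dataset's own column means are used.
    A column with no observed values at all cannot be imputed and raises.
    """
    out = dataset.copy()
    if not out.variables:
        return out
    if means is None:
        means = out.X.mean(axis=0, skipna=True)
    missing_mean = means[means.isna()]
    if len(missing_mean):
        raise DataError(
            f"cannot impute all-missing column(s): {list(missing_mean.index)}"
        )
    out.X = out.X.fillna(means)
    return out


class NUfaClassifier:
    """Flag-count classifier with a linear boundary.

    Fitting detects thresholds on the training data, counts high/low
    flags per observation and fits the boundary. When training produces
    no significant threshold the model degrades to the training majority
    class (with a constant ranking score), which keeps harness runs on
    uninformative data well-defined.
    """

    name = "nufa"

    def __init__(self, config: Optional[UfaConfig] = None,
                 boundary_method: str = "lda") -> None:
        self.config = config or UfaConfig()
        self.boundary_method = boundary_method
        self.thresholds_: Optional[ThresholdSet] = None
        self.boundary_: Optional[LinearBoundary] = None
        self.majority_: int = 0

    def fit(self, train: Dataset) -> "NUfaClassifier":
        self.thresholds_ = detect_thresholds(train, self.config)
        self.majority_ = int(train.y.mean() >= 0.5)
        self.boundary_ = None
        if len(self.thresholds_) == 0:
            logger.warning("no significant thresholds; majority fallback")
            return self
        counts = count_flags(apply_flags(self.thresholds_, train), self.thresholds_)
        self.boundary_ = fit_nufa(counts, train.y.to_numpy(),
                                  method=self.boundary_method)
        return self

    def predict(self, test: Dataset) -> tuple[np.ndarray, np.ndarray]:
        """Return (labels, ranking scores) for a test split."""
        if self.thresholds_ is None:
            raise RuntimeError("fit before predict")
        if self.boundary_ is None:
            labels = np.full(test.n_obs, self.majority_, dtype=np.int8)
            return labels, np.zeros(test.n_obs)
        counts = count_flags(apply_flags(self.thresholds_, test), self.thresholds_)
        return classify_nufa(self.boundary_, counts)


class RfUfaClassifier:
    """Random forest on the binary flag matrix."""

    name = "rf_ufa"

    def __init__(self, config: Optional[UfaConfig] = None, seed: int = 0,
                 n_estimators: int = 100) -> None:
        self.config = config or UfaConfig()
        self.seed = seed
        self.n_estimators = n_estimators
        self.thresholds_: Optional[ThresholdSet] = None
        self.forest_: Optional[RandomForestClassifier] = None
        self.majority_: int = 0

    def fit(self, train: Dataset) -> "RfUfaClassifier":
        self.thresholds_ = detect_thresholds(train, self.config)
        self.majority_ = int(train.y.mean() >= 0.5)
        self.forest_ = None
        if len(self.thresholds_) == 0:
            logger.warning("no significant thresholds; majority fallback")
            return self
        feats = flag_feature_matrix(self.thresholds_, train)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        )
        self.forest_.fit(feats.to_numpy(), train.y.to_numpy())
        return self

    def predict(self, test: Dataset) -> tuple[np.ndarray, np.ndarray]:
        if self.thresholds_ is None:
            raise RuntimeError("fit before predict")
        if self.forest_ is None:
            labels = np.full(test.n_obs, self.majority_, dtype=np.int8)
            return labels, np.zeros(test.n_obs)
        feats = flag_feature_matrix(self.thresholds_, test).to_numpy()
        scores = self.forest_.predict_proba(feats)[:, 1]
        return self.forest_.predict(feats).astype(np.int8), scores


class SklearnAdapter:
    """Baseline estimator on mean-imputed continuous inputs.

    Imputation means are learned on the training split and re-used on
    the test split.
    """

    def __init__(self, name: str, estimator) -> None:
        self.name = name
        self.estimator = estimator
        self.means_: Optional[pd.Series] = None

    def fit(self, train: Dataset) -> "SklearnAdapter":
        self.means_ = train.X.mean(axis=0, skipna=True)
        imputed = mean_impute(train, self.means_)
        self.estimator.fit(imputed.X.to_numpy(), train.y.to_numpy())
        return self

    def predict(self, test: Dataset) -> tuple[np.ndarray, np.ndarray]:
        if self.means_ is None:
            raise RuntimeError("fit before predict")
        Xt = mean_impute(test, self.means_).X.to_numpy()
        labels = self.estimator.predict(Xt).astype(np.int8)
        if hasattr(self.estimator, "predict_proba"):
            scores = self.estimator.predict_proba(Xt)[:, 1]
        else:
            scores = self.estimator.decision_function(Xt)
        return labels, scores


CLASSIFIER_NAMES = (
    "nufa", "nufa_exhaustive", "rf_ufa",
    "logistic", "random_forest", "svm", "knn", "tree",
)


def make_classifier(name: str, seed: int = 0,
                    config: Optional[UfaConfig] = None):
    """Instantiate a classifier by registry name."""
    if name == "nufa":
        return NUfaClassifier(config=config)
    if name == "nufa_exhaustive":
        clf = NUfaClassifier(config=config, boundary_method="exhaustive")
        clf.name = "nufa_exhaustive"
        return clf
    if name == "rf_ufa":
        return RfUfaClassifier(config=config, seed=seed)
    if name == "logistic":
        return SklearnAdapter("logistic", LogisticRegression(max_iter=1000))
    if name == "random_forest":
        return SklearnAdapter(
            "random_forest", RandomForestClassifier(random_state=seed)
        )
    if name == "svm":
        return SklearnAdapter("svm", SVC(random_state=seed))
    if name == "knn":
        return SklearnAdapter("knn", KNeighborsClassifier())
    if name == "tree":
        return SklearnAdapter("tree", DecisionTreeClassifier(random_state=seed))
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def _summary(name: str, metric: str, values: Sequence[float], seed: int) -> EvalResult:
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return EvalResult(
        classifier=name, metric=metric, mean=mean,
        lower=mean - 1.96 * se, upper=mean + 1.96 * se,
        n_runs=len(vals), seed=seed,
    )


def _fold_metrics(clf, train: Dataset, test: Dataset) -> tuple[float, float]:
    clf.fit(train)
    labels, scores = clf.predict(test)
    acc = 100.0 * accuracy_score(test.y.to_numpy(), labels)
    yt = test.y.to_numpy()
    if len(np.unique(yt)) < 2 or np.ptp(scores) == 0:
        auroc = np.nan if len(np.unique(yt)) < 2 else 0.5
    else:
        auroc = float(roc_auc_score(yt, scores))
    return acc, auroc


def cross_validate(
    dataset: Dataset,
    classifier: str,
    k: int = 10,
    seed: int = 0,
    config: Optional[UfaConfig] = None,
    splits: Optional[Iterable[tuple[np.ndarray, np.ndarray]]] = None,
    return_models: bool = False,
):
    """Stratified k-fold evaluation with in-fold threshold detection.

    Everything that constitutes "fitting" — threshold detection, flag
    boundary, imputation means, estimator training — happens on the
    training folds only. Returns ``(accuracy, auroc)`` EvalResults;
    with ``return_models=True`` also the fitted per-fold classifiers,
    which exposes the detected thresholds and boundaries for audit.

    ``splits`` overrides the stratified splitter with explicit
    (train_indices, test_indices) pairs.
    """
    y = dataset.y.to_numpy()
    if splits is None:
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise DataError(
                f"cannot stratify {k} folds with class counts {counts.tolist()}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(len(y)), y))
    accs, aurocs, models = [], [], []
    name = classifier
    for train_idx, test_idx in splits:
        clf = make_classifier(classifier, seed=seed, config=config)
        name = clf.name
        acc, auroc = _fold_metrics(
            clf, dataset.subset(train_idx), dataset.subset(test_idx)
        )
        accs.append(acc)
        aurocs.append(auroc)
        models.append(clf)
    out = (_summary(name, "accuracy", accs, seed),
           _summary(name, "auroc", aurocs, seed))
    return (*out, models) if return_models else out


def repeated_holdout(
    dataset: Dataset,
    classifier: str,
    n_runs: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    config: Optional[UfaConfig] = None,
):
    """Average metrics over repeated stratified train/test splits."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    y = dataset.y.to_numpy()
    idx = np.arange(len(y))
    accs, aurocs = [], []
    name = classifier
    for _ in range(n_runs):
        split_seed = int(rng.integers(0, 2**31 - 1))
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, random_state=split_seed, stratify=y
        )
        clf = make_classifier(classifier, seed=split_seed, config=config)
        name = clf.name
        acc, auroc = _fold_metrics(
            clf, dataset.subset(train_idx), dataset.subset(test_idx)
        )
        accs.append(acc)
        aurocs.append(auroc)
    return (_summary(name, "accuracy", accs, seed),
            _summary(name, "auroc", aurocs, seed))


def robustness_sweep(
    dataset: Dataset,
    classifiers: Sequence[str],
    perturbation: str,
    fractions: Sequence[float],
    seed: int = 0,
    n_runs: int = 10,
    train_fraction: float = 0.8,
    config: Optional[UfaConfig] = None,
) -> pd.DataFrame:
    """Degradation grid under increasing missingness or noise.

    For each fraction the whole dataset is perturbed once (``missing``
    -> :func:`ufa.synthetic.inject_missing`, ``noise`` ->
    :func:`ufa.synthetic.inject_noise`) and every classifier is scored
    by repeated holdout on the perturbed table. The returned frame has
    one row per (classifier, fraction) with accuracy/AUROC means,
    interval bounds and the deltas from that classifier's 0% row.
    """
    ops = {"missing": synthetic.inject_missing, "noise": synthetic.inject_noise}
    if perturbation not in ops:
        raise ValueError("perturbation must be 'missing' or 'noise'")
    perturb = ops[perturbation]
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        pseed = int(rng.integers(0, 2**31 - 1))
        perturbed = perturb(dataset, frac, pseed)
        for name in classifiers:
            acc, auroc = repeated_holdout(
                perturbed, name, n_runs=n_runs,
                train_fraction=train_fraction, seed=seed, config=config,
            )
            rows.append({
                "classifier": acc.classifier, "fraction": frac,
                "accuracy": acc.mean, "accuracy_lower": acc.lower,
                "accuracy_upper": acc.upper,
                "auroc": auroc.mean, "auroc_lower": auroc.lower,
                "auroc_upper": auroc.upper, "n_runs": n_runs,
            })
    out = pd.DataFrame(rows)
    base = out[out["fraction"] == out["fraction"].min()].set_index("classifier")
    out["delta_accuracy"] = out.apply(
        lambda r: base.loc[r["classifier"], "accuracy"] - r["accuracy"], axis=1
    )
    out["delta_auroc"] = out.apply(
        lambda r: base.loc[r["classifier"], "auroc"] - r["auroc"], axis=1
    )
    return out
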