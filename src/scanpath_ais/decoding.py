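"""Observer-state decoding from per-trial predictability features.

The experimental condition is classified from a single scalar feature per
trial (AIS, normalized AIS, or gaze transition entropy) under ten
repetitions of a five-fold stratified cross-validation.  Two classifiers are
provided: a 1-nearest-neighbour rule with deterministic tie-breaking, and a
random-undersampling boosting ensemble (RUSBoost) of shallow decision trees,
which handles the class imbalance created when trials without a significant
past state drop out of the AIS feature set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureMatrix",
    "DecodingReport",
    "FeatureComparison",
    "build_features",
    "knn_classify",
    "rusboost_classify",
    "compare_feature_sets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-trial feature rows: values, condition labels, trial/image groups."""

    values: np.ndarray  # shape (n, d)
    labels: np.ndarray  # shape (n,)
    groups: np.ndarray  # shape (n,)
    feature: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.atleast_2d(np.asarray(self.values, dtype=float).T).T)
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "groups", np.asarray(self.groups))
        if self.values.shape[0] != self.labels.size:
            raise ValueError("values and labels must align")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix must not contain missing values")
        if np.unique(self.labels).size < 2:
            raise ValueError("need at least 2 classes")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def majority_baseline(self) -> float:
        _, counts = np.unique(self.labels, return_counts=True)
        return float(counts.max() / counts.sum())


def build_features(
    table: pd.DataFrame,
    feature: str = "ais",
    aggregate: str = "trial",
) -> FeatureMatrix:
    """One scalar feature row per trial (or per image, averaged).

    Trials whose estimate is missing — e.g. AIS on trials with no significant
    past state — are dropped with a logged count; this is what creates the
    class imbalance the boosting classifier is meant to absorb.
    ``aggregate="image"`` averages the feature over participants per
    (condition, trial) pair, treating the trial id as the image identity.
    """
    if feature not in {"ais", "ais_norm", "gte", "h_next"}:
        raise ValueError(f"unknown feature: {feature!r}")
    df = table[["participant", "condition", "trial", feature]].copy()
    n_missing = int(df[feature].isna().sum())
    if n_missing:
        logger.info("dropping %d trial(s) without a valid %s estimate", n_missing, feature)
    df = df.dropna(subset=[feature])
    if df.empty:
        raise ValueError("no rows with valid feature values")
    if aggregate == "image":
        df = (
            df.groupby(["condition", "trial"], as_index=False)[feature]
            .mean()
            .assign(participant="pooled")
        )
    elif aggregate != "trial":
        raise ValueError(f"unknown aggregation: {aggregate!r}")
    return FeatureMatrix(
        values=df[feature].to_numpy(),
        labels=df["condition"].to_numpy(),
        groups=df["trial"].to_numpy(),
        feature=feature,
    )


@dataclass(frozen=True)
class DecodingReport:
    """Cross-validated accuracies for one classifier/feature pairing."""

    mean_accuracy: float
    sd_accuracy: float
    per_fold: tuple[float, ...]
    majority_baseline: float
    classifier: str
    feature_set: str
    folds: int
    repetitions: int


def _knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, k: int
) -> np.ndarray:
    """k-NN on (possibly 1-D) features; distance ties -> lowest train index."""
    d = np.linalg.norm(test_x[:, None, :] - train_x[None, :, :], axis=2)
    # stable argsort keeps the lowest index first among equal distances
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    pred = np.empty(test_x.shape[0], dtype=train_y.dtype)
    for i, neigh in enumerate(order):
        labels, counts = np.unique(train_y[neigh], return_counts=True)
        winners = labels[counts == counts.max()]
        if winners.size == 1:
            pred[i] = winners[0]
        else:  # vote tie -> label of the single nearest neighbour
            pred[i] = train_y[neigh[0]]
    return pred


def _cv_report(
    features: FeatureMatrix,
    predict,
    classifier: str,
    folds: int,
    repetitions: int,
    seed,
) -> DecodingReport:
    rng = np.random.default_rng(seed)
    _, counts = np.unique(features.labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows; stratified {folds}-fold CV needs >= {folds}"
        )
    accs: list[float] = []
    for _ in range(repetitions):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train_idx, test_idx in skf.split(features.values, features.labels):
            pred = predict(
                features.values[train_idx],
                features.labels[train_idx],
                features.values[test_idx],
                rng,
            )
            accs.append(float(np.mean(pred == features.labels[test_idx])))
    arr = np.asarray(accs)
    return DecodingReport(
        mean_accuracy=float(arr.mean()),
        sd_accuracy=float(arr.std(ddof=1)),
        per_fold=tuple(arr.tolist()),
        majority_baseline=features.majority_baseline,
        classifier=classifier,
        feature_set=features.feature,
        folds=folds,
        repetitions=repetitions,
    )


def knn_classify(
    features: FeatureMatrix,
    k: int = 1,
    folds: int = 5,
    repetitions: int = 10,
    seed: int | np.random.Generator | None = None,
) -> DecodingReport:
    """Repeated stratified CV with a k-nearest-neighbour classifier (k=1)."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def predict(tx, ty, sx, _rng):
        return _knn_predict(tx, ty, sx, k)

    return _cv_report(features, predict, f"knn(k={k})", folds, repetitions, seed)


class _RUSBoost:
    """AdaBoost with per-round random undersampling of the majority class.

    Each round draws an undersample that equalizes class counts (sampling the
    majority class by the current boosting weights), fits a depth-limited
    decision tree, and reweights by the weighted error on the *full* training
    set.  Two-class only; final label by weighted vote.
    """

    def __init__(self, n_rounds: int = 50, max_depth: int = 2):
        self.n_rounds = n_rounds
        self.max_depth = max_depth

    def fit(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "_RUSBoost":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("RUSBoost here supports exactly 2 classes")
        counts = np.array([(y == c).sum() for c in classes])
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 rows")
        self.classes_ = classes
        sign = np.where(y == classes[1], 1.0, -1.0)
        w = np.full(y.size, 1.0 / y.size)
        self.models_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        n_min = int(counts.min())
        minority = classes[int(np.argmin(counts))]
        for _ in range(self.n_rounds):
            idx_parts = []
            for c in classes:
                members = np.nonzero(y == c)[0]
                if c == minority or members.size == n_min:
                    idx_parts.append(members)
                else:
                    p = w[members] / w[members].sum()
                    idx_parts.append(
                        rng.choice(members, size=n_min, replace=False, p=p)
                    )
            idx = np.concatenate(idx_parts)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=int(rng.integers(2**31))
            )
            tree.fit(x[idx], y[idx], sample_weight=w[idx] / w[idx].sum())
            pred_sign = np.where(tree.predict(x) == classes[1], 1.0, -1.0)
            err = float(w[pred_sign != sign].sum() / w.sum())
            if err >= 0.5:
                continue  # weaker than chance on the weighted set; skip round
            err = max(err, 1e-10)
            alpha = 0.5 * np.log((1.0 - err) / err)
            self.models_.append(tree)
            self.alphas_.append(alpha)
            w = w * np.exp(-alpha * sign * pred_sign)
            w = w / w.sum()
        if not self.models_:  # degenerate data: fall back to one plain tree
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=int(rng.integers(2**31))
            )
            tree.fit(x, y)
            self.models_ = [tree]
            self.alphas_ = [1.0]
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        score = np.zeros(x.shape[0])
        for tree, alpha in zip(self.models_, self.alphas_):
            score += alpha * np.where(tree.predict(x) == self.classes_[1], 1.0, -1.0)
        return np.where(score >= 0, self.classes_[1], self.classes_[0])


def rusboost_classify(
    features: FeatureMatrix,
    n_rounds: int = 50,
    max_depth: int = 2,
    folds: int = 5,
    repetitions: int = 10,
    seed: int | np.random.Generator | None = None,
) -> DecodingReport:
    """Repeated stratified CV with the RUSBoost ensemble."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")

    def predict(tx, ty, sx, rng):
        model = _RUSBoost(n_rounds=n_rounds, max_depth=max_depth).fit(tx, ty, rng)
        return model.predict(sx)

    return _cv_report(features, predict, "rusboost", folds, repetitions, seed)


@dataclass(frozen=True)
class FeatureComparison:
    """Wilcoxon signed-rank comparison of paired per-fold accuracies."""

    statistic: float
    p_value: float
    n_pairs: int
    n_nonzero: int


def compare_feature_sets(
    report_a: DecodingReport, report_b: DecodingReport
) -> FeatureComparison:
    """Signed-rank test on fold-wise accuracy differences (a vs. b).

    Folds are paired by position across the two reports, which requires both
    to come from the same CV protocol (and ideally the same seed so the fold
    assignments match).  Zero differences are dropped per the classic
    convention; if every pair is tied the test is undefined and p = 1 is
    returned with a warning.
    """
    a = np.asarray(report_a.per_fold)
    b = np.asarray(report_b.per_fold)
    if a.size != b.size:
        raise ValueError("reports must contain equal numbers of fold accuracies")
    diff = a - b
    n_nonzero = int((diff != 0).sum())
    if n_nonzero == 0:
        warnings.warn("all paired fold accuracies are tied; p-value set to 1")
        return FeatureComparison(0.0, 1.0, int(a.size), 0)
    res = stats.wilcoxon(a, b, zero_method="wilcox")
    return FeatureComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=int(a.size),
        n_nonzero=n_nonzero,
    )
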