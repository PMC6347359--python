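"""Train and apply a tree-ensemble classifier for SL pair inference.

Positives are known SL pairs; negatives are sampled uniformly among pairs
of fully annotated genes that take part in no known SL interaction, giving
a balanced instance set.  A random-forest classifier is tuned over a grid
of ensemble sizes by k-fold cross-validated accuracy (ties broken toward
the smallest ensemble), then evaluated on a held-out test split and used to
score candidate pairs; candidates at or above the score threshold become
``predicted`` SL pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core import (  # noqa: F401  (merge_sl_sets re-exported per module surface)
    GenePair,
    PREDICTED,
    SLInteractionSet,
    merge_sl_sets,
)
from .network_features import FEATURE_VERSION, PairFeatureVector

POSITIVE = "positive"
NEGATIVE = "negative"

#: Ensemble sizes searched during cross-validation.
DEFAULT_TREE_GRID: tuple[int, ...] = (25, 50, 93, 150, 300)

#: Sentinel for metrics whose defining ratio has a zero denominator.
NOT_APPLICABLE = None


@dataclass(frozen=True)
class LabeledInstance:
    pair: GenePair
    features: PairFeatureVector
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative: {self.label!r}")


@dataclass
class ClassifierMetrics:
    """Test-set metrics; a field is None when its ratio is undefined."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None
    auc: float | None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "f1", "specificity", "auc"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if None not in (self.precision, self.recall, self.f1):
            if self.precision + self.recall > 0:
                hm = 2 * self.precision * self.recall / (self.precision + self.recall)
                if abs(self.f1 - hm) > 1e-9:
                    raise ValueError(
                        f"f1={self.f1} inconsistent with harmonic mean {hm}"
                    )


@dataclass
class SLClassifier:
    """A fitted forest plus the metadata needed to apply it safely."""

    estimator: RandomForestClassifier
    n_trees: int
    seed: int
    tree_grid: tuple[int, ...]
    cv_accuracy: dict[int, float] = field(default_factory=dict)
    feature_version: str = FEATURE_VERSION

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability for each row of X."""
        proba = self.estimator.predict_proba(X)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


def _instance_matrix(
    instances: Sequence[LabeledInstance],
) -> tuple[np.ndarray, np.ndarray]:
    versions = {inst.features.feature_version for inst in instances}
    if len(versions) > 1:
        raise ValueError(f"mixed feature versions: {sorted(versions)}")
    X = np.vstack([inst.features.as_array() for inst in instances])
    y = np.array([1 if inst.label == POSITIVE else 0 for inst in instances])
    return X, y


def sample_negative_pairs(
    eligible: Iterable[str],
    known_sl: SLInteractionSet,
    n: int,
    seed: int,
) -> set[GenePair]:
    """Sample n distinct non-SL pairs between SL-free eligible genes.

    The candidate universe is every unordered pair of eligible genes that
    appear in **no** known SL pair; the draw is uniform without replacement
    and fully determined by ``seed``.

    Raises
    ------
    ValueError
        If n exceeds the candidate-universe size (the message reports the
        maximum available).
    """
    sl_genes = known_sl.gene_universe
    pool = sorted(g for g in set(eligible) if g not in sl_genes)
    m = len(pool)
    total = m * (m - 1) // 2
    if n > total:
        raise ValueError(
            f"requested {n} negative pairs but only {total} are available"
        )
    if n == 0:
        return set()
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    if n > total // 2:
        all_pairs = list(itertools.combinations(pool, 2))
        idx = rng.choice(total, size=n, replace=False)
        chosen = {all_pairs[i] for i in idx}
    else:
        while len(chosen) < n:
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            a, b = (pool[i], pool[j]) if i < j else (pool[j], pool[i])
            chosen.add((a, b))
    out = {GenePair(a, b, provenance=None) for a, b in chosen}
    assert not any(p in known_sl for p in out)
    return out


def split_train_test(
    instances: Sequence[LabeledInstance],
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[list[LabeledInstance], list[LabeledInstance]]:
    """Class-stratified, seeded split into train and test lists.

    Each class is shuffled independently and split at
    ``round(train_fraction * class_size)``, so a balanced input yields
    splits balanced within one instance per class.
    """
    by_label: dict[str, list[LabeledInstance]] = {POSITIVE: [], NEGATIVE: []}
    for inst in instances:
        by_label[inst.label].append(inst)
    for label, group in by_label.items():
        if len(group) < 2:
            raise ValueError(
                f"need at least 2 instances per class, got {len(group)} {label}"
            )
    rng = np.random.default_rng(seed)
    train: list[LabeledInstance] = []
    test: list[LabeledInstance] = []
    for label in (POSITIVE, NEGATIVE):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_train = round(train_fraction * len(group))
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


def train_classifier(
    train: Sequence[LabeledInstance],
    cv_folds: int = 10,
    tree_grid: Sequence[int] = DEFAULT_TREE_GRID,
    seed: int = 0,
) -> SLClassifier:
    """Fit a random forest, tuning ensemble size by cross-validated accuracy.

    Every size in ``tree_grid`` is scored with ``cv_folds``-fold stratified
    cross-validation on the training set; the size with the highest mean
    accuracy wins, ties going to the smallest ensemble.  Per-tree
    hyperparameters stay at scikit-learn defaults and are recorded in the
    fitted estimator.  All-constant feature columns are tolerated but
    reported as a warning.
    """
    X, y = _instance_matrix(train)
    constant = np.all(X == X[0, :], axis=0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} feature column(s) are constant on the "
            "training set",
            stacklevel=2,
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_accuracy: dict[int, float] = {}
    for n_trees in tree_grid:
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        cv_accuracy[n_trees] = float(
            cross_val_score(model, X, y, cv=cv, scoring="accuracy").mean()
        )
    best = min(
        tree_grid, key=lambda n: (-round(cv_accuracy[n], 12), n)
    )
    final = RandomForestClassifier(n_estimators=best, random_state=seed)
    final.fit(X, y)
    return SLClassifier(
        estimator=final,
        n_trees=best,
        seed=seed,
        tree_grid=tuple(tree_grid),
        cv_accuracy=cv_accuracy,
    )


def _auc_midrank(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """Rank-statistic AUC with ties sharing midranks (Mann-Whitney form)."""
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return NOT_APPLICABLE
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metrics_from_scores(
    y_true: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> ClassifierMetrics:
    """Confusion-matrix metrics + midrank AUC from positive-class scores."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else NOT_APPLICABLE
    recall = tp / (tp + fn) if (tp + fn) > 0 else NOT_APPLICABLE
    specificity = tn / (tn + fp) if (tn + fp) > 0 else NOT_APPLICABLE
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = NOT_APPLICABLE if (precision is None or recall is None) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassifierMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        auc=_auc_midrank(y, s),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def evaluate_classifier(
    model: SLClassifier, test: Sequence[LabeledInstance]
) -> ClassifierMetrics:
    """Score the model on a held-out test set (both classes required)."""
    if not test:
        raise ValueError("test set is empty")
    X, y = _instance_matrix(test)
    if len(set(y)) < 2:
        raise ValueError("test set must contain both classes")
    if model.feature_version != test[0].features.feature_version:
        raise ValueError(
            f"feature version mismatch: model {model.feature_version!r} vs "
            f"test {test[0].features.feature_version!r}"
        )
    return metrics_from_scores(y, model.scores(X))


def predict_candidates(
    model: SLClassifier,
    candidates: Sequence[tuple[GenePair, PairFeatureVector]],
    threshold: float = 0.5,
    known_sl: SLInteractionSet | None = None,
) -> set[GenePair]:
    """Candidate pairs scoring >= threshold, tagged ``predicted``.

    Pairs already present in ``known_sl`` are excluded from the output.
    Raises ValueError when candidate features were built under a different
    feature-order version than the model was trained on.
    """
    if not candidates:
        return set()
    versions = {fv.feature_version for _, fv in candidates}
    bad = versions - {model.feature_version}
    if bad:
        raise ValueError(
            f"feature version mismatch: model {model.feature_version!r} vs "
            f"candidates {sorted(bad)}"
        )
    X = np.vstack([fv.as_array() for _, fv in candidates])
    scores = model.scores(X)
    out: set[GenePair] = set()
    for (pair, _), score in zip(candidates, scores):
        if score < threshold:
            continue
        if known_sl is not None and pair in known_sl:
            continue
        out.add(
            GenePair(
                pair.gene_a,
                pair.gene_b,
                species=pair.species,
                provenance=PREDICTED,
            )
        )
    return out
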