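"""Pairwise SVM decoding of imagined movement directions with stratified
10-fold cross-validation.

Classification is binary throughout (every unordered pair of the four
directions, or a fixed pair across candidate electrode combinations).
Features are standardized with statistics computed on the training folds
only; the scaler travels with the SVM inside one sklearn pipeline, so no
test-fold information leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import extract_feature_table

__all__ = [
    "CVResult",
    "PairResult",
    "PairwiseTable",
    "DEFAULT_ELECTRODE_PAIRS",
    "train_svm",
    "crossval_pair",
    "pairwise_task_table",
    "electrode_pair_screen",
]

TASKS = ("forward", "reverse", "left", "right")

DEFAULT_ELECTRODE_PAIRS = (
    ("P3", "P4"), ("O1", "O2"), ("F7", "F8"),
    ("C3", "C4"), ("F3", "F4"), ("Fc3", "Fc4"),
)


@dataclass
class CVResult:
    """Cross-validated accuracy for one binary problem (percent)."""

    task_pair: tuple[str, str]
    fold_accuracies: np.ndarray
    n_trials: int
    seed: int
    subject: int | None = None

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if np.any((self.fold_accuracies < 0) | (self.fold_accuracies > 100)):
            raise ValueError("fold accuracies must lie in [0, 100]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))


@dataclass
class PairResult:
    """Across-subject summary for one pair: per-subject CV results plus the
    mean and sd of the per-subject mean accuracies."""

    pair: tuple[str, str]
    per_subject: list[CVResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.mean_accuracy for r in self.per_subject]))

    @property
    def sd_accuracy(self) -> float:
        means = [r.mean_accuracy for r in self.per_subject]
        return float(np.std(means, ddof=1)) if len(means) > 1 else 0.0


@dataclass
class PairwiseTable:
    """One row per pair; the grand mean is the mean of the pair means and
    the grand sd the mean of the per-pair across-subject sds."""

    rows: list[PairResult] = field(default_factory=list)

    @property
    def grand_mean(self) -> float:
        return float(np.mean([r.mean_accuracy for r in self.rows]))

    @property
    def grand_sd(self) -> float:
        return float(np.mean([r.sd_accuracy for r in self.rows]))

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "pair": f"{r.pair[0]} vs {r.pair[1]}",
                "mean_accuracy": round(r.mean_accuracy, 4),
                "sd_accuracy": round(r.sd_accuracy, 4),
            }
            for r in self.rows
        ]
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------


def _make_pipeline(C: float, gamma) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma)),
        ]
    )


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    gamma="scale",
) -> Pipeline:
    """Gaussian-kernel SVM on standardized features; the scaler is part of
    the returned model."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    return _make_pipeline(C, gamma).fit(X, y)


def crossval_pair(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    task_pair: tuple[str, str] | None = None,
    subject: int | None = None,
    grid: bool = False,
) -> CVResult:
    """Stratified k-fold CV accuracy (percent) for one binary problem.

    Folds are shuffled with ``seed``; the scaler is refit inside each
    training fold. With ``grid=True`` a 3x3 (C, gamma) grid search runs
    inside the training folds only.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected 2 classes, got {classes.size}")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} trials, fewer than k={k} "
            f"folds; use k <= {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    accs = []
    for train, test in cv.split(X, y):
        if grid:
            search = GridSearchCV(
                _make_pipeline(C, gamma),
                {
                    "svm__C": [0.1, 1.0, 10.0],
                    "svm__gamma": [0.01, 0.1, "scale"],
                },
                cv=3,
            )
            model = search.fit(X[train], y[train]).best_estimator_
        else:
            model = _make_pipeline(C, gamma).fit(X[train], y[train])
        accs.append(100.0 * model.score(X[test], y[test]))
    pair = task_pair if task_pair is not None else (str(classes[0]),
                                                   str(classes[1]))
    return CVResult(
        task_pair=pair,
        fold_accuracies=np.array(accs),
        n_trials=len(y),
        seed=int(seed),
        subject=subject,
    )


def _per_subject_cv(
    table: pd.DataFrame,
    feature_cols: list[str],
    pair: tuple[str, str],
    k: int,
    seed: int,
    C: float,
    gamma,
    grid: bool = False,
) -> PairResult:
    sub = table[table["task"].isin(pair)]
    results = []
    for subject, grp in sub.groupby("subject"):
        res = crossval_pair(
            grp[feature_cols].to_numpy(),
            grp["task"].to_numpy(),
            k=k,
            seed=seed,
            C=C,
            gamma=gamma,
            task_pair=pair,
            subject=int(subject),
            grid=grid,
        )
        results.append(res)
    return PairResult(pair=pair, per_subject=results)


def pairwise_task_table(
    features: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    grid: bool = False,
) -> PairwiseTable:
    """All six binary problems among the four directions.

    ``features`` is the tidy table from :func:`extract_feature_table`
    (columns subject, block, task, then the 12 coefficients). CV runs per
    subject; each pair is summarized across subjects.
    """
    present = set(features["task"].unique())
    missing = set(TASKS) - present
    if missing:
        raise ValueError(f"missing task labels: {sorted(missing)}")
    feature_cols = [c for c in features.columns
                    if c not in ("subject", "block", "task")]
    table = PairwiseTable()
    for pair in combinations(TASKS, 2):
        table.rows.append(
            _per_subject_cv(
                features, feature_cols, pair, k, seed, C, gamma, grid
            )
        )
    return table


def electrode_pair_screen(
    epochs,
    pairs=DEFAULT_ELECTRODE_PAIRS,
    task_pair: tuple[str, str] = ("forward", "reverse"),
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    **feature_kwargs,
) -> PairwiseTable:
    """Decode one task pair from each candidate electrode pair.

    Features are re-extracted per electrode pair (6 AR coefficients per
    channel, 12 per pair) from the supplied preprocessed epochs.
    """
    available = set(epochs[0].channel_labels) if epochs else set()
    for pair in pairs:
        unknown = set(pair) - available
        if unknown:
            raise ValueError(f"unknown channel label(s): {sorted(unknown)}")
    table = PairwiseTable()
    for elec in pairs:
        feats = extract_feature_table(
            [e for e in epochs if e.task in task_pair],
            channels=tuple(elec),
            **feature_kwargs,
        )
        feature_cols = [c for c in feats.columns
                        if c not in ("subject", "block", "task")]
        result = _per_subject_cv(
            feats, feature_cols, task_pair, k, seed, C, gamma
        )
        table.rows.append(PairResult(pair=tuple(elec),
                                     per_subject=result.per_subject))
    return table
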