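"""Classifier harness: half-split, 0-1 scaling, 5-fold CV grid search,
soft-margin SVM, and tie-aware ROC/AUC.

The evaluation design mirrors the probing-to-binding prediction workflow:
the labeled feature matrix is divided in half at random (stratified), both
halves are scaled to [0, 1] using column ranges learned on the training
half only, hyperparameters are chosen by stratified 5-fold cross-validation
on the training half with mean held-out AUC as the objective, and the
selected SVM is scored on the held-out half.  AUC is computed by the
Mann-Whitney rank statistic with half credit for ties, which is exactly the
area under the tie-aware ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_formats import ValidationError
from .sites import FeatureMatrix


def _default_c_grid() -> list[float]:
    return [2.0**e for e in range(-5, 16, 2)]


def _default_gamma_grid() -> list[float]:
    return [2.0**e for e in range(-15, 4, 2)]


@dataclass
class ModelConfig:
    kernel: str = "rbf"
    C_grid: list[float] = field(default_factory=_default_c_grid)
    gamma_grid: list[float] = field(default_factory=_default_gamma_grid)
    folds: int = 5
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValidationError("kernel must be 'rbf' or 'linear'")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split_fraction must be in (0, 1)")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValidationError("grid values must be positive")


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class ScalingRecord:
    """Per-column min/max learned on the training half."""

    col_min: np.ndarray
    col_max: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        out = np.zeros_like(X, dtype=float)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.col_min[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)


def split_half(
    X: np.ndarray, y: np.ndarray, seed: int, split_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified random split into train/test; disjoint and exhaustive.

    Within each class, round(n_class * split_fraction) rows go to train, so
    the class ratio is preserved to within one row.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValidationError(f"class {c} has fewer than 2 rows")
        perm = rng.permutation(idx)
        k = int(round(len(idx) * split_fraction))
        k = min(max(k, 1), len(idx) - 1)  # both halves keep the class
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return X[tr], y[tr], X[te], y[te]


def scale_features(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, ScalingRecord]:
    """Min-max scale both halves to [0, 1] using the training half's ranges.

    Test values outside the training range are clamped; constant training
    columns map to 0.
    """
    if np.isnan(X_train).any() or np.isnan(X_test).any():
        raise ValidationError("feature matrices must be null-free")
    rec = ScalingRecord(X_train.min(axis=0), X_train.max(axis=0))
    return rec.transform(X_train), rec.transform(X_test), rec


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Tie-aware ROC curve and AUC.

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, counting ties as 1/2; the curve walks thresholds from
    high to low with ties collapsed into single diagonal segments.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes required for ROC")
    ranks = rankdata(s)  # average ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    sorted_scores = s[order]
    sorted_y = y[order]
    # collapse runs of equal score into single curve vertices
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)) , len(s) - 1]
    tp = np.cumsum(sorted_y)[distinct]
    fp = np.cumsum(1 - sorted_y)[distinct]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return ROCResult(fpr, tpr, float(auc), n_pos, n_neg)


def select_hyperparameters(
    X: np.ndarray, y: np.ndarray, config: ModelConfig
) -> tuple[float, float]:
    """Exhaustive grid search maximising mean held-out AUC over stratified
    CV folds; ties broken by smallest C, then smallest gamma."""
    c_grid = sorted(set(config.C_grid))
    g_grid = sorted(set(config.gamma_grid)) if config.kernel == "rbf" else [1.0]
    if not c_grid or not g_grid:
        raise ValidationError("hyperparameter grid must be non-empty")
    if len(y) < config.folds:
        raise ValidationError("fewer rows than CV folds")
    if len(c_grid) == 1 and len(g_grid) == 1:
        return c_grid[0], g_grid[0]
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    best = None
    for C in c_grid:
        for gamma in g_grid:
            aucs = []
            for tr, va in folds:
                if len(np.unique(y[va])) < 2:
                    continue
                scores = train_and_score(
                    X[tr], y[tr], X[va], C=C, gamma=gamma, kernel=config.kernel
                )
                aucs.append(roc_auc(scores, y[va]).auc)
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            key = (-mean_auc, C, gamma)
            if best is None or key < best[0]:
                best = (key, (C, gamma))
    return best[1]


def train_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float,
    gamma: float = 1.0,
    kernel: str = "rbf",
) -> np.ndarray:
    """Fit a soft-margin SVM and return real-valued decision scores on the
    test rows (higher = more positive-like); deterministic given inputs."""
    clf = SVC(C=C, gamma=gamma, kernel=kernel)
    clf.fit(X_train, y_train)
    return clf.decision_function(X_test)


def evaluate_design(
    X: np.ndarray, y: np.ndarray, config: ModelConfig
) -> tuple[ROCResult, float, float]:
    """Full harness on one feature design: split, scale, CV-select, train,
    score, ROC.  Returns (roc, C*, gamma*)."""
    Xtr, ytr, Xte, yte = split_half(X, y, config.seed, config.split_fraction)
    Xtr, Xte, _ = scale_features(Xtr, Xte)
    C, gamma = select_hyperparameters(Xtr, ytr, config)
    scores = train_and_score(Xtr, ytr, Xte, C=C, gamma=gamma, kernel=config.kernel)
    return roc_auc(scores, yte), C, gamma


def compare_reagents(
    fm: FeatureMatrix, designs: Mapping[str, Sequence[str]], config: ModelConfig
) -> dict[str, dict]:
    """Run the harness once per feature design over a shared site set.

    ``designs`` maps a design name to the reagent columns it concatenates,
    e.g. ``{"flexibility": ["flexibility_probe"], "combined": [...]}``.  All
    designs share ``config.seed`` so they see the same half-split rows.
    """
    out = {}
    for name, reagents in designs.items():
        X = fm.design_matrix(list(reagents))
        roc, C, gamma = evaluate_design(X, fm.labels, config)
        out[name] = {
            "auc": roc.auc,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
            "C": C,
            "gamma": gamma,
            "roc": roc,
        }
    return out


def sensitivity_at_specificity(roc: ROCResult, specificity: float = 0.9) -> float:
    """Highest TPR achievable with FPR <= 1 - specificity on the step curve."""
    ok = roc.fpr <= (1.0 - specificity) + 1e-12
    return float(roc.tpr[ok].max()) if ok.any() else 0.0
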