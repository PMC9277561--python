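"""Responder prediction from pre-treatment band powers.

An RBF-kernel SVM is evaluated with stratified 5-fold cross-validation.
Within every training fold the (C, gamma) pair is chosen by an inner
stratified-CV grid search over logarithmic decades spanning 0.001-100, and
features are standardized with training-fold statistics only, so no
information from the held-out fold leaks into model selection.  Held-out
decision scores from all folds are pooled into one ROC curve; sensitivity
and specificity (responders positive) are taken at decision threshold 0 and
averaged into the balanced accuracy.

On top of the cross-validated SVM sit the channel-level procedures: a
single-channel screen, greedy forward channel selection maximizing the
pooled CV AUC, and a label-permutation test of a fixed channel subset's AUC
with the add-one p-value estimate p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import sklearn
from scipy import stats as _stats
from sklearn.svm import SVC

from .core import BandPowerTable, ConfigError, DataValidationError

logger = logging.getLogger("eegresp")

#: Logarithmic decades spanning the searched hyperparameter range.
DEFAULT_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2)


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the cross-validated RBF-SVM."""

    kernel: str = "rbf"
    c_grid: tuple[float, ...] = DEFAULT_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GRID
    n_folds: int = 5
    inner_folds: int = 3
    cv_seed: int = 0
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ConfigError("only the rbf kernel is supported")
        if self.n_folds < 2 or self.inner_folds < 2:
            raise ConfigError("n_folds and inner_folds must be >= 2")
        if not self.c_grid or not self.gamma_grid:
            raise ConfigError("hyperparameter grids must be non-empty")
        if any(v <= 0 for v in self.c_grid) or any(v <= 0 for v in self.gamma_grid):
            raise ConfigError("C and gamma values must be positive")


@dataclass
class CVResult:
    """Pooled cross-validation performance of one feature set."""

    auc: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    per_fold_params: list[tuple[float, float]]
    pooled_scores: np.ndarray  # one decision value per subject, input order


@dataclass
class ChannelSelectionTrace:
    """Greedy forward-selection path: channel added and CV result per step."""

    band: str
    steps: list[tuple[str, CVResult]] = field(default_factory=list)

    @property
    def channels_in_order(self) -> list[str]:
        return [ch for ch, _ in self.steps]

    @property
    def best_step(self) -> int:
        """Index of the earliest step attaining the maximal AUC."""
        aucs = [r.auc for _, r in self.steps]
        return int(np.argmax(aucs))  # argmax returns the first maximizer

    @property
    def best_subset(self) -> list[str]:
        return self.channels_in_order[: self.best_step + 1]

    @property
    def best_auc(self) -> float:
        return self.steps[self.best_step][1].auc

    @property
    def best_result(self) -> CVResult:
        return self.steps[self.best_step][1]

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "steps": [
                {
                    "channel_added": ch,
                    "n_channels": k + 1,
                    "auc": r.auc,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "balanced_accuracy": r.balanced_accuracy,
                }
                for k, (ch, r) in enumerate(self.steps)
            ],
            "best_subset": self.best_subset,
            "best_auc": self.best_auc,
        }


@dataclass
class PermutationResult:
    """Label-permutation null distribution of the cross-validated AUC."""

    observed_auc: float
    null_aucs: np.ndarray
    p_value: float


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return (sensitivity + specificity) / 2.0


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment: within each class, indices are
    shuffled and dealt round-robin, so class proportions are balanced across
    folds.  Returns test-index arrays, one per fold."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) identity, with tie handling."""
    y_true = np.asarray(y_true).astype(bool)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = _stats.rankdata(scores)
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def grid_search_params(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    spec: ClassifierSpec,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search scored by inner stratified-CV accuracy.

    Ties break deterministically toward the smallest C, then the smallest
    gamma, by scanning the grid in ascending order and only replacing the
    incumbent on a strict improvement.
    """
    X = np.asarray(train_features, float)
    y = np.asarray(train_labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DataValidationError("grid search needs both classes present")
    candidates = list(product(sorted(spec.c_grid), sorted(spec.gamma_grid)))
    if len(candidates) == 1:
        return candidates[0]
    n_inner = min(spec.inner_folds, int(counts.min()))
    if n_inner < 2:
        raise DataValidationError("too few samples per class for inner CV")
    all_idx = np.arange(y.size)
    splits = []
    for te in _stratified_folds(y, n_inner, spec.cv_seed):
        tr = np.setdiff1d(all_idx, te, assume_unique=True)
        if spec.scale_features:
            splits.append((tr, te, *_standardize(X[tr], X[te])))
        else:
            splits.append((tr, te, X[tr], X[te]))
    best = candidates[0]
    best_acc = -np.inf
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for C, gamma in candidates:
            correct = 0
            for tr, te, Xtr, Xte in splits:
                clf = SVC(kernel=spec.kernel, C=C, gamma=gamma)
                clf.fit(Xtr, y[tr])
                correct += int((clf.predict(Xte) == y[te]).sum())
            acc = correct / y.size
            if acc > best_acc:
                best_acc = acc
                best = (C, gamma)
    return best


def cross_validated_svm(
    features: np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
) -> CVResult:
    """Stratified k-fold RBF-SVM with nested hyperparameter selection.

    ``labels`` are booleans (True = responder, the positive class).  Returns
    pooled held-out decision scores (one per subject), the pooled-ROC AUC,
    and threshold-0 sensitivity/specificity.
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.size:
        raise DataValidationError("features and labels disagree on subject count")
    if np.any(~np.isfinite(X)):
        raise DataValidationError("features contain NaN or infinite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < spec.n_folds:
        raise DataValidationError(
            f"need >= {spec.n_folds} subjects per class for stratified "
            f"{spec.n_folds}-fold CV; class counts are {dict(zip(classes, counts))}"
        )

    # hyperparameters are chosen on the (already standardized) training fold only
    inner_spec = ClassifierSpec(
        kernel=spec.kernel,
        c_grid=spec.c_grid,
        gamma_grid=spec.gamma_grid,
        n_folds=spec.n_folds,
        inner_folds=spec.inner_folds,
        cv_seed=spec.cv_seed,
        scale_features=False,
    )
    all_idx = np.arange(y.size)
    scores = np.empty(y.size)
    per_fold_params: list[tuple[float, float]] = []
    for te in _stratified_folds(y, spec.n_folds, spec.cv_seed):
        tr = np.setdiff1d(all_idx, te, assume_unique=True)
        Xtr, Xte = (X[tr], X[te])
        if spec.scale_features:
            Xtr, Xte = _standardize(Xtr, Xte)
        C, gamma = grid_search_params(Xtr, y[tr], inner_spec)
        with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
            clf = SVC(kernel=spec.kernel, C=C, gamma=gamma)
            clf.fit(Xtr, y[tr])
            scores[te] = clf.decision_function(Xte)
        per_fold_params.append((C, gamma))

    auc = rank_auc(y, scores)
    pred = scores > 0
    sens = float(pred[y == 1].mean())
    specf = float((~pred[y == 0]).mean())
    return CVResult(
        auc=auc,
        sensitivity=sens,
        specificity=specf,
        balanced_accuracy=balanced_accuracy(sens, specf),
        per_fold_params=per_fold_params,
        pooled_scores=scores,
    )


# ------------------------------------------------------------ channel level


def _band_features(table: BandPowerTable, band: str) -> np.ndarray:
    return table.get_band(band)


def _align_labels(table: BandPowerTable, labels) -> np.ndarray:
    if isinstance(labels, Mapping):
        missing = [s for s in table.subjects if s not in labels]
        if missing:
            raise DataValidationError(f"labels missing for subjects {missing}")
        return np.array([labels[s] for s in table.subjects], dtype=bool)
    arr = np.asarray(labels, dtype=bool)
    if arr.size != len(table.subjects):
        raise DataValidationError("labels length does not match table subjects")
    return arr


def single_channel_screen(
    bandpower_pre: BandPowerTable,
    labels,
    band: str,
    spec: ClassifierSpec = ClassifierSpec(),
) -> dict[str, CVResult]:
    """Cross-validated SVM on each channel alone (d = 1), channel -> result."""
    X = _band_features(bandpower_pre, band)
    y = _align_labels(bandpower_pre, labels)
    return {
        ch: cross_validated_svm(X[:, [c]], y, spec)
        for c, ch in enumerate(bandpower_pre.channels)
    }


def forward_channel_selection(
    bandpower_pre: BandPowerTable,
    labels,
    band: str,
    spec: ClassifierSpec = ClassifierSpec(),
    max_steps: int | None = None,
) -> ChannelSelectionTrace:
    """Greedy forward selection maximizing pooled CV AUC.

    Step 1 keeps the best single channel; each later step tentatively adds
    every unused channel and commits the AUC maximizer (ties resolved toward
    the earliest channel in montage order).  ``max_steps`` truncates the
    search; by default it continues until every channel is included.
    """
    X = _band_features(bandpower_pre, band)
    y = _align_labels(bandpower_pre, labels)
    channels = bandpower_pre.channels
    if len(channels) < 2:
        raise DataValidationError("forward selection needs at least 2 channels")
    n_steps = len(channels) if max_steps is None else min(max_steps, len(channels))

    trace = ChannelSelectionTrace(band=band)
    selected: list[int] = []
    remaining = list(range(len(channels)))
    for _ in range(n_steps):
        best_c, best_res = None, None
        for c in remaining:  # montage order => earliest-channel tie-break
            res = cross_validated_svm(X[:, selected + [c]], y, spec)
            if best_res is None or res.auc > best_res.auc:
                best_c, best_res = c, res
        selected.append(best_c)
        remaining.remove(best_c)
        trace.steps.append((channels[best_c], best_res))
        logger.debug(
            "band %s step %d: +%s AUC=%.3f", band, len(selected), channels[best_c], best_res.auc
        )
    return trace


def permutation_test(
    bandpower_pre: BandPowerTable,
    labels,
    channel_subset: Sequence[str],
    band: str,
    spec: ClassifierSpec = ClassifierSpec(),
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of a fixed channel subset's CV AUC.

    Every permutation re-runs the complete cross-validation, inner grid
    search included, so the null distribution reflects the whole fitting
    procedure.  p = (1 + #{null >= observed}) / (n_perm + 1), so the
    smallest attainable p-value is 1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    channel_subset = list(channel_subset)
    if not channel_subset:
        raise ValueError("channel_subset must be non-empty")
    idx = [bandpower_pre.channels.index(ch) for ch in channel_subset]
    X = _band_features(bandpower_pre, band)[:, idx]
    y = _align_labels(bandpower_pre, labels)
    return permutation_test_features(X, y, spec=spec, n_perm=n_perm, seed=seed)


def permutation_test_features(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test on an explicit feature matrix (see permutation_test)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels).astype(bool)
    observed = cross_validated_svm(features, y, spec).auc
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null_aucs[i] = cross_validated_svm(features, y_perm, spec).auc
    p = (1 + int((null_aucs >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed_auc=observed, null_aucs=null_aucs, p_value=float(p))
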