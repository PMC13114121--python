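"""Cross-validation training, metrics, bootstrap inference and cohort transfer.

Evaluation mirrors the study protocol: stratified five-fold cross-validation
with a fixed seed (42) covering both the split and model initialization,
metrics (accuracy at 0.5, trapezoidal ROC AUC, step-wise average-precision
AUPR) averaged over folds, percentile bootstrap confidence intervals, a
paired-bootstrap test for AUC differences, an L1-logistic (LASSO) baseline on
the same folds, and a train-on-one / test-on-others cross-cohort harness in
which every test cohort is aligned to the training cohort's reference
feature space and standardized by the training cohort's scaler.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import nn
from .features import mi_scores, select_top_k
from .io import (
    AbundanceMatrix,
    LabelTable,
    PriorMatrix,
    Scaler,
    align_to_reference,
    apply_scaler,
    fit_scaler,
)
from .model import LossBreakdown, NetworkConfig, PriorFusionVAE
from .synthetic import Cohort

logger = logging.getLogger("priorvae")

__all__ = [
    "TrainSettings",
    "FoldAssignment",
    "FoldMetrics",
    "EvalResult",
    "make_folds",
    "train_model",
    "evaluate",
    "run_cv",
    "bootstrap_ci",
    "auc_difference_test",
    "lasso_baseline",
    "cross_cohort_eval",
]


@dataclass(frozen=True)
class TrainSettings:
    """Optimization hyperparameters (Adam, no early stopping, no schedule)."""

    epochs: int = 500
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 0 or self.learning_rate <= 0:
            raise ValueError("training settings must be positive")


@dataclass
class FoldAssignment:
    """Per-sample fold index of a stratified partition."""

    fold_index: np.ndarray
    seed: int
    n_folds: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = np.where(self.fold_index == fold)[0]
        train = np.where(self.fold_index != fold)[0]
        return train, val


@dataclass
class FoldMetrics:
    accuracy: float
    auc: float
    aupr: float
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class EvalResult:
    """Per-fold metrics with their means and standard deviations."""

    accuracy: list[float] = field(default_factory=list)
    auc: list[float] = field(default_factory=list)
    aupr: list[float] = field(default_factory=list)
    fold_scores: list[np.ndarray] = field(default_factory=list)
    fold_labels: list[np.ndarray] = field(default_factory=list)
    fold_val_indices: list[np.ndarray] = field(default_factory=list)
    fold_models: list = field(default_factory=list)
    fold_feature_ids: list[list[str]] = field(default_factory=list)
    fold_scalers: list[Scaler] = field(default_factory=list)

    def _agg(self, values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            return float("nan"), float("nan")
        return float(arr.mean()), float(arr.std())

    @property
    def mean_auc(self) -> float:
        return self._agg(self.auc)[0]

    @property
    def mean_accuracy(self) -> float:
        return self._agg(self.accuracy)[0]

    @property
    def mean_aupr(self) -> float:
        return self._agg(self.aupr)[0]

    def summary(self) -> dict[str, float]:
        out = {}
        for name, vals in (("accuracy", self.accuracy), ("auc", self.auc), ("aupr", self.aupr)):
            mean, sd = self._agg(vals)
            out[f"{name}_mean"] = mean
            out[f"{name}_sd"] = sd
        return out


def make_folds(y: LabelTable, n_folds: int = 5, seed: int = 42) -> FoldAssignment:
    """Stratified partition, deterministic given the seed."""
    labels = y.labels
    n = len(labels)
    if n < n_folds:
        raise ValueError(f"{n} samples cannot fill {n_folds} folds")
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if counts.min() < n_folds:
        warnings.warn(
            f"minority class has {counts.min()} members for {n_folds} folds; "
            "stratification is best-effort",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_index = np.empty(n, dtype=int)
    for k, (_, val) in enumerate(skf.split(np.zeros(n), labels)):
        fold_index[val] = k
    return FoldAssignment(fold_index, seed, n_folds)


def train_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    prior: PriorMatrix,
    net_cfg: NetworkConfig,
    settings: TrainSettings,
) -> tuple[PriorFusionVAE, list[LossBreakdown]]:
    """Train for exactly ``settings.epochs`` epochs; no early stopping.

    Returns the trained model and a per-epoch history of averaged loss
    breakdowns.  Tail batches of size 1 are dropped (batch normalization
    needs batch statistics) and logged.
    """
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    if X_train.shape[1] != net_cfg.input_dim:
        raise ValueError("X_train width does not match net_cfg.input_dim")
    model = PriorFusionVAE(net_cfg, prior)
    if net_cfg.reconstruction_target == "minmax":
        lo = X_train.min(axis=0)
        span = np.where(X_train.max(axis=0) > lo, X_train.max(axis=0) - lo, 1.0)
        target = (X_train - lo) / span
    else:
        target = X_train
    optimizer = nn.Adam(model.parameters(), lr=settings.learning_rate)
    rng = np.random.default_rng(settings.seed)
    history: list[LossBreakdown] = []
    n = X_train.shape[0]
    dropped_singletons = 0
    for _ in range(settings.epochs):
        order = rng.permutation(n)
        epoch_parts = np.zeros(4)
        n_batches = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            if len(idx) < 2:
                dropped_singletons += 1
                continue
            optimizer.zero_grad()
            loss, parts = model.batch_loss(X_train[idx], target[idx], y_train[idx], rng)
            if not np.isfinite(loss.data):
                bad = {k: v for k, v in parts.as_dict().items() if not np.isfinite(v)}
                raise FloatingPointError(f"non-finite loss terms: {bad or parts.as_dict()}")
            loss.backward()
            optimizer.step()
            epoch_parts += [parts.total, parts.reconstruction, parts.kl, parts.classification]
            n_batches += 1
        if n_batches:
            epoch_parts /= n_batches
        history.append(LossBreakdown(*epoch_parts))
    if dropped_singletons:
        logger.info("train_model: dropped %d singleton tail batches", dropped_singletons)
    model.eval_mode()
    return model, history


def _score_fn(metric: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if metric == "auc":
        return lambda y, s: roc_auc_score(y, s)
    if metric == "aupr":
        return lambda y, s: average_precision_score(y, s)
    if metric == "accuracy":
        return lambda y, s: float(np.mean((s >= 0.5).astype(int) == y))
    raise ValueError(f"unknown metric {metric!r}")


def evaluate(model: PriorFusionVAE, X_val: np.ndarray, y_val: np.ndarray) -> FoldMetrics:
    """Accuracy at threshold 0.5, trapezoidal AUC, step-wise AUPR."""
    y_val = np.asarray(y_val, int)
    scores = model.predict_proba(np.asarray(X_val, float))
    accuracy = float(np.mean((scores >= 0.5).astype(int) == y_val))
    if len(np.unique(y_val)) < 2:
        warnings.warn("single-class validation labels: AUC/AUPR undefined", stacklevel=2)
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(y_val, scores))
        aupr = float(average_precision_score(y_val, scores))
    return FoldMetrics(accuracy, auc, aupr, scores, y_val)


def run_cv(
    X: AbundanceMatrix,
    y: LabelTable,
    prior: PriorMatrix,
    net_cfg: NetworkConfig,
    settings: TrainSettings,
    select_k: Optional[int] = None,
    n_folds: int = 5,
    scaling_scope: str = "fold",
    select_scope: str = "fold",
    folds: Optional[FoldAssignment] = None,
) -> EvalResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Feature selection (if ``select_k``) and z-score standardization run on
    the training fold only by default; the ``global`` scopes fit them on the
    full matrix once before splitting.  Per-fold validation predictions,
    models, scalers and selected feature lists are retained so attribution
    can replay the exact fold pipelines.
    """
    labels = y.reindex(X.sample_ids)
    if folds is None:
        folds = make_folds(labels, n_folds=n_folds, seed=settings.seed)

    global_features: Optional[list[str]] = None
    if select_k is not None and select_scope == "global":
        global_features = select_top_k(mi_scores(X, labels, seed=settings.seed), select_k)
    global_scaler = fit_scaler(X) if scaling_scope == "global" else None

    result = EvalResult()
    for fold in range(folds.n_folds):
        train_idx, val_idx = folds.split(fold)
        Xtr = AbundanceMatrix(
            [X.sample_ids[i] for i in train_idx], list(X.feature_ids), X.values[train_idx]
        )
        ytr = LabelTable([X.sample_ids[i] for i in train_idx], labels.labels[train_idx])

        if select_k is not None:
            feats = (
                global_features
                if global_features is not None
                else select_top_k(mi_scores(Xtr, ytr, seed=settings.seed), select_k)
            )
            Xtr = align_to_reference(Xtr, feats)
            Xva_raw = align_to_reference(
                AbundanceMatrix(
                    [X.sample_ids[i] for i in val_idx], list(X.feature_ids), X.values[val_idx]
                ),
                feats,
            )
        else:
            feats = list(X.feature_ids)
            Xva_raw = AbundanceMatrix(
                [X.sample_ids[i] for i in val_idx], list(X.feature_ids), X.values[val_idx]
            )

        if global_scaler is not None and select_k is None:
            scaler = global_scaler
        else:
            scaler = fit_scaler(Xtr)
        Xtr_s = apply_scaler(scaler, Xtr)
        Xva_s = apply_scaler(scaler, Xva_raw)

        cfg = replace(net_cfg, input_dim=len(feats), seed=net_cfg.seed + fold)
        fold_settings = replace(settings, seed=settings.seed + 1000 * (fold + 1))
        model, _ = train_model(Xtr_s, ytr.labels, prior, cfg, fold_settings)
        metrics = evaluate(model, Xva_s, labels.labels[val_idx])

        result.accuracy.append(metrics.accuracy)
        result.auc.append(metrics.auc)
        result.aupr.append(metrics.aupr)
        result.fold_scores.append(metrics.scores)
        result.fold_labels.append(metrics.labels)
        result.fold_val_indices.append(val_idx)
        result.fold_models.append(model)
        result.fold_feature_ids.append(list(feats))
        result.fold_scalers.append(scaler)
    return result


def _auc_by_ranks(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC via midranks (Mann-Whitney), identical to trapezoidal
    ROC integration with tie handling; vectorized over replicate rows."""
    from scipy.stats import rankdata

    ranks = rankdata(scores, axis=1, method="average")
    npos = labels.sum(axis=1)
    nneg = labels.shape[1] - npos
    pos_rank_sum = (ranks * labels).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (pos_rank_sum - npos * (npos + 1) / 2) / (npos * nneg)


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    metric: str = "auc",
    n_rep: int = 1000,
    seed: int = 42,
) -> tuple[float, float]:
    """Percentile (2.5, 97.5) interval under sample-level resampling.

    Replicates that resample a single class (where the metric is undefined)
    are skipped and logged.  For the AUC the replicates are computed with
    the midrank (Mann-Whitney) identity, which equals trapezoidal ROC
    integration exactly and vectorizes over replicates.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(scores) < 10:
        raise ValueError("need at least 10 samples for a bootstrap interval")
    rng = np.random.default_rng(seed)
    n = len(scores)
    if metric == "auc":
        idx = rng.integers(0, n, (n_rep, n))
        aucs = _auc_by_ranks(scores[idx], labels[idx])
        valid = np.isfinite(aucs)
        if (~valid).any():
            logger.info("bootstrap_ci: skipped %d single-class replicates",
                        int((~valid).sum()))
        values = aucs[valid]
    else:
        fn = _score_fn(metric)
        values = []
        skipped = 0
        for _ in range(n_rep):
            idx = rng.integers(0, n, n)
            if metric == "aupr" and len(np.unique(labels[idx])) < 2:
                skipped += 1
                continue
            values.append(fn(labels[idx], scores[idx]))
        if skipped:
            logger.info("bootstrap_ci: skipped %d single-class replicates", skipped)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def auc_difference_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_rep: int = 2000,
    seed: int = 42,
) -> float:
    """Two-sided paired-bootstrap p-value for the AUC difference.

    Both score vectors must be over the same samples; each replicate
    resamples samples with replacement and recomputes both AUCs.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    y = np.asarray(labels, int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("score vectors and labels must share one sample set")
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_rep):
        idx = rng.integers(0, len(y), len(y))
        if len(np.unique(y[idx])) < 2:
            continue
        deltas.append(roc_auc_score(y[idx], a[idx]) - roc_auc_score(y[idx], b[idx]))
    deltas = np.asarray(deltas)
    p = 2.0 * min(np.mean(deltas <= 0), np.mean(deltas >= 0))
    return float(min(p, 1.0))


def lasso_baseline(
    X: AbundanceMatrix,
    y: LabelTable,
    folds: FoldAssignment,
) -> EvalResult:
    """L1-penalized logistic regression on the same folds and metrics.

    The penalty strength is chosen by inner cross-validation on each
    training fold; all-zero features are dropped (they carry no signal and
    destabilize the solver) with a warning.
    """
    labels = y.reindex(X.sample_ids)
    nonzero = ~np.all(X.values == 0, axis=0)
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero features", stacklevel=2)
    values = X.values[:, nonzero]
    result = EvalResult()
    for fold in range(folds.n_folds):
        train_idx, val_idx = folds.split(fold)
        scaler = fit_scaler(values[train_idx])
        Xtr = apply_scaler(scaler, values[train_idx])
        Xva = apply_scaler(scaler, values[val_idx])
        clf = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=10, cv=3,
            max_iter=2000, random_state=folds.seed, scoring="roc_auc",
        )
        clf.fit(Xtr, labels.labels[train_idx])
        scores = clf.predict_proba(Xva)[:, 1]
        y_val = labels.labels[val_idx]
        result.accuracy.append(float(np.mean((scores >= 0.5).astype(int) == y_val)))
        if len(np.unique(y_val)) < 2:
            result.auc.append(float("nan"))
            result.aupr.append(float("nan"))
        else:
            result.auc.append(float(roc_auc_score(y_val, scores)))
            result.aupr.append(float(average_precision_score(y_val, scores)))
        result.fold_scores.append(scores)
        result.fold_labels.append(y_val)
        result.fold_val_indices.append(val_idx)
        result.fold_models.append(clf)
    return result


def cross_cohort_eval(
    cohorts: Sequence[Cohort] | Sequence[tuple[AbundanceMatrix, LabelTable]],
    reference_feature_ids: Sequence[str],
    prior: PriorMatrix,
    net_cfg: NetworkConfig,
    settings: TrainSettings,
    select_k: Optional[int] = None,
) -> pd.DataFrame:
    """Train-on-one / test-on-others AUC matrix (rows = test, columns = train).

    One model per training cohort, trained on all its samples after alignment
    to the fixed reference feature space; every test cohort is aligned the
    same way and standardized with the *training* cohort's scaler (test
    statistics are never consulted).  Test cohorts with a single class yield
    NaN entries with a warning.
    """
    pairs = [(c[0], c[1]) for c in cohorts]
    names = [getattr(c, "abundance", c[0]).sample_ids[0].rsplit("_", 1)[0] for c in cohorts]
    auc = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for j, (Xtr_raw, ytr) in enumerate(pairs):
        Xtr = align_to_reference(Xtr_raw, reference_feature_ids)
        ytr = ytr.reindex(Xtr.sample_ids)
        feats = list(reference_feature_ids)
        if select_k is not None:
            feats = select_top_k(mi_scores(Xtr, ytr, seed=settings.seed), select_k)
            Xtr = align_to_reference(Xtr, feats)
        scaler = fit_scaler(Xtr)
        cfg = replace(net_cfg, input_dim=len(feats), seed=net_cfg.seed + j)
        model, _ = train_model(
            apply_scaler(scaler, Xtr), ytr.labels, prior, cfg,
            replace(settings, seed=settings.seed + 10_000 * (j + 1)),
        )
        for i, (Xte_raw, yte) in enumerate(pairs):
            Xte = align_to_reference(Xte_raw, feats)
            yte = yte.reindex(Xte.sample_ids)
            if len(np.unique(yte.labels)) < 2:
                warnings.warn(f"test cohort {names[i]} has one class; AUC undefined",
                              stacklevel=2)
                continue
            scores = model.predict_proba(apply_scaler(scaler, Xte))
            auc.iloc[i, j] = roc_auc_score(yte.labels, scores)
    return auc
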