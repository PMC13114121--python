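"""Integrated-gradients attribution and taxonomic aggregation.

Attribution follows the path-integral definition: for a sample x and
baseline x0 (default: the all-zero vector in standardized space, i.e. the
per-feature training mean on the raw scale),

    attr_j = (x_j - x0_j) * mean_{alpha in grid} dF/dx_j (x0 + alpha (x - x0))

where F is the predicted responder probability.  The midpoint grid makes the
completeness identity  sum_j attr_j = F(x) - F(x0)  hold to within 1% at 200
steps.  Per-feature scores are averaged over the correctly predicted
validation samples of every cross-validation fold, separately for samples
predicted as responders and non-responders, then ranked by absolute value or
accumulated per genus/family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .io import TaxAnnotationTable
from .model import PriorFusionVAE
from .nn import Tensor, sum_all
from .training import EvalResult

logger = logging.getLogger("priorvae")

__all__ = [
    "AttributionTable",
    "TaxonAggregate",
    "integrated_gradients",
    "attribute_cv",
    "top_k_by_attribution",
    "format_feature_label",
    "aggregate_by_taxon",
    "plot_attribution_bars",
]

DEFAULT_STEPS = 50


@dataclass
class AttributionTable:
    """Mean integrated-gradient score per feature, split by predicted class.

    A group with no correctly predicted sample carries NaN scores and a zero
    count.
    """

    feature_ids: list[str]
    responder_mean: np.ndarray
    nonresponder_mean: np.ndarray
    responder_n: int
    nonresponder_n: int

    def group_scores(self, group: str) -> np.ndarray:
        if group in ("responder", "response"):
            return self.responder_mean
        if group in ("nonresponder", "no-response"):
            return self.nonresponder_mean
        raise ValueError(f"unknown group {group!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "responder_mean_ig": self.responder_mean,
                "nonresponder_mean_ig": self.nonresponder_mean,
            }
        )


@dataclass
class TaxonAggregate:
    """Cumulative attribution of one taxon (sum of member feature means)."""

    taxon: str
    cumulative_score: float
    n_features: int


def _grad_wrt_input(model: PriorFusionVAE, x: np.ndarray) -> np.ndarray:
    """d(responder probability)/d(input) for each row of x, inference mode."""
    model.eval_mode()
    xt = Tensor(x, requires_grad=True)
    prob = model.classify(model.encode(xt))
    # rows are independent in inference mode, so summing gives per-row grads
    sum_all(prob).backward()
    g = xt.grad
    if g is None or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite input gradient")
    return g


def integrated_gradients(
    model: PriorFusionVAE,
    x: np.ndarray,
    baseline: Optional[np.ndarray] = None,
    steps: int = DEFAULT_STEPS,
) -> np.ndarray:
    """Per-feature attribution of one standardized sample.

    Midpoint Riemann approximation of the path integral from ``baseline``
    (default all zeros) to ``x``.
    """
    x = np.asarray(x, float).ravel()
    base = np.zeros_like(x) if baseline is None else np.asarray(baseline, float).ravel()
    if base.shape != x.shape:
        raise ValueError("baseline dimension does not match sample")
    alphas = (np.arange(steps) + 0.5) / steps
    points = base + alphas[:, None] * (x - base)
    grads = _grad_wrt_input(model, points)
    return (x - base) * grads.mean(axis=0)


def attribute_cv(
    result: EvalResult,
    X: "AbundanceMatrix",
    steps: int = DEFAULT_STEPS,
    baseline: Optional[np.ndarray] = None,
) -> AttributionTable:
    """Average attributions over correctly predicted validation samples.

    Replays each fold's exact pipeline (feature selection, scaler) on its
    validation samples.  Only samples whose thresholded prediction (0.5)
    matches the truth contribute; means are taken within the
    predicted-responder and predicted-non-responder groups, pooled across all
    folds.  Scores live in the full feature space of ``X``: a feature not
    selected in some fold contributes zero for that fold's samples.
    """
    from .io import AbundanceMatrix, align_to_reference, apply_scaler

    feature_ids = list(X.feature_ids)
    col = {f: j for j, f in enumerate(feature_ids)}
    sums = {g: np.zeros(len(feature_ids)) for g in ("pos", "neg")}
    counts = {"pos": 0, "neg": 0}
    for model, feats, scaler, val_idx, scores, labels in zip(
        result.fold_models,
        result.fold_feature_ids,
        result.fold_scalers,
        result.fold_val_indices,
        result.fold_scores,
        result.fold_labels,
    ):
        sub = AbundanceMatrix(
            [X.sample_ids[i] for i in val_idx], feature_ids, X.values[val_idx]
        )
        Xva = apply_scaler(scaler, align_to_reference(sub, feats))
        cols = np.array([col[f] for f in feats])
        preds = (scores >= 0.5).astype(int)
        for i in np.where(preds == labels)[0]:
            attr = integrated_gradients(model, Xva[i], baseline=baseline, steps=steps)
            group = "pos" if preds[i] == 1 else "neg"
            sums[group][cols] += attr
            counts[group] += 1
    nanvec = np.full(len(feature_ids), np.nan)
    if counts["pos"] == 0:
        logger.warning("attribute_cv: no correctly predicted responders")
    if counts["neg"] == 0:
        logger.warning("attribute_cv: no correctly predicted non-responders")
    return AttributionTable(
        feature_ids=list(feature_ids),
        responder_mean=sums["pos"] / counts["pos"] if counts["pos"] else nanvec,
        nonresponder_mean=sums["neg"] / counts["neg"] if counts["neg"] else nanvec,
        responder_n=counts["pos"],
        nonresponder_n=counts["neg"],
    )


def top_k_by_attribution(t: AttributionTable, group: str, k: int = 20) -> list[tuple[str, float]]:
    """The k features with largest |mean IG|, reported with signed values.

    Descending absolute score; exact ties broken by feature id ascending.
    """
    scores = t.group_scores(group)
    if np.all(np.isnan(scores)):
        raise ValueError(f"group {group!r} has no correctly predicted samples")
    order = sorted(
        range(len(t.feature_ids)),
        key=lambda j: (-abs(scores[j]), t.feature_ids[j]),
    )
    return [(t.feature_ids[j], float(scores[j])) for j in order[:k]]


def format_feature_label(feature_id: str, ann: TaxAnnotationTable) -> str:
    """"Family-x.xx > Genus-y.yy" display label; missing parts become "null"."""
    a = ann.get(feature_id)
    fam = f"{a.family}-{a.family_conf:.2f}" if a.family is not None and a.family_conf is not None else "null"
    gen = f"{a.genus}-{a.genus_conf:.2f}" if a.genus is not None and a.genus_conf is not None else "null"
    return f"{fam} > {gen}"


def aggregate_by_taxon(
    t: AttributionTable,
    ann: TaxAnnotationTable,
    level: Literal["genus", "family"],
    group: str,
) -> list[TaxonAggregate]:
    """Cumulative attribution per taxon, sorted descending.

    Unannotated features pool under the "null" taxon.  The sum over all
    aggregates equals the sum over all feature means (conservation).
    """
    if level not in ("genus", "family"):
        raise ValueError(f"level must be 'genus' or 'family', got {level!r}")
    scores = t.group_scores(group)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for fid, s in zip(t.feature_ids, scores):
        a = ann.get(fid)
        taxon = (a.genus if level == "genus" else a.family) or "null"
        sums[taxon] = sums.get(taxon, 0.0) + float(s)
        counts[taxon] = counts.get(taxon, 0) + 1
    aggregates = [TaxonAggregate(tx, sums[tx], counts[tx]) for tx in sums]
    aggregates.sort(key=lambda a: (-a.cumulative_score, a.taxon))
    return aggregates


def plot_attribution_bars(
    items: Sequence[tuple[str, float]], path: str, title: str = ""
) -> None:
    """Horizontal-bar export of ranked (label, score) attribution pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [lbl for lbl, _ in items][::-1]
    values = [v for _, v in items][::-1]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.35 * len(items))))
    ax.barh(labels, values, color=["tab:blue" if v >= 0 else "tab:red" for v in values])
    ax.set_xlabel("mean integrated-gradient score")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
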