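"""Typed containers and tabular I/O for abundance, prior, label and annotation data.

All on-disk formats are UTF-8 tab-separated text with a mandatory header row
and '.' as the decimal mark.  Sample order between abundance matrices, label
tables and prior matrices is reconciled by joining on sample identifiers,
never by positional order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("priorvae")

__all__ = [
    "AbundanceMatrix",
    "PriorMatrix",
    "LabelTable",
    "TaxAnnotation",
    "TaxAnnotationTable",
    "Scaler",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_prior_tsv",
    "write_prior_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "align_to_reference",
    "fit_scaler",
    "apply_scaler",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class AbundanceMatrix:
    """Samples x features table of non-negative abundance values (RPKM units).

    Rows are samples, columns are features (assembled contig identifiers).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {n} value rows"
            )
        if m != len(self.feature_ids):
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids but {m} value columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("abundance values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class PriorMatrix:
    """Fixed P x E matrix of protein-sequence embeddings.

    The embedding width E (default 320) is fixed for the lifetime of a model
    and the matrix itself is never updated during training.
    """

    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValidationError("prior matrix must be 2-D with P >= 1 rows")
        if self.values.shape[0] != len(self.protein_ids):
            raise ValidationError("protein id count does not match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("prior matrix contains non-finite entries")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def embedding_dim(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelTable:
    """Binary response labels per sample (1 = responder)."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValidationError("one label per sample required")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")

    def reindex(self, sample_ids: Sequence[str]) -> "LabelTable":
        """Labels reordered to ``sample_ids`` (join on id, not position)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"labels missing for samples: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return LabelTable(list(sample_ids), self.labels[idx])


@dataclass(frozen=True)
class TaxAnnotation:
    """GTDB-style family/genus assignment of one contig, with confidences."""

    family: Optional[str] = None
    family_conf: Optional[float] = None
    genus: Optional[str] = None
    genus_conf: Optional[float] = None

    def __post_init__(self) -> None:
        for c in (self.family_conf, self.genus_conf):
            if c is not None and not (0.0 <= c <= 1.0):
                raise ValidationError(f"confidence {c} outside [0, 1]")


@dataclass
class TaxAnnotationTable:
    """feature_id -> taxonomic annotation mapping."""

    annotations: dict[str, TaxAnnotation] = field(default_factory=dict)

    def get(self, feature_id: str) -> TaxAnnotation:
        return self.annotations.get(feature_id, TaxAnnotation())


@dataclass
class Scaler:
    """Per-feature z-score parameters fitted on exactly one matrix."""

    mean: np.ndarray
    std: np.ndarray
    ddof: int = 0

    @property
    def n_features(self) -> int:
        return len(self.mean)


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_tsv(path: str | Path) -> AbundanceMatrix:
    """Read a samples x features RPKM table.

    First header field is ignored (sample-id column name); remaining header
    fields are feature ids; the first column of each body row is the sample id.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        feature_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(feature_ids)))
    return AbundanceMatrix(sample_ids, feature_ids, values)


def write_abundance_tsv(m: AbundanceMatrix, path: str | Path) -> None:
    """Write an abundance matrix at full float precision (repr round-trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(m.feature_ids) + "\n")
        for sid, row in zip(m.sample_ids, m.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels_tsv(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "response"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns sample_id, response")
    return LabelTable(df["sample_id"].tolist(), df["response"].to_numpy())


def write_labels_tsv(t: LabelTable, path: str | Path) -> None:
    pd.DataFrame({"sample_id": t.sample_ids, "response": t.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_prior_tsv(path: str | Path) -> PriorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PriorMatrix(df.index.astype(str).tolist(), df.to_numpy(dtype=float))


def write_prior_tsv(p: PriorMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        p.values,
        index=pd.Index(p.protein_ids, name="protein_id"),
        columns=[f"e{j}" for j in range(p.embedding_dim)],
    )
    df.to_csv(path, sep="\t")


_NULL = "null"


def read_annotations_tsv(path: str | Path) -> TaxAnnotationTable:
    """Read feature annotations; the literal string "null" marks a missing field."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"feature_id", "family", "family_conf", "genus", "genus_conf"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(need)}")
    if df["feature_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate feature ids")
    table: dict[str, TaxAnnotation] = {}
    for rec in df.itertuples(index=False):
        table[rec.feature_id] = TaxAnnotation(
            family=None if rec.family == _NULL else rec.family,
            family_conf=None if rec.family_conf == _NULL else float(rec.family_conf),
            genus=None if rec.genus == _NULL else rec.genus,
            genus_conf=None if rec.genus_conf == _NULL else float(rec.genus_conf),
        )
    return TaxAnnotationTable(table)


def write_annotations_tsv(t: TaxAnnotationTable, path: str | Path) -> None:
    rows = []
    for fid, a in t.annotations.items():
        rows.append(
            {
                "feature_id": fid,
                "family": a.family if a.family is not None else _NULL,
                "family_conf": repr(a.family_conf) if a.family_conf is not None else _NULL,
                "genus": a.genus if a.genus is not None else _NULL,
                "genus_conf": repr(a.genus_conf) if a.genus_conf is not None else _NULL,
            }
        )
    pd.DataFrame(rows, columns=["feature_id", "family", "family_conf", "genus", "genus_conf"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# feature alignment and standardization


def align_to_reference(
    m: AbundanceMatrix, reference_feature_ids: Sequence[str]
) -> AbundanceMatrix:
    """Project a cohort onto a fixed reference feature space.

    Output columns are exactly ``reference_feature_ids`` in that order.
    Reference features absent from ``m`` are zero-filled; features of ``m``
    absent from the reference are dropped.  Every cohort entering a model
    trained on a fixed reference must pass through this projection so feature
    dimensionality is identical across cohorts.
    """
    ref = list(reference_feature_ids)
    if len(set(ref)) != len(ref):
        raise ValidationError("reference feature ids are not unique")
    pos = {f: j for j, f in enumerate(m.feature_ids)}
    out = np.zeros((m.n_samples, len(ref)))
    filled = 0
    for j, f in enumerate(ref):
        if f in pos:
            out[:, j] = m.values[:, pos[f]]
        else:
            filled += 1
    dropped = len(m.feature_ids) - (len(ref) - filled)
    logger.info(
        "align_to_reference: %d reference features, %d zero-filled, %d dropped",
        len(ref), filled, dropped,
    )
    return AbundanceMatrix(list(m.sample_ids), ref, out)


def fit_scaler(
    m: AbundanceMatrix | np.ndarray, convention: Literal["population", "sample"] = "population"
) -> Scaler:
    """Fit per-feature z-score parameters.

    Population SD (divide by n) by default; ``convention="sample"`` switches
    to the n-1 denominator.
    """
    values = m.values if isinstance(m, AbundanceMatrix) else np.asarray(m, float)
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 samples to fit a scaler")
    ddof = 0 if convention == "population" else 1
    return Scaler(values.mean(axis=0), values.std(axis=0, ddof=ddof), ddof=ddof)


def apply_scaler(s: Scaler, m: AbundanceMatrix | np.ndarray) -> np.ndarray:
    """Standardize features; zero-variance features map to 0.

    Keeping constant features (as exact zeros) instead of dropping them
    preserves the feature count, so model input dimensions stay fixed across
    folds and cohorts.
    """
    values = m.values if isinstance(m, AbundanceMatrix) else np.asarray(m, float)
    if values.shape[1] != s.n_features:
        raise ValidationError(
            f"scaler fitted on {s.n_features} features, input has {values.shape[1]}"
        )
    std = np.where(s.std > 0, s.std, 1.0)
    out = (values - s.mean) / std
    out[:, s.std == 0] = 0.0
    return out
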