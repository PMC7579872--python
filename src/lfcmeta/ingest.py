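"""Reading expression cohorts and applying the dataset-selection filter.

A *study* is one case/control expression cohort: a gene-by-sample matrix of
log2 expression values plus a case/control label per sample and a metadata
record (accession, group sizes, country, study age).  This module reads the
on-disk layout (tab-separated matrix + two-column label file + metadata
table), applies the selection filter used to qualify cohorts for pooling
(series entry, RNA expression study, total n >= 10, Homo sapiens,
case/control design), detects linear-scale matrices and log2-transforms
them, and collapses duplicate gene rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: strict threshold above which a matrix is judged to be on linear scale
LOG2_DETECTION_MAX = 50.0


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class StudyMeta:
    """Metadata for one cohort, including the selection-filter attributes."""

    geo_id: str
    study_name: str
    n_control: int
    n_case: int
    country: str
    study_age: float
    entry_type: str = "series"
    study_type: str = "RNA expression"
    organism: str = "Homo sapiens"
    design: str = "case_control"

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_case < 0:
            raise DataError(f"{self.geo_id}: negative group size")
        if self.study_age < 0:
            raise DataError(f"{self.geo_id}: negative study age")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_case


@dataclass
class ExpressionDataset:
    """A gene x sample log2 expression matrix with case/control labels.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    sample; ``labels`` maps each sample (column) to ``"case"`` or
    ``"control"``; ``meta`` is the matching :class:`StudyMeta`.
    """

    values: pd.DataFrame
    labels: pd.Series
    meta: StudyMeta
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.meta.n_total:
            raise DataError(
                f"{self.meta.geo_id}: matrix has {self.values.shape[1]} sample "
                f"columns but metadata declares {self.meta.n_total}"
            )
        missing = set(self.values.columns) - set(self.labels.index)
        if missing:
            raise DataError(
                f"{self.meta.geo_id}: no label for sample(s) {sorted(missing)}"
            )
        self.labels = self.labels.loc[self.values.columns]
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise DataError(f"{self.meta.geo_id}: unknown labels {sorted(bad)}")
        counts = self.labels.value_counts()
        if (
            counts.get(CASE, 0) != self.meta.n_case
            or counts.get(CONTROL, 0) != self.meta.n_control
        ):
            raise DataError(
                f"{self.meta.geo_id}: label counts "
                f"({counts.get(CASE, 0)} case / {counts.get(CONTROL, 0)} control) "
                f"disagree with metadata ({self.meta.n_case}/{self.meta.n_control})"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def group(self, label: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying ``label`` (case or control)."""
        return self.values.loc[:, self.labels[self.labels == label].index]


# ---------------------------------------------------------------------------
# selection filter
# ---------------------------------------------------------------------------

#: filter criteria a cohort must satisfy to enter the pooled analysis
FILTER_CRITERIA = {
    "entry_type": "series",
    "study_type": "RNA expression",
    "organism": "Homo sapiens",
    "design": "case_control",
}
MIN_TOTAL_SAMPLES = 10


def filter_datasets(records: list[StudyMeta]) -> list[StudyMeta]:
    """Keep cohorts qualifying for the pooled analysis; order preserved.

    A record is retained when it is a series entry of an RNA expression
    study on Homo sapiens with a case/control design and a total sample
    size of at least 10.  Records failing (or missing) a criterion are
    dropped with a logged reason, never an exception.
    """
    kept = []
    for rec in records:
        reason = _rejection_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            logger.info("excluded dataset %s: %s", rec.geo_id, reason)
    return kept


def _rejection_reason(rec: StudyMeta) -> str | None:
    for attr, wanted in FILTER_CRITERIA.items():
        got = getattr(rec, attr, None)
        if got is None or got == "":
            return f"missing_{attr}"
        if got != wanted:
            return f"{attr}={got!r}"
    if rec.n_total < MIN_TOTAL_SAMPLES:
        return f"sample_size={rec.n_total}<{MIN_TOTAL_SAMPLES}"
    return None


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_expression_table(
    matrix_path: str | Path,
    labels_path: str | Path,
    meta: StudyMeta,
) -> ExpressionDataset:
    """Read one cohort from a TSV matrix and a two-column label file.

    The matrix file has a header row of sample identifiers and a first
    column of gene identifiers; the label file has two columns
    (sample id, ``case``/``control``), no header.  Gene rows containing any
    missing value are dropped and counted in the log.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.empty or values.shape[1] == 0:
        raise DataError(f"{matrix_path}: empty expression matrix")
    values.columns = values.columns.astype(str)
    values.index = values.index.astype(str)
    values.index.name = None

    lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "label"])
    labels = pd.Series(lab["label"].values, index=lab["sample"].astype(str))
    unlabelled = [c for c in values.columns if c not in labels.index]
    if unlabelled:
        raise DataError(
            f"{labels_path}: no label for sample(s) {unlabelled} of {matrix_path}"
        )

    n_missing = int(values.isna().any(axis=1).sum())
    if n_missing:
        logger.info(
            "%s: dropped %d gene row(s) with missing values", meta.geo_id, n_missing
        )
        values = values.dropna(axis=0)
    if not np.isfinite(values.to_numpy()).all():
        raise DataError(f"{matrix_path}: non-finite expression values")
    return ExpressionDataset(values=values, labels=labels, meta=meta)


METADATA_COLUMNS = [
    "geo_id", "study_name", "n_control", "n_case", "country", "study_age",
    "entry_type", "study_type", "organism", "design",
]


def read_metadata_table(path: str | Path) -> list[StudyMeta]:
    """Read a StudyMeta table (TSV, one row per cohort)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise DataError(f"{path}: metadata table lacks column(s) {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        kwargs = {k: row[k] for k in METADATA_COLUMNS if k in row}
        kwargs["n_control"] = int(kwargs["n_control"])
        kwargs["n_case"] = int(kwargs["n_case"])
        kwargs["study_age"] = float(kwargs["study_age"])
        records.append(StudyMeta(**kwargs))
    return records


def write_metadata_table(records: list[StudyMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in METADATA_COLUMNS} for r in records]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def ensure_log2(dataset: ExpressionDataset) -> ExpressionDataset:
    """Log2-transform a matrix judged to be on linear scale.

    A matrix whose maximum exceeds 50 is taken to hold linear-scale
    intensities (log2 microarray data tops out well below 20) and every
    entry is replaced by ``log2(x + 1)``; otherwise the dataset is returned
    unchanged.  The ``log2_transformed`` flag records the decision.
    """
    arr = dataset.values.to_numpy()
    if arr.max(initial=-np.inf) > LOG2_DETECTION_MAX:
        if (arr < 0).any():
            raise DataError(
                f"{dataset.meta.geo_id}: negative values in a matrix judged "
                "linear-scale; cannot log2-transform"
            )
        values = np.log2(dataset.values + 1.0)
        logger.info("%s: log2(x+1)-transformed linear-scale matrix", dataset.meta.geo_id)
        return ExpressionDataset(
            values=values, labels=dataset.labels, meta=dataset.meta,
            log2_transformed=True,
        )
    return dataset


def collapse_duplicate_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Keep, per duplicated gene identifier, the row of highest mean expression.

    Standard probe-to-gene collapsing for array data; ties keep the
    first-occurring row.
    """
    if dataset.values.index.is_unique:
        return dataset
    means = dataset.values.mean(axis=1).to_numpy()
    df = dataset.values.copy()
    df["_mean"] = means
    df["_pos"] = np.arange(len(df))
    # stable sort: highest mean first, original order breaks ties
    order = df.sort_values(["_mean", "_pos"], ascending=[False, True], kind="stable")
    collapsed = order[~order.index.duplicated(keep="first")]
    collapsed = collapsed.sort_values("_pos").drop(columns=["_mean", "_pos"])
    logger.info(
        "%s: collapsed %d duplicate gene row(s)",
        dataset.meta.geo_id, len(dataset.values) - len(collapsed),
    )
    return ExpressionDataset(
        values=collapsed, labels=dataset.labels, meta=dataset.meta,
        log2_transformed=dataset.log2_transformed,
    )
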