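"""Per-study, per-gene effect sizes.

The effect size is the log fold change (LFC): the difference of group means
of log2 expression, case minus control.  Its variance is the two-sample
(Welch-style) variance of a mean difference,
``s2_case/n_case + s2_control/n_control`` with unbiased sample variances —
the quantity inverse-variance pooling weights against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import CASE, CONTROL, DataError, ExpressionDataset

logger = logging.getLogger(__name__)

#: floor applied to a zero sample variance (degenerate constant groups)
VARIANCE_EPS = 1e-8

EFFECT_COLUMNS = ["gene_id", "study_id", "lfc", "variance", "n_case", "n_control"]


@dataclass(frozen=True)
class GeneEffect:
    """LFC of one gene in one study, with its variance and group sizes."""

    gene_id: str
    study_id: str
    lfc: float
    variance: float
    n_case: int
    n_control: int


def compute_gene_effect(
    dataset: ExpressionDataset, gene_id: str, variance_floor: float = VARIANCE_EPS
) -> GeneEffect | None:
    """LFC and variance for one gene; ``None`` when the gene is not measured.

    Both groups must be non-empty.  A zero variance (both groups constant)
    is floored at ``variance_floor`` with a logged warning so downstream
    inverse-variance weights stay finite.
    """
    if gene_id not in dataset.values.index:
        return None
    case = dataset.group(CASE).loc[gene_id].to_numpy(dtype=float)
    control = dataset.group(CONTROL).loc[gene_id].to_numpy(dtype=float)
    if case.size == 0 or control.size == 0:
        raise DataError(
            f"{dataset.meta.geo_id}: empty case or control group for {gene_id}"
        )
    lfc = float(case.mean() - control.mean())
    variance = _mean_difference_variance(case, control)
    if variance <= 0.0:
        logger.warning(
            "%s/%s: zero LFC variance floored at %g",
            dataset.meta.geo_id, gene_id, variance_floor,
        )
        variance = variance_floor
    return GeneEffect(
        gene_id=gene_id, study_id=dataset.meta.geo_id, lfc=lfc, variance=variance,
        n_case=case.size, n_control=control.size,
    )


def _mean_difference_variance(case: np.ndarray, control: np.ndarray) -> float:
    s2c = case.var(ddof=1) if case.size > 1 else 0.0
    s2n = control.var(ddof=1) if control.size > 1 else 0.0
    return float(s2c / case.size + s2n / control.size)


def effects_table(
    datasets: Sequence[ExpressionDataset],
    genes: Sequence[str] | None = None,
    variance_floor: float = VARIANCE_EPS,
) -> pd.DataFrame:
    """Tidy table of per-(gene, study) effects, vectorised over genes.

    One row per gene/study pair where the gene is measured; genes absent
    from a study are simply not represented (the pooling layer tolerates
    partial coverage).  Rows are ordered by gene, then by the input study
    order.  Columns: gene_id, study_id, lfc, variance, n_case, n_control.
    """
    if not datasets:
        raise DataError("effects_table requires at least one dataset")
    frames = []
    for ds in datasets:
        values = ds.values if genes is None else ds.values.loc[
            ds.values.index.intersection(list(genes))
        ]
        if values.empty:
            continue
        case = values.loc[:, ds.labels[ds.labels == CASE].index].to_numpy(dtype=float)
        ctrl = values.loc[:, ds.labels[ds.labels == CONTROL].index].to_numpy(dtype=float)
        lfc = case.mean(axis=1) - ctrl.mean(axis=1)
        s2c = case.var(axis=1, ddof=1) if case.shape[1] > 1 else np.zeros(len(values))
        s2n = ctrl.var(axis=1, ddof=1) if ctrl.shape[1] > 1 else np.zeros(len(values))
        variance = s2c / case.shape[1] + s2n / ctrl.shape[1]
        n_floored = int((variance <= 0.0).sum())
        if n_floored:
            logger.warning(
                "%s: %d zero LFC variance(s) floored", ds.meta.geo_id, n_floored
            )
            variance = np.maximum(variance, variance_floor)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": values.index,
                    "study_id": ds.meta.geo_id,
                    "lfc": lfc,
                    "variance": variance,
                    "n_case": case.shape[1],
                    "n_control": ctrl.shape[1],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=EFFECT_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    study_order = {ds.meta.geo_id: i for i, ds in enumerate(datasets)}
    gene_order = (
        {g: i for i, g in enumerate(genes)}
        if genes is not None
        else {g: i for i, g in enumerate(pd.unique(table["gene_id"]))}
    )
    table = table.sort_values(
        ["gene_id", "study_id"],
        key=lambda col: col.map(gene_order if col.name == "gene_id" else study_order),
        kind="stable",
    ).reset_index(drop=True)
    return table
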