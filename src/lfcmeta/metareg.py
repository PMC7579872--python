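"""Meta-regression: per-study effect sizes on study-level covariates.

Regresses a gene's per-study log fold changes on total sample size,
geographic region and study age by ordinary least squares, reporting
two-sided t p-values and 95% confidence intervals per coefficient.  With
~11 cohorts the seven countries are grouped into broad regions (Asia /
Europe / North America, Europe as reference) so the design keeps residual
degrees of freedom; the grouping is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ingest import DataError, StudyMeta

logger = logging.getLogger(__name__)

DEFAULT_REGION_MAP: dict[str, str] = {
    "China": "Asia",
    "Japan": "Asia",
    "Luxembourg": "Europe",
    "France": "Europe",
    "Netherlands": "Europe",
    "Germany": "Europe",
    "USA": "North America",
}
REFERENCE_REGION = "Europe"


@dataclass(frozen=True)
class RegressionResult:
    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    ci95: np.ndarray  # (n_params, 2)
    n_obs: int
    df_resid: int
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "coefficient": self.coefficients,
                "se": self.standard_errors,
                "p_value": self.p_values,
                "ci95_low": self.ci95[:, 0],
                "ci95_high": self.ci95[:, 1],
            }
        )


def build_design(
    metas: Sequence[StudyMeta],
    region_map: Mapping[str, str] | None = None,
    reference_region: str = REFERENCE_REGION,
) -> pd.DataFrame:
    """Design matrix: intercept, total sample size, region dummies, study age.

    The reference region's indicator is dropped; a region level present in
    no study, or a single-region design, simply yields fewer (or no)
    region columns, with a log note.  An unmapped country is a hard error.
    """
    region_map = dict(region_map) if region_map is not None else DEFAULT_REGION_MAP
    if len(metas) < 2:
        raise DataError("meta-regression needs at least two studies")
    unmapped = sorted({m.country for m in metas} - set(region_map))
    if unmapped:
        raise DataError(f"country not in region map: {unmapped}")

    regions = [region_map[m.country] for m in metas]
    levels = sorted(set(regions))
    dummy_levels = [r for r in levels if r != reference_region]
    if not dummy_levels:
        logger.info("single-region design: region columns dropped")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "sample_size": [float(m.n_total) for m in metas],
        },
        index=[m.geo_id for m in metas],
    )
    for lvl in dummy_levels:
        X[f"region[{lvl}]"] = [1.0 if r == lvl else 0.0 for r in regions]
    X["study_age"] = [m.study_age for m in metas]
    return X


def fit_mlr(y: Sequence[float], X: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with t-based inference.

    Constant columns other than the intercept are dropped with a log note;
    a rank-deficient design after that guard is a hard error naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise DataError(f"{len(y)} responses for {len(X)} design rows")
    X = X.copy()
    degenerate = [
        c for c in X.columns
        if c != "intercept" and np.ptp(X[c].to_numpy()) == 0.0
    ]
    if degenerate:
        logger.info("dropping constant covariate column(s): %s", degenerate)
        X = X.drop(columns=degenerate)
    if len(y) - X.shape[1] < 1:
        raise DataError(
            f"insufficient residual degrees of freedom "
            f"({len(y)} obs, {X.shape[1]} parameters)"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DataError(f"rank-deficient design; columns: {list(X.columns)}")

    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    ci_arr = ci.to_numpy() if hasattr(ci, "to_numpy") else np.asarray(ci)
    return RegressionResult(
        names=tuple(X.columns),
        coefficients=np.asarray(fit.params, dtype=float),
        standard_errors=np.asarray(fit.bse, dtype=float),
        p_values=np.asarray(fit.pvalues, dtype=float),
        ci95=ci_arr,
        n_obs=int(fit.nobs),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
    )


def regress_gene_effects(
    effects: pd.DataFrame,
    metas: Sequence[StudyMeta],
    region_map: Mapping[str, str] | None = None,
) -> RegressionResult:
    """Regress one gene's per-study LFCs on the study-level covariates.

    ``effects`` is the tidy per-study table for a single gene; studies
    without a measurement for the gene are omitted from the design.
    """
    by_id = {m.geo_id: m for m in metas}
    missing = sorted(set(effects["study_id"]) - set(by_id))
    if missing:
        raise DataError(f"effects reference unknown studies: {missing}")
    metas_used = [by_id[s] for s in effects["study_id"]]
    X = build_design(metas_used, region_map)
    return fit_mlr(effects["lfc"].to_numpy(dtype=float), X)
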