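"""Pooling per-study effects across cohorts.

For each gene the per-study log fold changes are combined by
inverse-variance weighting.  Heterogeneity is quantified with Cochran's Q
(weighted squared deviations from the fixed-effect mean), the I-squared
percentage ``(Q - df)/Q * 100`` clamped at 0, and the upper chi-square tail
of Q.  The model is chosen per gene: fixed effect when ``Q <= df``
(observed dispersion within what sampling alone explains), otherwise
random effects with the DerSimonian-Laird moment estimate of the
between-study variance tau2 and weights ``1/(v_i + tau2)``.

Two-sided p-values come from the normal approximation ``z = pooled/se``;
a small-k t-based option is available via ``use_t``.  Significant genes
must satisfy ``p < 0.005`` and ``|pooled LFC| > 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FIXED = "fixed"
RANDOM = "random"

P_THRESHOLD = 0.005
LFC_THRESHOLD = 1.0

#: z quantile used for 95% confidence intervals
Z_95 = 1.96

RESULT_COLUMNS = [
    "gene_id", "k", "pooled_lfc", "se", "std_lfc", "p_value", "Q", "df",
    "isq", "p_q", "tau2", "model", "ci95_low", "ci95_high",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate and heterogeneity statistics for one gene."""

    gene_id: str
    k: int
    pooled_lfc: float
    se: float
    std_lfc: float
    p_value: float
    Q: float
    df: int
    isq: float
    p_q: float
    tau2: float
    model: Literal["fixed", "random"]
    weights: Mapping[str, float]
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def _as_arrays(lfc, variance) -> tuple[np.ndarray, np.ndarray]:
    lfc = np.asarray(lfc, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if lfc.shape != variance.shape:
        raise ValueError("lfc and variance must have equal length")
    if (variance <= 0).any():
        raise ValueError("all variances must be > 0")
    return lfc, variance


def cochran_q(lfc: Sequence[float], variance: Sequence[float]) -> tuple[float, int]:
    """Cochran's Q and its degrees of freedom ``k - 1``.

    ``Q = sum w_i (lfc_i - mu_F)^2`` with inverse-variance weights and the
    fixed-effect pooled mean ``mu_F``; under homogeneity Q ~ chi2(k-1).
    """
    lfc, variance = _as_arrays(lfc, variance)
    k = lfc.size
    if k < 2:
        raise ValueError("heterogeneity undefined for fewer than 2 studies")
    w = 1.0 / variance
    mu = float((w * lfc).sum() / w.sum())
    q = float((w * (lfc - mu) ** 2).sum())
    return q, k - 1


def isq(q: float, df: int) -> float:
    """I-squared heterogeneity percentage ``(Q - df)/Q * 100``, clamped at 0."""
    if q < 0 or df < 1:
        raise ValueError("require Q >= 0 and df >= 1")
    if q <= df:
        return 0.0
    return (q - df) / q * 100.0


def q_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square probability of Q: the chance that the observed
    dispersion arises from within-study sampling alone."""
    if q < 0 or df < 1:
        raise ValueError("require Q >= 0 and df >= 1")
    return float(stats.chi2.sf(q, df))


def select_model(q: float, df: int) -> str:
    """Fixed effect iff ``Q <= df``, random effects otherwise."""
    return FIXED if q <= df else RANDOM


def pool_fixed(lfc: Sequence[float], variance: Sequence[float]) -> tuple[float, float]:
    """Inverse-variance weighted mean and its standard error."""
    lfc, variance = _as_arrays(lfc, variance)
    w = 1.0 / variance
    return float((w * lfc).sum() / w.sum()), float(math.sqrt(1.0 / w.sum()))


def dl_tau2(lfc: Sequence[float], variance: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    ``tau2 = max(0, (Q - df) / (S1 - S2/S1))`` with ``S1 = sum w_i``,
    ``S2 = sum w_i^2`` and inverse-variance weights.
    """
    lfc, variance = _as_arrays(lfc, variance)
    q, df = cochran_q(lfc, variance)
    w = 1.0 / variance
    s1, s2 = float(w.sum()), float((w**2).sum())
    return max(0.0, (q - df) / (s1 - s2 / s1))


def pool_random(
    lfc: Sequence[float], variance: Sequence[float], tau2: float
) -> tuple[float, float]:
    """Random-effects pooled mean with weights ``1/(v_i + tau2)``."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    lfc, variance = _as_arrays(lfc, variance)
    w = 1.0 / (variance + tau2)
    return float((w * lfc).sum() / w.sum()), float(math.sqrt(1.0 / w.sum()))


# ---------------------------------------------------------------------------
# per-gene analysis
# ---------------------------------------------------------------------------

def min_studies(total_studies: int, min_fraction: float = 0.5) -> int:
    """Coverage threshold: a gene must be measured in a majority of cohorts,
    never fewer than 2: ``max(2, ceil(min_fraction * total_studies))``."""
    return max(2, math.ceil(min_fraction * total_studies))


def meta_analyze_gene(
    effects: pd.DataFrame,
    total_studies: int | None = None,
    min_fraction: float = 0.5,
    use_t: bool = False,
) -> MetaResult | None:
    """Pool one gene's per-study effects; ``None`` if coverage is short.

    ``effects`` is the tidy per-study table for a single gene (columns
    gene_id, study_id, lfc, variance).  ``total_studies`` is the number of
    qualifying cohorts the majority rule refers to (defaults to the rows
    present).  The model is selected from Q versus df, p from the normal
    approximation (or Student t with df = k-1 when ``use_t``).
    """
    genes = effects["gene_id"].unique()
    if len(genes) != 1:
        raise ValueError(f"expected a single gene, got {list(genes)}")
    k = len(effects)
    total = total_studies if total_studies is not None else k
    if k < min_studies(total, min_fraction):
        return None

    lfc = effects["lfc"].to_numpy(dtype=float)
    variance = effects["variance"].to_numpy(dtype=float)
    q, df = cochran_q(lfc, variance)
    model = select_model(q, df)
    tau2 = dl_tau2(lfc, variance) if model == RANDOM else 0.0
    if model == RANDOM:
        pooled, se = pool_random(lfc, variance, tau2)
        w = 1.0 / (variance + tau2)
    else:
        pooled, se = pool_fixed(lfc, variance)
        w = 1.0 / variance
    z = pooled / se
    if use_t:
        p = float(2.0 * stats.t.sf(abs(z), df))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene_id=str(genes[0]), k=k, pooled_lfc=pooled, se=se,
        std_lfc=float(np.std(lfc, ddof=1)), p_value=p, Q=q, df=df,
        isq=isq(q, df), p_q=q_pvalue(q, df), tau2=tau2, model=model,
        weights=dict(zip(effects["study_id"], w / w.sum())),
        ci95=(pooled - Z_95 * se, pooled + Z_95 * se),
    )


def meta_analyze(
    effects: pd.DataFrame,
    total_studies: int | None = None,
    min_fraction: float = 0.5,
    use_t: bool = False,
) -> pd.DataFrame:
    """Pool every gene in a tidy effects table (vectorised across genes).

    Genes measured in fewer than the majority threshold of cohorts are
    excluded.  Returns one row per retained gene with the pooled estimate,
    heterogeneity statistics, selected model and 95% CI; numerically
    identical to mapping :func:`meta_analyze_gene` over genes.
    """
    if effects.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    total = (
        total_studies if total_studies is not None
        else effects["study_id"].nunique()
    )
    k_min = min_studies(total, min_fraction)

    # genes x studies matrices, NaN where unmeasured
    lfc_m = effects.pivot(index="gene_id", columns="study_id", values="lfc")
    var_m = effects.pivot(index="gene_id", columns="study_id", values="variance")
    order = pd.unique(effects["gene_id"])
    lfc_m, var_m = lfc_m.loc[order], var_m.loc[order]

    L, V = lfc_m.to_numpy(dtype=float), var_m.to_numpy(dtype=float)
    measured = ~np.isnan(L)
    k = measured.sum(axis=1)
    keep = k >= k_min
    if not keep.any():
        return pd.DataFrame(columns=RESULT_COLUMNS)
    L, V, measured, k = L[keep], V[keep], measured[keep], k[keep]
    gene_ids = lfc_m.index.to_numpy()[keep]

    W = np.where(measured, 1.0 / V, 0.0)
    s1 = W.sum(axis=1)
    s2 = (W**2).sum(axis=1)
    mu_f = (W * np.where(measured, L, 0.0)).sum(axis=1) / s1
    dev = np.where(measured, L - mu_f[:, None], 0.0)
    q = (W * dev**2).sum(axis=1)
    df = k - 1
    isq_v = np.where(q > df, (q - df) / np.where(q > 0, q, 1.0) * 100.0, 0.0)
    p_q = stats.chi2.sf(q, df)
    random_model = q > df
    tau2 = np.where(random_model, np.maximum(0.0, (q - df) / (s1 - s2 / s1)), 0.0)

    Wr = np.where(measured, 1.0 / (V + tau2[:, None]), 0.0)
    s1r = Wr.sum(axis=1)
    mu_r = (Wr * np.where(measured, L, 0.0)).sum(axis=1) / s1r
    pooled = np.where(random_model, mu_r, mu_f)
    se = np.where(random_model, np.sqrt(1.0 / s1r), np.sqrt(1.0 / s1))
    z = pooled / se
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(z), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    std_lfc = _nan_std_ddof1(L, measured)

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "k": k,
            "pooled_lfc": pooled,
            "se": se,
            "std_lfc": std_lfc,
            "p_value": p,
            "Q": q,
            "df": df,
            "isq": isq_v,
            "p_q": p_q,
            "tau2": tau2,
            "model": np.where(random_model, RANDOM, FIXED),
            "ci95_low": pooled - Z_95 * se,
            "ci95_high": pooled + Z_95 * se,
        }
    )


def _nan_std_ddof1(L: np.ndarray, measured: np.ndarray) -> np.ndarray:
    k = measured.sum(axis=1)
    mean = np.where(measured, L, 0.0).sum(axis=1) / k
    ss = (np.where(measured, L - mean[:, None], 0.0) ** 2).sum(axis=1)
    return np.sqrt(ss / np.maximum(k - 1, 1))


def significant_genes(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Filter pooled results to ``p < p_threshold`` and ``|LFC| > lfc_threshold``,
    sorted by p ascending."""
    keep = (results["p_value"] < p_threshold) & (
        results["pooled_lfc"].abs() > lfc_threshold
    )
    return results[keep].sort_values("p_value", kind="stable").reset_index(drop=True)


def forest_table(result: MetaResult, effects: pd.DataFrame) -> pd.DataFrame:
    """Per-study rows (LFC, 95% CI, weight %) plus a pooled summary row.

    Weights come from the selected model's normalised weights and sum to
    100%; per-study CIs are ``lfc_i +/- 1.96 * sqrt(v_i)``.
    """
    rows = []
    for rec in effects.itertuples():
        half = Z_95 * math.sqrt(rec.variance)
        rows.append(
            {
                "study_id": rec.study_id,
                "lfc": rec.lfc,
                "ci95_low": rec.lfc - half,
                "ci95_high": rec.lfc + half,
                "weight_percent": 100.0 * result.weights[rec.study_id],
            }
        )
    rows.append(
        {
            "study_id": "POOLED",
            "lfc": result.pooled_lfc,
            "ci95_low": result.ci95[0],
            "ci95_high": result.ci95[1],
            "weight_percent": 100.0,
        }
    )
    return pd.DataFrame(rows)


def add_bh_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg FDR column (informational; the
    significance filter uses raw p-values only)."""
    out = results.copy()
    if len(out):
        out["bh_fdr"] = stats.false_discovery_control(out["p_value"], method="bh")
    else:
        out["bh_fdr"] = pd.Series(dtype=float)
    return out
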