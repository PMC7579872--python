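"""Synthetic multi-study case/control expression data.

The generator emulates the statistical structure the pooling model assumes:
for gene *g* in study *i* the true study-level effect is drawn as
``theta_gi ~ Normal(true_lfc_g, tau2)``, control samples as
``Normal(baseline_mean, sigma2)`` and case samples as
``Normal(baseline_mean + theta_gi, sigma2)``, all on the log2 scale.
``tau2`` is the between-study heterogeneity variance and ``sigma2`` the
within-group sample variance.  Per-study gene coverage below 1 removes a
random gene subset from each study, emulating platform differences.

The default study design is the eleven-cohort catalogue
(:func:`cohort_catalogue`): 358 cases and 278 controls across seven
countries, study ages 2-13 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import CASE, CONTROL, ExpressionDataset, StudyMeta, write_metadata_table

_CATALOGUE_ROWS = [
    # study_name, geo_id, n_control, n_case, country, study_age (years)
    ("Nazarov et al., 2017", "GSE84784", 9, 9, "Luxembourg", 2),
    ("Tong et al., 2016", "GSE67061", 8, 69, "China", 3),
    ("Rousseaux et al., 2014", "GSE30219", 14, 61, "France", 5),
    ("Mascaux et al., 2014", "GSE33479", 27, 14, "USA", 5),
    ("Girard et al., 2012", "GSE32036", 59, 12, "USA", 7),
    ("Philipsen et al., 2010", "GSE19188", 65, 27, "Netherlands", 9),
    ("Takahashi et al., 2009", "GSE11969", 5, 35, "Japan", 10),
    ("Boelens et al., 2009", "GSE12472", 28, 35, "Netherlands", 10),
    ("Ishikawa et al., 2009", "GSE2088", 30, 48, "Japan", 10),
    ("Boelens et al., 2008", "GSE12428", 28, 34, "Netherlands", 11),
    ("Rosskopf et al., 2006", "GSE6044", 5, 14, "Germany", 13),
]


def cohort_catalogue() -> list[StudyMeta]:
    """The eleven-cohort catalogue used throughout as the default design.

    358 cases and 278 controls over seven countries; every record carries
    filter attributes that qualify it for the pooled analysis.
    """
    return [
        StudyMeta(
            geo_id=geo, study_name=name, n_control=nc, n_case=na,
            country=country, study_age=float(age),
        )
        for name, geo, nc, na, country, age in _CATALOGUE_ROWS
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    ``true_lfc`` maps gene identifier -> true log2 effect; genes not listed
    are null (effect 0).  ``coverage`` is the fraction of genes measured in
    each study (1.0 = every gene everywhere).  ``studies`` defaults to the
    eleven-cohort catalogue; pass an explicit list to change the design.
    """

    n_genes: int = 500
    true_lfc: Mapping[str, float] = field(default_factory=dict)
    tau2: float = 0.0
    sigma2: float = 1.0
    baseline_mean: float = 8.0
    coverage: float = 1.0
    seed: int = 0
    studies: Sequence[StudyMeta] | None = None

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValueError("variances must be >= 0")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.studies is None:
            self.studies = cohort_catalogue()
        if len(self.studies) < 1:
            raise ValueError("need at least one study")
        for s in self.studies:
            if s.n_case < 1 or s.n_control < 1:
                raise ValueError(f"{s.geo_id}: group sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        """Named (spiked) genes first, then auto-named nulls up to n_genes."""
        ids = [str(g) for g in self.true_lfc]
        if len(ids) > self.n_genes:
            raise ValueError("more named genes in true_lfc than n_genes")
        ids += [f"G{i:05d}" for i in range(self.n_genes - len(ids))]
        return ids

    def truth(self) -> pd.Series:
        """True log2 effect per gene (null genes at 0)."""
        ids = self.gene_ids
        return pd.Series(
            [float(self.true_lfc.get(g, 0.0)) for g in ids], index=ids, name="true_lfc"
        )


def generate_studies(config: SyntheticConfig) -> list[ExpressionDataset]:
    """Draw one expression cohort per study under the generative model.

    One master seed spawns per-study substreams, so the data of study *i*
    do not change when studies are appended after it.  With ``coverage < 1``
    each study measures a without-replacement gene subset; a configuration
    that would leave some gene unmeasured everywhere is rejected.
    """
    gene_ids = np.asarray(config.gene_ids, dtype=object)
    n_genes = len(gene_ids)
    truth = config.truth().to_numpy()
    tau = math.sqrt(config.tau2)
    sigma = math.sqrt(config.sigma2)

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.studies))

    n_cover = max(1, int(round(config.coverage * n_genes)))
    datasets, covered_any = [], np.zeros(n_genes, dtype=bool)
    for meta, stream in zip(config.studies, streams):
        rng = np.random.default_rng(stream)
        if n_cover < n_genes:
            idx = np.sort(rng.choice(n_genes, size=n_cover, replace=False))
        else:
            idx = np.arange(n_genes)
        covered_any[idx] = True
        g = len(idx)
        theta = truth[idx] + tau * rng.standard_normal(g)
        controls = config.baseline_mean + sigma * rng.standard_normal((g, meta.n_control))
        cases = (
            config.baseline_mean
            + theta[:, None]
            + sigma * rng.standard_normal((g, meta.n_case))
        )
        cols = [f"{meta.geo_id}_ctl{j}" for j in range(meta.n_control)] + [
            f"{meta.geo_id}_case{j}" for j in range(meta.n_case)
        ]
        values = pd.DataFrame(
            np.hstack([controls, cases]), index=gene_ids[idx], columns=cols
        )
        labels = pd.Series(
            [CONTROL] * meta.n_control + [CASE] * meta.n_case, index=cols
        )
        datasets.append(ExpressionDataset(values=values, labels=labels, meta=meta))
    if not covered_any.all():
        raise ValueError(
            f"coverage leaves {int((~covered_any).sum())} gene(s) measured in no study"
        )
    return datasets


def tau2_for_target_isq(
    variances: Sequence[float], isq_percent: float, df: int | None = None
) -> float:
    """Between-study variance giving an expected I-squared of ``isq_percent``.

    Solves E[Q] = df / (1 - I2/100) for tau2 through the moment identity
    E[Q] = df + tau2 * (S1 - S2/S1) with S1 = sum of inverse-variance
    weights and S2 = sum of squared weights.  Used to place simulations in
    a prescribed heterogeneity regime.
    """
    v = np.asarray(variances, dtype=float)
    if df is None:
        df = len(v) - 1
    if not (0.0 <= isq_percent < 100.0):
        raise ValueError("isq_percent must be in [0, 100)")
    w = 1.0 / v
    s1, s2 = w.sum(), (w**2).sum()
    expected_q = df / (1.0 - isq_percent / 100.0)
    return max(0.0, (expected_q - df) / (s1 - s2 / s1))


def write_bundle(
    datasets: Sequence[ExpressionDataset],
    config: SyntheticConfig,
    out_dir: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a generated cohort bundle in the layout the ingest module reads.

    Per study: ``<geo_id>_expr.tsv`` (gene x sample matrix) and
    ``<geo_id>_labels.tsv``; plus ``metadata.tsv`` and the ground-truth
    effect table ``truth_lfc.tsv`` for downstream evaluation.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.values.to_csv(out / f"{ds.meta.geo_id}_expr.tsv", sep="\t", index_label="gene_id")
        ds.labels.to_csv(out / f"{ds.meta.geo_id}_labels.tsv", sep="\t", header=False)
    write_metadata_table([ds.meta for ds in datasets], out / "metadata.tsv")
    config.truth().to_csv(out / "truth_lfc.tsv", sep="\t", index_label="gene_id")
    return out
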