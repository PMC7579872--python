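"""Venn decomposition and hypergeometric overlap test for two gene lists.

Given two disease gene lists drawn from a common universe of genes, the
overlap is scored with the one-sided (enrichment) hypergeometric upper
tail — the Fisher exact test of the directional question "do the lists
share more genes than two random lists of the same sizes would?".  The
universe size must be supplied by the caller; 20,000 protein-coding genes
is offered as a default, clearly a convention rather than a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

#: conventional protein-coding gene universe
DEFAULT_UNIVERSE = 20_000


def _normalize(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).strip().upper() for g in genes if str(g).strip())


@dataclass(frozen=True)
class GeneSetPair:
    """Two gene lists and the universe they are drawn from.

    Identifiers are case-normalised (uppercase, stripped) before any set
    arithmetic.
    """

    list_a: frozenset[str]
    list_b: frozenset[str]
    universe_n: int = DEFAULT_UNIVERSE

    def __init__(self, list_a: Iterable[str], list_b: Iterable[str],
                 universe_n: int = DEFAULT_UNIVERSE):
        object.__setattr__(self, "list_a", _normalize(list_a))
        object.__setattr__(self, "list_b", _normalize(list_b))
        object.__setattr__(self, "universe_n", int(universe_n))
        if len(self.list_a) > self.universe_n or len(self.list_b) > self.universe_n:
            raise ValueError("a gene list is larger than the universe")
        union = len(self.list_a | self.list_b)
        if union > self.universe_n:
            raise ValueError(
                f"union of lists ({union}) exceeds universe ({self.universe_n})"
            )


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    k_overlap: int
    a_only: int
    b_only: int
    percent_of_a: float
    p_value: float


def venn_counts(pair: GeneSetPair) -> tuple[int, int, int]:
    """(A-only, shared, B-only) counts by exact set arithmetic."""
    shared = pair.list_a & pair.list_b
    return (
        len(pair.list_a) - len(shared),
        len(shared),
        len(pair.list_b) - len(shared),
    )


def overlap_test(pair: GeneSetPair, two_sided: bool = False) -> OverlapResult:
    """Hypergeometric overlap test for the pair.

    ``p_value = P(X >= k)`` for ``X ~ Hypergeometric(universe_n, n_a, n_b)``
    (one-sided enrichment; ``two_sided`` doubles the smaller tail, capped
    at 1).  ``percent_of_a`` is the shared fraction of list A as a
    percentage.
    """
    a_only, k, b_only = venn_counts(pair)
    n_a, n_b = len(pair.list_a), len(pair.list_b)
    if n_a == 0:
        return OverlapResult(0, n_b, 0, 0, n_b, 0.0, 1.0)
    dist = stats.hypergeom(pair.universe_n, n_a, n_b)
    upper = float(dist.sf(k - 1))  # P(X >= k)
    if two_sided:
        lower = float(dist.cdf(k))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = min(1.0, upper)
    return OverlapResult(
        n_a=n_a, n_b=n_b, k_overlap=k, a_only=a_only, b_only=b_only,
        percent_of_a=100.0 * k / n_a, p_value=p,
    )


def read_gene_list(path: str | Path, sheet: str | None = None) -> list[str]:
    """Read a gene list: one symbol per line (plain text) or the first
    column of a named sheet in an xlsx workbook."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet or 0)
        return [str(g) for g in df.iloc[:, 0].dropna()]
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_overlap_report(result: OverlapResult, path: str | Path) -> None:
    pd.DataFrame([result.__dict__]).to_csv(path, sep="\t", index=False)
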