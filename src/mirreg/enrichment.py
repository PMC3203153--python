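"""Hypergeometric GO-term enrichment with C/O/E/R/rawP/adjP reporting.

For a gene set of size n drawn from a reference universe of N annotated
genes, a term annotating C universe genes and O gene-set genes is scored by
the hypergeometric upper tail P(X >= O), the expected overlap E = C*n/N,
and the enrichment ratio R = O/E. Raw p-values are adjusted across terms by
Benjamini-Hochberg step-up, and terms are flagged enriched at adjP below a
cutoff (default 0.001).

The universe is the set of measured genes carrying at least one annotation;
both it and the cutoff are explicit arguments, since reported p-values are
only meaningful relative to a stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnnotationTable


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    C: int
    O: int
    E: float
    R: float
    rawP: float
    adjP: float
    enriched: bool = False


def hypergeom_upper_tail(N: int, n: int, C: int, O: int) -> float:
    """P(X >= O) for X ~ Hypergeometric(N population, C successes, n draws)."""
    if not (0 <= O <= min(n, C) <= N and n <= N and C <= N):
        raise ValueError(f"inconsistent counts: N={N}, n={n}, C={C}, O={O}")
    return float(stats.hypergeom.sf(O - 1, N, C, n))


def enrichment_ratio(O: float, E: float) -> float:
    """R = O/E rounded to two decimals as printed in report tables."""
    if E <= 0:
        if O > 0:
            raise ValueError("expected count E = 0 with observed O > 0")
        return 0.0
    return round(O / E, 2)


def expected_and_ratio(C: int, n: int, N: int, O: int) -> tuple[float, float]:
    """Expected overlap E = C*n/N and ratio R = O/E (both 2-decimal rounded)."""
    if N <= 0 or n <= 0:
        raise ValueError("N and n must be positive")
    E = C * n / N
    return round(E, 2), enrichment_ratio(O, E)


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def enrich(
    gene_set: set[str],
    annotation: AnnotationTable,
    universe: set[str],
    p_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Score every term overlapping the gene set; one row per term with O >= 1.

    N is the number of universe genes with at least one annotation and n the
    number of gene-set genes among them. Rows are sorted by rawP; those with
    adjP < p_cutoff carry enriched=True.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    ann = annotation.restrict_to(universe)
    mapped_universe = ann.annotated_genes()
    N = len(mapped_universe)
    mapped_set = gene_set & mapped_universe
    n = len(mapped_set)
    rows = []
    for term, genes in sorted(ann.term_genes.items()):
        C = len(genes)
        O = len(genes & mapped_set)
        if O < 1:
            continue
        E, R = expected_and_ratio(C, n, N, O)
        rows.append(
            {
                "term_id": term,
                "term_name": ann.term_names.get(term, ""),
                "C": C,
                "O": O,
                "E": E,
                "R": R,
                "rawP": hypergeom_upper_tail(N, n, C, O),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "C", "O", "E", "R", "rawP"]
    )
    if len(df):
        df["adjP"] = bh_adjust(df["rawP"].to_numpy())
        df["enriched"] = df["adjP"] < p_cutoff
        df = df.sort_values("rawP", kind="stable").reset_index(drop=True)
    else:
        df["adjP"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df
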