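"""Gene-set restriction and two-group differential expression.

Tumour-vs-normal filtering of a metabolic gene universe: per-gene
log2 fold change on pseudocounted group means, a two-sided Wilcoxon
rank-sum p-value (robust for FPKM-like abundances), and the standard
threshold filter p < alpha and |log2FC| > lfc (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialResult",
    "restrict_to_gene_set",
    "differential_test",
    "de_filter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialResult:
    gene: str
    log2fc: float
    p_value: float
    p_adjusted: float
    direction: str  # up / down / ns


def _norm_symbol(g: str) -> str:
    return g.strip().upper()


def restrict_to_gene_set(expr: pd.DataFrame, genes) -> pd.DataFrame:
    """Keep only rows whose gene symbol is in ``genes`` (order preserved).

    Matching is case-insensitive after trimming; symbol collisions keep
    the first occurrence.  An empty intersection is an error.
    """
    wanted = {_norm_symbol(g) for g in genes}
    norm_index = expr.index.map(_norm_symbol)
    dup = norm_index.duplicated(keep="first")
    if dup.any():
        log.warning("dropping %d duplicate gene symbols (first kept)", dup.sum())
        expr = expr.loc[~dup]
        norm_index = norm_index[~dup]
    mask = norm_index.isin(wanted)
    matched = int(mask.sum())
    if matched == 0:
        raise ValueError("gene set does not intersect the expression matrix")
    log.info(
        "gene-set restriction: %d matched, %d unmatched rows, %d set members absent",
        matched,
        len(expr) - matched,
        len(wanted) - matched,
    )
    return expr.loc[mask]


def differential_test(
    expr: pd.DataFrame,
    groups: pd.Series,
    *,
    pseudocount: float = 1.0,
    method: str = "ranksum",
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> list[DifferentialResult]:
    """Per-gene tumour-vs-normal test on a genes x samples matrix.

    ``groups`` maps sample id -> 'tumour'/'normal'.  log2FC uses
    pseudocounted group means; the p-value is a two-sided Wilcoxon
    rank-sum by default (``method='ttest'`` swaps in Welch's t).
    Benjamini-Hochberg adjusted p-values are reported alongside.
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("every expression column needs a group label")
    t_cols = groups[groups == "tumour"].index
    n_cols = groups[groups == "normal"].index
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >=2 samples per group")

    T = expr[t_cols].to_numpy(dtype=float)
    N = expr[n_cols].to_numpy(dtype=float)
    log2fc = np.log2((T.mean(axis=1) + pseudocount) / (N.mean(axis=1) + pseudocount))

    pvals = np.empty(expr.shape[0])
    for i in range(expr.shape[0]):
        if np.ptp(np.concatenate([T[i], N[i]])) == 0:
            pvals[i] = 1.0  # constant gene carries no group signal
            continue
        if method == "ranksum":
            pvals[i] = stats.mannwhitneyu(T[i], N[i], alternative="two-sided").pvalue
        elif method == "ttest":
            pvals[i] = stats.ttest_ind(T[i], N[i], equal_var=False).pvalue
        else:
            raise ValueError(f"unknown test method {method!r}")
    p_adj = stats.false_discovery_control(pvals, method="bh")

    results = []
    for gene, fc, p, pa in zip(expr.index, log2fc, pvals, p_adj):
        if p < alpha and fc > lfc:
            direction = "up"
        elif p < alpha and fc < -lfc:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DifferentialResult(
                gene=str(gene),
                log2fc=float(fc),
                p_value=float(p),
                p_adjusted=float(pa),
                direction=direction,
            )
        )
    return results


def de_filter(
    results: list[DifferentialResult], alpha: float = 0.05, lfc: float = 1.0
) -> tuple[list[str], list[str]]:
    """Partition into up/down lists by p < alpha and |log2FC| strictly > lfc."""
    up = [r.gene for r in results if r.p_value < alpha and r.log2fc > lfc]
    down = [r.gene for r in results if r.p_value < alpha and r.log2fc < -lfc]
    return up, down


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabular view of DE results (gene, log2fc, p, p_adj, direction)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
        }
    )
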