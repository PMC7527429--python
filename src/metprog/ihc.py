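"""Semi-quantitative immunohistochemistry scoring and clinical association.

Staining intensity (0 none, 1 weak, 2 strong) is multiplied by a staining
extent score (0-4, binned from the percentage of immunoreactive cells) to
give a 0-8 composite; 0-4 is called negative, 5-8 positive.  Marker status
is then crossed with clinical covariates and tested by Pearson chi-square
without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IHCScore",
    "ContingencyResult",
    "extent_from_percent",
    "ihc_score",
    "chi_square_association",
    "association_table",
]

log = logging.getLogger(__name__)

POSITIVE_THRESHOLD = 5  # composite score >= 5 is called positive

# Upper edges of the extent bins: 0%, (0,5], (5,25], (25,75], (75,100].
# The published bin labels overlap at 5 and 25; upper-edge-inclusive
# half-open bins make the mapping deterministic and honour ">75%" on top.
_EXTENT_EDGES = (0.0, 5.0, 25.0, 75.0)


@dataclass(frozen=True)
class IHCScore:
    intensity: int
    extent: int
    score: int
    label: str  # negative / positive


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    chi_square: float
    df: int
    p_value: float


def extent_from_percent(pct: float) -> int:
    """Map percent immunoreactive cells to the 0-4 extent score."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage must be in [0, 100], got {pct}")
    for score, edge in enumerate(_EXTENT_EDGES):
        if pct <= edge:
            return score
    return 4


def ihc_score(intensity: int, pct: float) -> IHCScore:
    """Composite staining score = intensity x extent, dichotomized."""
    if intensity not in (0, 1, 2):
        raise ValueError(f"intensity must be 0, 1 or 2, got {intensity}")
    extent = extent_from_percent(pct)
    score = intensity * extent
    label = "positive" if score >= POSITIVE_THRESHOLD else "negative"
    return IHCScore(intensity=intensity, extent=extent, score=score, label=label)


def chi_square_association(table) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) on an r x c count table.

    Low expected counts are logged but do not switch the method to an
    exact test; the uncorrected Pearson statistic is used throughout.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any() or table.sum() <= 0:
        raise ValueError("table must contain non-negative counts with positive total")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        log.warning(
            "%d of %d expected counts below 5; Pearson chi-square kept",
            int((expected < 5).sum()),
            expected.size,
        )
    return ContingencyResult(
        table=table.astype(int), chi_square=float(chi2), df=int(df), p_value=float(p)
    )


def association_table(
    clinical: pd.DataFrame,
    marker_col: str = "marker",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Cross each clinical covariate with marker status (Table-1 style).

    ``clinical`` holds one row per patient with a binary/negative-positive
    marker column and categorical covariates.  Returns one row per
    covariate with its chi-square, df and p-value.
    """
    if covariates is None:
        covariates = [c for c in clinical.columns if c != marker_col]
    rows = []
    for cov in covariates:
        counts = pd.crosstab(clinical[cov], clinical[marker_col])
        res = chi_square_association(counts.to_numpy())
        rows.append(
            {
                "variable": cov,
                "levels": counts.shape[0],
                "chi_square": res.chi_square,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
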