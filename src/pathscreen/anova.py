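"""Pairwise cell-type comparisons of per-analyte Z-scores.

One-way ANOVA for every unordered pair of cell types within each analyte,
with Bonferroni adjustment.  With four cell types there are six pairs per
analyte; the default Bonferroni family is those six comparisons (m = 6),
configurable to span analytes as well (m = 66 for eleven analytes).

For two groups the ANOVA F statistic equals the square of the
pooled-variance t statistic, so the p-value coincides with a two-sided
pooled t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "pairwise_anova_bonferroni"]


@dataclass(frozen=True)
class AnovaResult:
    analyte: str
    group_a: str
    group_b: str
    F: float
    df1: int
    df2: int
    p_raw: float
    p_adjusted: float
    m: int
    testable: bool = True


def _one_way_f(a: np.ndarray, b: np.ndarray) -> tuple[float, int, int, float]:
    res = stats.f_oneway(a, b)
    df1 = 1
    df2 = a.size + b.size - 2
    return float(res.statistic), df1, df2, float(res.pvalue)


def pairwise_anova_bonferroni(
    z: dict[str, pd.DataFrame], m: int | None = None
) -> pd.DataFrame:
    """One-way ANOVA per (analyte, cell-type pair) with Bonferroni correction.

    Parameters
    ----------
    z : mapping of cell type to Z-score matrix (rows samples, columns analytes).
    m : Bonferroni family size; defaults to the number of cell-type pairs
        (the per-analyte family).

    Returns a DataFrame of ``AnovaResult`` fields; pairs where a group has
    fewer than two non-missing values are flagged untestable rather than
    dropped.  p_adjusted = min(1, m * p_raw).
    """
    cell_types = list(z)
    pairs = list(combinations(cell_types, 2))
    if m is None:
        m = len(pairs)
    analytes: list[str] = []
    for mat in z.values():
        for an in mat.columns:
            if an not in analytes:
                analytes.append(an)
    rows = []
    for an in analytes:
        for ct_a, ct_b in pairs:
            a = z[ct_a][an].dropna().to_numpy(dtype=float) if an in z[ct_a] else np.array([])
            b = z[ct_b][an].dropna().to_numpy(dtype=float) if an in z[ct_b] else np.array([])
            if a.size < 2 or b.size < 2:
                rows.append(
                    AnovaResult(an, ct_a, ct_b, np.nan, 1, a.size + b.size - 2,
                                np.nan, np.nan, m, testable=False)
                )
                continue
            # Identical groups give SSB = 0; scipy warns about degenerate F.
            if np.ptp(np.concatenate([a, b])) == 0.0:
                F, df1, df2, p = 0.0, 1, a.size + b.size - 2, 1.0
            else:
                F, df1, df2, p = _one_way_f(a, b)
                if not np.isfinite(F):
                    F, p = np.inf, 0.0
                if F == 0.0:
                    p = 1.0
            rows.append(
                AnovaResult(an, ct_a, ct_b, F, df1, df2, p, min(1.0, m * p), m)
            )
    return pd.DataFrame([r.__dict__ for r in rows])
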