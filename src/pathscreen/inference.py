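"""Significance of a Pearson correlation and Fisher r-to-z comparison of
two correlations.

``pearson_p`` converts a coefficient to a t statistic,
t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom, and returns
the two-sided tail probability.

``compare_correlations`` applies the Fisher transformation z = atanh(r),
whose sampling variance is approximately 1 / (n - 3), and compares two
coefficients with

    z_stat = (atanh(r2) - atanh(r1)) / sqrt(1/(n1 - 3) + 1/(n2 - 3))

against the standard normal (two-sided).  This is the independent-samples
formula; when the two correlations share samples (e.g. r(x, y) versus
r(x, ln y) on the same cohort) it is an approximation, and a dependent
overlapping-correlation variant (Steiger's Z) is available separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RToZResult",
    "pearson_p",
    "compare_correlations",
    "compare_dependent_correlations",
    "table1_report",
]


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation of r at sample size n.

    |r| = 1 returns exactly 0; |r| > 1 or n < 3 is an error.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class RToZResult:
    r1: float
    r2: float
    n1: int
    n2: int
    z_stat: float
    p: float
    method: str = "independent_fisher_rtoz"


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> RToZResult:
    """Compare two Pearson correlations from independent samples.

    z_stat is signed (positive when r2 > r1 on the z scale); p is
    two-sided.  Swapping the two correlations flips the sign of z_stat and
    leaves p unchanged.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("n must be >= 4 for the r-to-z comparison")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = float((z2 - z1) / se)
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return RToZResult(r1=r1, r2=r2, n1=n1, n2=n2, z_stat=z_stat, p=p)


def compare_dependent_correlations(
    r12: float, r13: float, r23: float, n: int
) -> RToZResult:
    """Steiger's Z for two overlapping dependent correlations.

    Compares r12 = r(x, y1) with r13 = r(x, y2) measured on the same n
    samples, where r23 = r(y1, y2) captures their dependence.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    for r in (r12, r13):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = (r12 + r13) / 2.0
    # covariance of the two correlations (Steiger 1980, eq. 14 pooled form)
    num = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
        1.0 - 2.0 * rbar**2 - r23**2
    )
    den = (1.0 - rbar**2) ** 2
    cov = num / den
    se = np.sqrt((2.0 - 2.0 * cov) / (n - 3))
    z_stat = float((z13 - z12) / se)
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return RToZResult(
        r1=r12, r2=r13, n1=n, n2=n, z_stat=z_stat, p=p, method="dependent_steiger"
    )


def table1_report(rows: pd.DataFrame, dependent: bool = False) -> pd.DataFrame:
    """Build a per-cell-type comparison table of a raw versus a
    transformed correlation.

    ``rows`` needs columns cell_type, r_raw, r_transformed, n (and r_dep
    when ``dependent``).  Output columns follow the four-column layout:
    cell type, n, each correlation with its own significance, and the
    r-to-z p for the contrast.
    """
    out = []
    for _, row in rows.iterrows():
        n = int(row["n"])
        r1, r2 = float(row["r_raw"]), float(row["r_transformed"])
        if dependent:
            res = compare_dependent_correlations(r1, r2, float(row["r_dep"]), n)
        else:
            res = compare_correlations(r1, n, r2, n)
        out.append(
            {
                "cell_type": row["cell_type"],
                "n": n,
                "r_raw": r1,
                "p_raw": pearson_p(r1, n),
                "r_transformed": r2,
                "p_transformed": pearson_p(r2, n),
                "z_stat": res.z_stat,
                "p_rtoz": res.p,
            }
        )
    return pd.DataFrame(out)


def format_p_magnitude(p: float) -> str:
    """Order-of-magnitude display (e.g. 1e-19 -> '10^-19') for tiny p."""
    if p <= 0:
        return "0"
    if p >= 0.001:
        return f"{p:.4f}"
    return f"10^{int(np.floor(np.log10(p)))}"
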