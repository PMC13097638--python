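"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths (and numpy's corrcoef /
polyfit / median where practical): Pearson r from raw sums, OLS via the
normal equations, a sort-based median, and one-way ANOVA from explicit
sums of squares.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_oracle(x, y) -> float:
    """Pearson r from the raw-sum formula."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    if den == 0:
        return float("nan")
    return num / den


def ols_oracle(u, v) -> tuple[float, float]:
    """(intercept, slope) by solving the normal equations directly."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.column_stack([np.ones_like(u), u])
    beta = np.linalg.solve(X.T @ X, X.T @ v)
    return float(beta[0]), float(beta[1])


def median_oracle(values) -> float:
    """Median via explicit sorting and the even-count mean convention."""
    s = sorted(float(v) for v in values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return 0.5 * (s[mid - 1] + s[mid])


def anova_oracle(*groups) -> tuple[float, int, int, float]:
    """One-way ANOVA (F, df1, df2, p) from explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = sum(g.sum() for g in groups) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        return (float("inf") if ssb > 0 else 0.0), df1, df2, (0.0 if ssb > 0 else 1.0)
    f = (ssb / df1) / (ssw / df2)
    return f, df1, df2, float(stats.f.sf(f, df1, df2))


def transform_matrix_oracle(values: np.ndarray) -> dict[str, np.ndarray]:
    """The four transform-pair correlation matrices, entry by entry, using
    ``pearson_oracle`` on pairwise-complete observations."""
    k = values.shape[1]
    coords = {"x": values, "lnx": np.log(values)}
    out = {}
    for key, (cx, cy) in {
        "x.y": ("x", "x"),
        "lnx.y": ("lnx", "x"),
        "x.lny": ("x", "lnx"),
        "lnx.lny": ("lnx", "lnx"),
    }.items():
        mat = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                xi = coords[cx][:, i]
                yj = coords[cy][:, j]
                mask = ~np.isnan(xi) & ~np.isnan(yj)
                if mask.sum() < 3:
                    continue
                mat[i, j] = pearson_oracle(list(xi[mask]), list(yj[mask]))
        out[key] = mat
    return out
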