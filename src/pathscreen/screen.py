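"""Transform-pair correlation matrices and nonlinear-candidate screening.

A linear association shows up in the ordinary Pearson correlation matrix;
logarithmic, exponential and power associations do not, but each becomes
linear after taking the natural log of one or both coordinates.  Screening
therefore computes four matrices per cell type over the analyte panel:

    (x, y)        linear form
    (ln x, y)     logarithmic form
    (x, ln y)     exponential form
    (ln x, ln y)  power form

Only the (x, y) and (ln x, ln y) matrices are symmetric in the analyte
pair; r(ln x, y) is generally different from r(x, ln y), so the mixed
matrices are stored as full asymmetric tables.

Entries are shaded by |r|: strong at |r| >= 0.7, weak for 0.6 < |r| < 0.7,
none at |r| <= 0.6 (the boundary 0.6 itself is not shaded; 0.7 is strong).
A pair is flagged as a nonlinear candidate when a transformed-coordinate
|r| exceeds the raw |r| and clears the strong threshold.  As a sanity
check on the transform the self-correlation r(x, ln x) is reported per
analyte and flagged when any value drops to 0.9 or below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRANSFORM_PAIRS",
    "Thresholds",
    "CorrelationMatrixSet",
    "ShadeCall",
    "correlation_matrix_set",
    "screen_and_shade",
]

TRANSFORM_PAIRS = ("x.y", "lnx.y", "x.lny", "lnx.lny")

MIN_PAIRWISE_N = 3


@dataclass(frozen=True)
class Thresholds:
    strong: float = 0.7
    shade: float = 0.6
    self_ln: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.shade < self.strong < 1):
            raise ValueError("need 0 < shade < strong < 1")


@dataclass
class CorrelationMatrixSet:
    """Four Pearson matrices (r and pairwise-complete n) for one cell type."""

    cell_type: str
    r: dict[str, pd.DataFrame] = field(default_factory=dict)
    n: dict[str, pd.DataFrame] = field(default_factory=dict)
    self_ln_r: pd.Series | None = None  # r(x, ln x) per analyte


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def correlation_matrix_set(
    m: pd.DataFrame, cell_type: str = "", min_n: int = MIN_PAIRWISE_N
) -> CorrelationMatrixSet:
    """Compute the four transform-pair correlation matrices for one
    expression matrix (rows samples, columns analytes, positive values).

    Pearson r is computed on pairwise-complete observations in each of the
    four coordinate systems; entries with fewer than ``min_n`` complete
    pairs are reported missing, as are entries with zero variance in either
    coordinate (with a warning).  Natural logs are taken of the raw
    positive medians; any nonpositive value is an error, not a silent shift.
    """
    values = m.to_numpy(dtype=float)
    if np.any(values[~np.isnan(values)] <= 0):
        raise ValueError("expression matrix contains nonpositive values; ln undefined")
    analytes = list(m.columns)
    k = len(analytes)
    raw = values
    ln = np.log(values)
    coords = {"x": raw, "lnx": ln}
    out = CorrelationMatrixSet(cell_type=cell_type)
    for key in TRANSFORM_PAIRS:
        xs_key, ys_key = key.split(".")
        X = coords["lnx"] if xs_key == "lnx" else coords["x"]
        Y = coords["lnx"] if ys_key == "lny" else coords["x"]
        r_mat = np.full((k, k), np.nan)
        n_mat = np.zeros((k, k), dtype=int)
        for i in range(k):
            for j in range(k):
                mask = ~np.isnan(X[:, i]) & ~np.isnan(Y[:, j])
                n_ij = int(mask.sum())
                n_mat[i, j] = n_ij
                if n_ij < min_n:
                    continue
                r_ij = _pearson(X[mask, i], Y[mask, j])
                if np.isnan(r_ij):
                    warnings.warn(
                        f"zero variance for pair ({analytes[i]}, {analytes[j]}) "
                        f"under transform {key}; entry set missing",
                        stacklevel=2,
                    )
                r_mat[i, j] = r_ij
        out.r[key] = pd.DataFrame(r_mat, index=analytes, columns=analytes)
        out.n[key] = pd.DataFrame(n_mat, index=analytes, columns=analytes)
    # r(x, ln x) per analyte: diagonal of the (x, ln y) matrix.
    out.self_ln_r = pd.Series(
        np.diag(out.r["x.lny"].to_numpy()), index=analytes, name="r_x_lnx"
    )
    return out


@dataclass(frozen=True)
class ShadeCall:
    x_analyte: str
    y_analyte: str
    transform: str
    r: float
    category: str


def _category(r: float, th: Thresholds) -> str:
    if np.isnan(r):
        return "none"
    if abs(r) >= th.strong:
        return "strong_positive" if r > 0 else "strong_negative"
    if abs(r) > th.shade:
        return "weak_positive" if r > 0 else "weak_negative"
    return "none"


def screen_and_shade(
    cms: CorrelationMatrixSet, thresholds: Thresholds | None = None
) -> tuple[list[ShadeCall], pd.DataFrame]:
    """Shade every matrix entry and flag nonlinear candidates.

    Returns the list of shade calls (one per analyte pair and transform
    pair, plus ``self_ln_check`` entries for the x-vs-ln(x) diagonal) and a
    DataFrame of nonlinear candidates: pairs where a transformed-coordinate
    |r| exceeds the raw |r| and reaches the strong threshold.
    """
    th = thresholds if thresholds is not None else Thresholds()
    analytes = list(cms.r["x.y"].columns)
    calls: list[ShadeCall] = []
    candidates = []
    for i, ax in enumerate(analytes):
        for j, ay in enumerate(analytes):
            if ax == ay:
                continue
            r_raw = cms.r["x.y"].iat[i, j]
            for key in TRANSFORM_PAIRS:
                r_val = cms.r[key].iat[i, j]
                calls.append(ShadeCall(ax, ay, key, float(r_val), _category(r_val, th)))
                if key == "x.y" or np.isnan(r_val):
                    continue
                if (
                    not np.isnan(r_val)
                    and abs(r_val) >= th.strong
                    and (np.isnan(r_raw) or abs(r_val) > abs(r_raw))
                ):
                    candidates.append(
                        {
                            "cell_type": cms.cell_type,
                            "x_analyte": ax,
                            "y_analyte": ay,
                            "transform": key,
                            "r_raw": float(r_raw),
                            "r_transformed": float(r_val),
                            "n": int(cms.n[key].iat[i, j]),
                        }
                    )
    if cms.self_ln_r is not None:
        for an, r_val in cms.self_ln_r.items():
            flagged = (not np.isnan(r_val)) and r_val <= th.self_ln
            calls.append(
                ShadeCall(an, an, "x.lny", float(r_val),
                          "self_ln_check_flagged" if flagged else "self_ln_check")
            )
    cand = pd.DataFrame(
        candidates,
        columns=[
            "cell_type", "x_analyte", "y_analyte", "transform",
            "r_raw", "r_transformed", "n",
        ],
    )
    return calls, cand
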