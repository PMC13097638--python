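"""Event-level data to per-sample median expression and per-analyte Z-scores.

A sample's expression level for an analyte is the median fluorescence
intensity of its (unimodal) event peak.  For cross-cell-type display the
medians are converted to Z-scores per analyte, pooling samples of all cell
types — pooling within a cell type would force every cell-type mean to
zero and defeat the comparison.

Association analyses downstream always consume the raw positive medians,
never Z-scores: the natural-log transforms are undefined for the negative
values Z-scoring produces.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import EventTable

__all__ = ["summarise_medians", "zscore"]

logger = logging.getLogger(__name__)


def summarise_medians(events: EventTable) -> dict[str, pd.DataFrame]:
    """Median fluorescence intensity per (sample, analyte), one wide matrix
    per cell type (rows = sample_id, columns = analyte).

    Even event counts use the mean of the two central order statistics.
    An empty event list yields a missing value with a logged warning.
    """
    rec = events.records
    medians = np.empty(len(rec))
    for i, ev in enumerate(rec["events"].to_numpy()):
        ev = np.asarray(ev, dtype=float)
        if ev.size == 0:
            logger.warning(
                "no events for (%s, %s, %s); value set missing",
                rec["cell_type"].iat[i],
                rec["sample_id"].iat[i],
                rec["analyte"].iat[i],
            )
            medians[i] = np.nan
        else:
            medians[i] = np.median(ev)
    flat = rec[["cell_type", "sample_id", "analyte"]].copy()
    flat["median"] = medians
    out: dict[str, pd.DataFrame] = {}
    for ct, sub in flat.groupby("cell_type", sort=False):
        wide = sub.pivot(index="sample_id", columns="analyte", values="median")
        # preserve first-appearance analyte order
        order = sub["analyte"].drop_duplicates().tolist()
        out[ct] = wide[order]
    return out


def apply_exclusions(
    matrices: dict[str, pd.DataFrame], exclusions: dict[str, list[str]]
) -> dict[str, pd.DataFrame]:
    """Drop pre-registered sample ids per cell type before any statistic."""
    out = {}
    for ct, m in matrices.items():
        drop = [s for s in exclusions.get(ct, ()) if s in m.index]
        out[ct] = m.drop(index=drop)
    return out


def zscore(matrices: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Per-analyte Z-scores pooled across all cell types.

    Z = (x - pooled mean) / pooled sample SD (ddof=1), pooling the samples
    of every cell type for each analyte.  Missing values stay missing.
    Raises ``ValueError`` naming the analyte if its pooled variance is zero.
    """
    analytes: list[str] = []
    for m in matrices.values():
        for an in m.columns:
            if an not in analytes:
                analytes.append(an)
    stats: dict[str, tuple[float, float]] = {}
    for an in analytes:
        pooled = np.concatenate(
            [
                m[an].dropna().to_numpy(dtype=float)
                for m in matrices.values()
                if an in m.columns
            ]
        )
        if pooled.size < 2 or np.unique(pooled).size < 2:
            raise ValueError(f"zero pooled variance for analyte {an!r}")
        sd = float(np.std(pooled, ddof=1))
        if sd == 0.0:
            raise ValueError(f"zero pooled variance for analyte {an!r}")
        stats[an] = (float(np.mean(pooled)), sd)
    out = {}
    for ct, m in matrices.items():
        z = m.copy().astype(float)
        for an in m.columns:
            mean, sd = stats[an]
            z[an] = (m[an] - mean) / sd
        out[ct] = z
    return out
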