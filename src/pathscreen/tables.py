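"""TSV/CSV interchange for the pipeline's tables.

Expression and Z-score matrices travel as wide-format TSV (rows =
samples, columns = analytes, missing = "NA"), one file per cell type.
Event tables travel as long-format CSV.  Floats are written with
``repr``-level precision so a round trip through disk is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .simulate import CohortConfig, Coupling, EventTable, TruthTable

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_event_table",
    "read_event_table",
    "write_truth_table",
    "read_config",
]


def write_matrix(m: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written floats come back bit-identical
    return pd.read_csv(
        path, sep="\t", index_col="sample_id", na_values=["NA"],
        float_precision="round_trip",
    )


def write_event_table(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_long().to_csv(path, index=False)
    return path


def read_event_table(path: str | Path) -> EventTable:
    return EventTable.from_long(pd.read_csv(path))


def write_truth_table(truth: TruthTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.latents.to_csv(path, sep="\t", index=False)
    return path


def _coupling_from_dict(d: dict) -> Coupling:
    return Coupling(
        cell_type=d["cell_type"],
        x_analyte=d["x_analyte"],
        y_analyte=d["y_analyte"],
        form=d["form"],
        a=float(d["a"]),
        b=float(d["b"]),
        noise_sd=float(d.get("noise_sd", 0.05)),
    )


def read_config(path: str | Path) -> dict:
    """Load a pipeline/cohort config from YAML or JSON.

    A ``cohort`` section, if present, is materialised into a
    ``CohortConfig`` (baseline keys are "cell_type:analyte" strings).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "cohort" in raw and isinstance(raw["cohort"], dict):
        c = dict(raw["cohort"])
        if "couplings" in c:
            c["couplings"] = [_coupling_from_dict(d) for d in c["couplings"]]
        if "baseline" in c:
            c["baseline"] = {
                tuple(k.split(":")): tuple(v) for k, v in c["baseline"].items()
            }
        if "cell_types" in c:
            c["cell_types"] = tuple(c["cell_types"])
        if "analytes" in c:
            c["analytes"] = tuple(c["analytes"])
        raw["cohort"] = CohortConfig(**c)
    return raw
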