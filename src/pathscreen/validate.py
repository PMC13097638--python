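"""Parameter-recovery and screening-power studies on simulated cohorts.

These routines quantify how well the full analysis chain (event simulation
-> median summarisation -> model fitting and classification) recovers a
known ground truth, replicate by replicate.  They are the package's own
calibration experiments: each replicate simulates a two-analyte cohort
with a single coupling at the study's sample sizes and event counts, runs
the standard pipeline functions on it, and scores the outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import classify_relationship
from .screen import correlation_matrix_set
from .simulate import CohortConfig, Coupling, generate_cohort
from .summarise import summarise_medians

__all__ = ["FORM_BENCHMARKS", "form_recovery", "exponential_screen_improvement"]

# One benchmark coupling per model form.  Sample sizes follow the cohort
# design (the cell type each motif appears in); coefficients are sized so
# the linearized signal spans O(1) at baseline intensity scale.
FORM_BENCHMARKS: dict[str, dict] = {
    "linear": dict(a=0.6, b=30.0, n=115, x_loc=120.0, x_scale=0.5, label="rheostat"),
    "logarithmic": dict(a=40.0, b=-50.0, n=108, x_loc=120.0, x_scale=0.5,
                        label="on_switch"),
    "exponential": dict(a=50.0, b=0.004, n=115, x_loc=150.0, x_scale=0.6,
                        label="on_switch"),
    "power": dict(a=2.0e5, b=-1.5, n=108, x_loc=120.0, x_scale=0.5,
                  label="off_switch"),
}


def _benchmark_config(form: str, noise_sd: float, n: int | None, seed: int,
                      events_per_peak: int) -> tuple[CohortConfig, dict]:
    spec = FORM_BENCHMARKS[form]
    n = n if n is not None else spec["n"]
    cfg = CohortConfig(
        cell_types=("ct",),
        n_samples={"ct": n},
        analytes=("X", "Y"),
        events_per_peak_mean=events_per_peak,
        baseline={
            ("ct", "X"): (spec["x_loc"], spec["x_scale"]),
            ("ct", "Y"): (100.0, 0.5),
        },
        couplings=[Coupling("ct", "X", "Y", form, spec["a"], spec["b"], noise_sd)],
        seed=seed,
    )
    return cfg, spec


def form_recovery(
    n_replicates: int = 200,
    noise_sd: float = 0.05,
    seed: int = 0,
    forms: tuple[str, ...] = ("linear", "logarithmic", "exponential", "power"),
    n: int | None = None,
    events_per_peak: int = 6246,
    rel_tol: float = 0.10,
) -> pd.DataFrame:
    """Replicate-level recovery of each generating form.

    For every form and replicate: simulate the benchmark cohort, summarise
    event medians, classify the pair, and record whether the generating
    form and switch label were recovered and whether both fitted
    coefficients are within ``rel_tol`` relative error of the truth.

    Returns one row per form with columns ``form_rate`` (fraction of
    replicates with correct form and label) and ``coeff_rate`` (fraction
    with both coefficients inside the tolerance).
    """
    rows = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 10_000)
    for form in forms:
        form_ok = 0
        coeff_ok = 0
        for rep in range(n_replicates):
            cfg, spec = _benchmark_config(
                form, noise_sd, n, int(base) + rep, events_per_peak
            )
            events, _ = generate_cohort(cfg)
            m = summarise_medians(events)["ct"]
            call = classify_relationship(m["X"], m["Y"])
            if call.best.form == form and call.switch_label == spec["label"]:
                form_ok += 1
            fit = call.fits.get(form)
            if fit is not None and (
                abs(fit.a - spec["a"]) <= rel_tol * abs(spec["a"])
                and abs(fit.b - spec["b"]) <= rel_tol * abs(spec["b"])
            ):
                coeff_ok += 1
        rows.append(
            {
                "form": form,
                "n_replicates": n_replicates,
                "n_samples": n if n is not None else FORM_BENCHMARKS[form]["n"],
                "noise_sd": noise_sd,
                "form_rate": form_ok / n_replicates,
                "coeff_rate": coeff_ok / n_replicates,
            }
        )
    return pd.DataFrame(rows)


def exponential_screen_improvement(
    n_replicates: int = 100,
    n: int = 99,
    noise_sd: float = 0.05,
    seed: int = 0,
    events_per_peak: int = 6246,
) -> float:
    """Fraction of replicates where the (x, ln y) correlation-matrix entry
    beats the raw (x, y) entry for an exponential-truth pair."""
    wins = 0
    base = np.random.default_rng(seed).integers(0, 2**31 - 10_000)
    for rep in range(n_replicates):
        cfg, _ = _benchmark_config("exponential", noise_sd, n, int(base) + rep,
                                   events_per_peak)
        events, _ = generate_cohort(cfg)
        m = summarise_medians(events)["ct"]
        cms = correlation_matrix_set(m, cell_type="ct")
        if abs(cms.r["x.lny"].loc["X", "Y"]) >= abs(cms.r["x.y"].loc["X", "Y"]):
            wins += 1
    return wins / n_replicates
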