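import numpy as np
import pandas as pd
import pytest

from pathscreen.simulate import CohortConfig, Coupling


def small_config(form: str, a: float, b: float, noise_sd: float, n: int,
                 seed: int, x_loc: float = 120.0, x_scale: float = 0.5,
                 events: int = 6246) -> CohortConfig:
    """Two-analyte single-cell-type cohort with one coupling of the given form."""
    return CohortConfig(
        cell_types=("ct",),
        n_samples={"ct": n},
        analytes=("X", "Y"),
        events_per_peak_mean=events,
        baseline={("ct", "X"): (x_loc, x_scale), ("ct", "Y"): (100.0, 0.5)},
        couplings=[Coupling("ct", "X", "Y", form, a, b, noise_sd)],
        seed=seed,
    )


# One coupling per model form (shared with the package's own calibration
# benchmarks so tests and validation studies agree on the truth).
from pathscreen.validate import FORM_BENCHMARKS as FORM_TRUTH  # noqa: E402

EXPECTED_LABEL = {form: spec["label"] for form, spec in FORM_TRUTH.items()}


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (4 cell types, 11 analytes) and its medians;
    generated once per session because it simulates ~30M events."""
    import pathscreen as ps

    events, truth = ps.generate_cohort(ps.default_config(seed=11))
    medians = ps.summarise_medians(events)
    return events, truth, medians


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def positive_matrix(rng):
    """Seeded 5-analyte, 40-sample positive expression matrix with some
    missing entries."""
    values = np.exp(rng.normal(4.5, 0.6, size=(40, 5)))
    values[rng.random(values.shape) < 0.05] = np.nan
    return pd.DataFrame(
        values,
        columns=list("ABCDE"),
        index=pd.Index([f"s{i}" for i in range(40)], name="sample_id"),
    )
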