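"""Seeded event-level cohort and agonist-titration simulators.

The generators emulate the structure of a restricted-dimensionality
flow-cytometry study of STING-pathway analytes in peripheral blood
mononuclear cells: four cell types with unequal sample counts, eleven
analytes summarised as positive median fluorescence intensities, and a
set of bivariate couplings between analytes of four functional forms
(linear, logarithmic, exponential, power).

Couplings act on the *latent* sample-level median scale, not per event:
downstream association analyses correlate per-sample medians, so the
generator's ground truth lives on the same scale the fitters see.  Noise
is added on the linearizing coordinate of each form (on y for linear and
logarithmic couplings, on ln y for exponential and power couplings) so
that recovered coefficients can be compared to the truth directly.

Each event cloud is log-normal around its latent median — fluorescence
intensities are positive and right-skewed, and the log-normal median
equals exp(mu), so the emitted events are centred where the truth table
says.  Event counts per peak are Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Coupling",
    "CohortConfig",
    "EventTable",
    "TruthTable",
    "generate_cohort",
    "generate_titration",
    "default_config",
    "CELL_TYPES",
    "ANALYTES",
    "SAMPLE_COUNTS",
    "EVENTS_PER_PEAK",
]

FORMS = ("linear", "logarithmic", "exponential", "power")

# Study design: four mononuclear cell types with the cohort's per-cell-type
# sample counts, eleven STING-pathway analytes, ~6246 events per peak.
CELL_TYPES = ("CD4_T", "CD8_T", "B", "monocyte")
SAMPLE_COUNTS = {"CD4_T": 115, "CD8_T": 99, "B": 108, "monocyte": 115}
ANALYTES = (
    "STING",
    "pSTING",
    "pTBK1",
    "pRelA",
    "IRF3",
    "NLRP3",
    "BDNF",
    "pAkt",
    "pULK1",
    "Traf6",
    "MyD88",
)
EVENTS_PER_PEAK = 6246

# Typical median-fluorescence locations (arbitrary units).  Values are
# invented but echo the qualitative cell-type differences reported for
# this pathway: B cells low in STING and IRF3, antigen-presenting cells
# (B, monocyte) lower in pRelA and IRF3 than T cells.
_BASE_LOCATION = {
    "STING": 180.0,
    "pSTING": 120.0,
    "pTBK1": 150.0,
    "pRelA": 90.0,
    "IRF3": 200.0,
    "NLRP3": 110.0,
    "BDNF": 140.0,
    "pAkt": 130.0,
    "pULK1": 100.0,
    "Traf6": 160.0,
    "MyD88": 170.0,
}
_CELLTYPE_ADJUST = {
    ("B", "STING"): 0.15,
    ("B", "IRF3"): 0.3,
    ("B", "pRelA"): 0.6,
    ("monocyte", "pRelA"): 0.6,
    ("monocyte", "IRF3"): 0.7,
}


@dataclass(frozen=True)
class Coupling:
    """A directed bivariate coupling between two analytes.

    Forms and their latent-scale equations (before noise):

    ==============  =====================
    linear          y = a*x + b
    logarithmic     y = a*ln(x) + b
    exponential     y = a*exp(b*x)
    power           y = a*x**b
    ==============  =====================

    ``noise_sd`` is the standard deviation of Gaussian noise added on the
    linearizing coordinate: on y for linear/logarithmic, on ln y for
    exponential/power (so y stays positive for those forms).
    """

    cell_type: str
    x_analyte: str
    y_analyte: str
    form: str
    a: float
    b: float
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if self.x_analyte == self.y_analyte:
            raise ValueError("coupling requires distinct x and y analytes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.form in ("exponential", "power") and self.a <= 0:
            raise ValueError(f"{self.form} coupling requires a > 0")

    def latent(self, x: np.ndarray, eps: np.ndarray) -> np.ndarray:
        """Evaluate y given latent x and linearized-scale noise draws."""
        if self.form == "linear":
            return self.a * x + self.b + eps
        if self.form == "logarithmic":
            return self.a * np.log(x) + self.b + eps
        if self.form == "exponential":
            return self.a * np.exp(self.b * x + eps)
        return self.a * np.power(x, self.b) * np.exp(eps)  # power


def _default_baseline() -> dict[tuple[str, str], tuple[float, float]]:
    baseline = {}
    for ct in CELL_TYPES:
        for an in ANALYTES:
            loc = _BASE_LOCATION[an] * _CELLTYPE_ADJUST.get((ct, an), 1.0)
            baseline[(ct, an)] = (loc, 0.5)
    return baseline


def _default_couplings(noise_sd: float = 0.05) -> list[Coupling]:
    """The study's four coupling motifs.

    Linear STING->BDNF/pAkt in T cells and monocytes (rheostat), logarithmic
    pSTING->BDNF/pAkt in B cells (on-switch), inverse-power pSTING->pTBK1 in
    every cell type (off-switch) and exponential pTBK1->pRelA in every cell
    type (on-switch).  Coefficients are chosen so each form's signal spans an
    O(1) range on its linearizing coordinate at the baseline MFI scales.
    """
    couplings: list[Coupling] = []
    for ct in ("CD4_T", "CD8_T", "monocyte"):
        couplings.append(Coupling(ct, "STING", "BDNF", "linear", 0.6, 30.0, noise_sd))
        couplings.append(Coupling(ct, "STING", "pAkt", "linear", 0.5, 40.0, noise_sd))
    couplings.append(Coupling("B", "pSTING", "BDNF", "logarithmic", 40.0, -50.0, noise_sd))
    couplings.append(Coupling("B", "pSTING", "pAkt", "logarithmic", 30.0, -20.0, noise_sd))
    for ct in CELL_TYPES:
        couplings.append(Coupling(ct, "pSTING", "pTBK1", "power", 2.0e5, -1.5, noise_sd))
        couplings.append(Coupling(ct, "pTBK1", "pRelA", "exponential", 50.0, 0.004, noise_sd))
    return couplings


@dataclass
class CohortConfig:
    """Full description of a simulated cohort.

    ``baseline`` maps (cell type, analyte) to (location, scale): the
    geometric-mean latent median in fluorescence units and the
    between-sample log-scale standard deviation.  ``event_log_sd`` is the
    within-peak log-scale spread of the event cloud around the latent
    median.  ``dropout`` optionally maps a cell type to sample ids excluded
    before any statistic, emulating viability-based exclusions.
    """

    cell_types: tuple[str, ...] = CELL_TYPES
    n_samples: dict[str, int] = field(default_factory=lambda: dict(SAMPLE_COUNTS))
    analytes: tuple[str, ...] = ANALYTES
    events_per_peak_mean: int = EVENTS_PER_PEAK
    baseline: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_baseline
    )
    couplings: list[Coupling] = field(default_factory=_default_couplings)
    event_log_sd: float = 0.25
    dropout: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for ct in self.cell_types:
            if ct not in self.n_samples:
                raise ValueError(f"no sample count for cell type {ct!r}")
            if self.n_samples[ct] < 4:
                raise ValueError("all n_samples must be >= 4")
        if self.events_per_peak_mean < 10:
            raise ValueError("events_per_peak_mean must be >= 10")
        for key, (loc, scale) in self.baseline.items():
            if loc <= 0:
                raise ValueError(f"baseline location must be > 0 for {key}")
            if scale < 0:
                raise ValueError(f"baseline scale must be >= 0 for {key}")
        for c in self.couplings:
            if c.x_analyte not in self.analytes or c.y_analyte not in self.analytes:
                raise ValueError(f"coupling references unknown analyte: {c}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Couplings form a directed graph per cell type; a cycle would make
        # the latent construction order-ill-defined.
        for ct in self.cell_types:
            edges = [
                (c.x_analyte, c.y_analyte)
                for c in self.couplings
                if c.cell_type == ct
            ]
            targets: dict[str, list[str]] = {}
            for x, y in edges:
                targets.setdefault(x, []).append(y)
            visiting: set[str] = set()
            done: set[str] = set()

            def visit(node: str) -> None:
                if node in done:
                    return
                if node in visiting:
                    raise ValueError(
                        f"coupling cycle among analytes in cell type {ct!r}"
                    )
                visiting.add(node)
                for nxt in targets.get(node, ()):
                    visit(nxt)
                visiting.discard(node)
                done.add(node)

            for node in list(targets):
                visit(node)


@dataclass
class EventTable:
    """Per-(cell type, sample, analyte) simulated fluorescence events.

    ``records`` is a DataFrame with columns cell_type, sample_id, analyte
    and an object column ``events`` holding a float array per peak.  All
    intensities are positive and keys are unique.
    """

    records: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Explode to long format (cell_type, sample_id, analyte, event_intensity)."""
        out = self.records.explode("events", ignore_index=True)
        out = out.rename(columns={"events": "event_intensity"})
        out["event_intensity"] = out["event_intensity"].astype(float)
        return out

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "EventTable":
        grouped = (
            long.groupby(["cell_type", "sample_id", "analyte"], sort=False)[
                "event_intensity"
            ]
            .apply(lambda s: np.asarray(s, dtype=float))
            .reset_index()
            .rename(columns={"event_intensity": "events"})
        )
        return cls(records=grouped)


@dataclass
class TruthTable:
    """Realised latent per-sample medians plus the coupling list used."""

    latents: pd.DataFrame  # columns: cell_type, sample_id, analyte, latent_median
    couplings: list[Coupling]

    def wide(self, cell_type: str) -> pd.DataFrame:
        sub = self.latents[self.latents["cell_type"] == cell_type]
        return sub.pivot(index="sample_id", columns="analyte", values="latent_median")


def _topological_order(analytes: tuple[str, ...], couplings: list[Coupling]) -> list[str]:
    # Declaration order of couplings defines evaluation order; analytes that
    # are never targets come first so every x is realised before its y.
    order = [a for a in analytes]
    targets = [c.y_analyte for c in couplings]
    roots = [a for a in order if a not in targets]
    return roots + [a for a in order if a in targets]


def _draw_latents(
    cfg: CohortConfig, cell_type: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent sample-level medians for one cell type, couplings applied."""
    couplings = [c for c in cfg.couplings if c.cell_type == cell_type]
    coupled = {c.y_analyte for c in couplings}
    latent = pd.DataFrame(index=pd.RangeIndex(n), columns=list(cfg.analytes), dtype=float)
    for an in cfg.analytes:
        if an in coupled:
            continue
        loc, scale = cfg.baseline[(cell_type, an)]
        latent[an] = np.exp(rng.normal(np.log(loc), scale, size=n))
    # Apply couplings in declaration order (config guarantees acyclicity).
    for c in couplings:
        x = latent[c.x_analyte].to_numpy()
        if np.any(~np.isfinite(x)):
            raise ValueError(f"coupling {c} evaluated before its source analyte")
        if c.form in ("logarithmic", "power") and np.any(x <= 0):
            raise ValueError(f"{c.form} coupling requires positive x")
        eps = rng.normal(0.0, c.noise_sd, size=n)
        y = c.latent(x, eps)
        # Nonpositive latents break the downstream ln transforms: resample
        # the offending noise draws up to 100 times, then give up.
        for _ in range(100):
            bad = y <= 0
            if not bad.any():
                break
            eps_new = rng.normal(0.0, c.noise_sd, size=int(bad.sum()))
            y = y.copy()
            y[bad] = c.latent(x[bad], eps_new)
        else:  # pragma: no cover - requires pathological config
            raise ValueError(
                f"coupling {c} produced nonpositive latents after 100 resamples"
            )
        latent[c.y_analyte] = y
    return latent


def generate_cohort(config: CohortConfig | None = None) -> tuple[EventTable, TruthTable]:
    """Generate a seeded event-level cohort and its ground truth.

    For each sample and analyte a latent median is drawn (couplings applied
    in declaration order on the latent scale), then a log-normal event cloud
    is emitted around it with a Poisson event count.  Identical config and
    seed give identical output.
    """
    cfg = config if config is not None else default_config()
    rng = np.random.default_rng(cfg.seed)
    rec_ct: list[str] = []
    rec_sample: list[str] = []
    rec_analyte: list[str] = []
    rec_events: list[np.ndarray] = []
    truth_rows: list[pd.DataFrame] = []
    for ct in cfg.cell_types:
        n = cfg.n_samples[ct]
        latent = _draw_latents(cfg, ct, n, rng)
        sample_ids = [f"{ct}_s{i:03d}" for i in range(n)]
        dropped = set(cfg.dropout.get(ct, ()))
        counts = rng.poisson(cfg.events_per_peak_mean, size=(n, len(cfg.analytes)))
        counts = np.maximum(counts, 1)
        total = int(counts.sum())
        # One vectorised draw for the whole cell type, then split per peak.
        all_noise = rng.normal(0.0, cfg.event_log_sd, size=total)
        offsets = np.concatenate([[0], np.cumsum(counts.ravel())])
        flat = 0
        for i, sid in enumerate(sample_ids):
            if sid in dropped:
                flat += len(cfg.analytes)
                continue
            for j, an in enumerate(cfg.analytes):
                k = flat
                flat += 1
                lo, hi = offsets[k], offsets[k + 1]
                med = latent.iloc[i, j]
                events = med * np.exp(all_noise[lo:hi])
                rec_ct.append(ct)
                rec_sample.append(sid)
                rec_analyte.append(an)
                rec_events.append(events)
        truth = latent.copy()
        truth.index = sample_ids
        truth = truth[~truth.index.isin(dropped)]
        truth = truth.rename_axis("sample_id").reset_index().melt(
            id_vars="sample_id", var_name="analyte", value_name="latent_median"
        )
        truth.insert(0, "cell_type", ct)
        truth_rows.append(truth)
    records = pd.DataFrame(
        {
            "cell_type": rec_ct,
            "sample_id": rec_sample,
            "analyte": rec_analyte,
            "events": rec_events,
        }
    )
    latents = pd.concat(truth_rows, ignore_index=True)
    return EventTable(records), TruthTable(latents, list(cfg.couplings))


DEFAULT_DOSES_UM = (0.0, 1.0 / 625, 1.0 / 125, 1.0 / 25, 1.0 / 5, 1.0)
"""Agonist titration: 0 plus five 5-fold dilutions from 1 micromolar."""


def default_titration_couplings(noise_sd: float = 0.05) -> list[Coupling]:
    """Short-term in-vitro couplings: agonist-driven pSTING feeds pTBK1
    logarithmically (on-switch) and pTBK1 feeds pRelA exponentially."""
    return [
        Coupling("PBMC", "pSTING", "pTBK1", "logarithmic", 60.0, -120.0, noise_sd),
        Coupling("PBMC", "pTBK1", "pRelA", "exponential", 40.0, 0.006, noise_sd),
    ]


def generate_titration(
    donors: int = 6,
    doses: tuple[float, ...] = DEFAULT_DOSES_UM,
    couplings: list[Coupling] | None = None,
    seed: int = 0,
    root_analyte: str = "pSTING",
    root_base: float = 60.0,
    root_gain: float = 400.0,
    root_ec50: float = 0.05,
    donor_log_sd: float = 0.1,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a STING-agonist dose titration across donors.

    Dose drives the root analyte through a strictly increasing saturating
    response ``base + gain * dose / (dose + ec50)`` scaled by a log-normal
    donor effect; downstream analytes follow ``couplings``.  Returns a
    donor-by-dose expression matrix (MultiIndex rows) and the truth table.
    The default design is 6 donors x 6 dose levels (0 plus five 5-fold
    dilutions from 1 uM).
    """
    if couplings is None:
        couplings = default_titration_couplings()
    if not couplings:
        raise ValueError("titration requires at least one coupling")
    doses = tuple(float(d) for d in doses)
    if len(doses) < 2:
        raise ValueError("at least 2 dose levels required")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be nonnegative")
    rng = np.random.default_rng(seed)
    analytes = [root_analyte]
    for c in couplings:
        for an in (c.x_analyte, c.y_analyte):
            if an not in analytes:
                analytes.append(an)
    index = pd.MultiIndex.from_product(
        [[f"donor{i + 1}" for i in range(donors)], doses], names=["donor", "dose_uM"]
    )
    donor_effect = np.exp(rng.normal(0.0, donor_log_sd, size=donors))
    rows = []
    for i in range(donors):
        for d in doses:
            stim = root_base + root_gain * d / (d + root_ec50)
            root = stim * donor_effect[i] * np.exp(rng.normal(0.0, noise_sd))
            row = {root_analyte: root}
            for c in couplings:
                x = np.asarray([row[c.x_analyte]])
                y = c.latent(x, rng.normal(0.0, c.noise_sd, size=1))
                if y[0] <= 0:
                    for _ in range(100):
                        y = c.latent(x, rng.normal(0.0, c.noise_sd, size=1))
                        if y[0] > 0:
                            break
                    else:  # pragma: no cover
                        raise ValueError(f"coupling {c} produced nonpositive latent")
                row[c.y_analyte] = float(y[0])
            rows.append(row)
    matrix = pd.DataFrame(rows, index=index, columns=analytes)
    matrix.columns.name = "analyte"
    truth = matrix.stack().rename("latent_median").reset_index()
    truth.insert(0, "cell_type", "PBMC")
    truth["sample_id"] = (
        truth["donor"].astype(str) + "@" + truth["dose_uM"].astype(str)
    )
    truth = truth[["cell_type", "sample_id", "analyte", "latent_median"]]
    return matrix, TruthTable(truth, list(couplings))


def default_config(seed: int = 0, noise_sd: float = 0.05, **overrides) -> CohortConfig:
    """The study's default cohort: 4 cell types (n = 115/99/108/115), 11
    analytes, ~6246 events per peak, and the four coupling motifs."""
    cfg = CohortConfig(seed=seed, couplings=_default_couplings(noise_sd))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
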