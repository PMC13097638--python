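import numpy as np
import pandas as pd
import pytest

import pathscreen as ps
from pathscreen.simulate import CohortConfig, Coupling, DEFAULT_DOSES_UM

from _oracles import pearson_oracle
from conftest import small_config


class TestCohortConfig:
    def test_default_design_counts(self, default_cohort):
        """Default cohort matches the study design: 115/99/108/115 samples."""
        events, truth, medians = default_cohort
        counts = {ct: len(m) for ct, m in medians.items()}
        assert counts == {"CD4_T": 115, "CD8_T": 99, "B": 108, "monocyte": 115}

    def test_coupling_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            CohortConfig(
                cell_types=("ct",),
                n_samples={"ct": 10},
                analytes=("X", "Y"),
                baseline={("ct", "X"): (100.0, 0.5), ("ct", "Y"): (100.0, 0.5)},
                couplings=[
                    Coupling("ct", "X", "Y", "linear", 1.0, 0.0),
                    Coupling("ct", "Y", "X", "linear", 1.0, 0.0),
                ],
                seed=0,
            )

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(n_samples={"ct": 3}), "n_samples"),
            (dict(events_per_peak_mean=5), "events_per_peak"),
            (dict(baseline={("ct", "X"): (-1.0, 0.5), ("ct", "Y"): (1.0, 0.5)}),
             "location"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs, match):
        base = dict(
            cell_types=("ct",),
            n_samples={"ct": 10},
            analytes=("X", "Y"),
            baseline={("ct", "X"): (100.0, 0.5), ("ct", "Y"): (100.0, 0.5)},
            couplings=[],
            seed=0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            CohortConfig(**base)

    def test_coupling_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            Coupling("ct", "X", "X", "linear", 1.0, 0.0)
        with pytest.raises(ValueError, match="form"):
            Coupling("ct", "X", "Y", "quadratic", 1.0, 0.0)
        with pytest.raises(ValueError, match="a > 0"):
            Coupling("ct", "X", "Y", "exponential", -2.0, 0.1)


class TestGenerateCohort:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        """Equal config + seed gives byte-identical serialized tables."""
        from pathscreen.tables import write_event_table, write_truth_table

        cfg = small_config("linear", 0.6, 30.0, 0.05, 12, seed=7, events=50)
        paths = []
        for tag in ("a", "b"):
            ev, tr = ps.generate_cohort(cfg)
            pe = write_event_table(ev, tmp_path / f"ev_{tag}.csv")
            pt = write_truth_table(tr, tmp_path / f"tr_{tag}.tsv")
            paths.append((pe.read_bytes(), pt.read_bytes()))
        assert paths[0] == paths[1]

    def test_all_intensities_positive_and_keys_unique(self):
        cfg = small_config("power", 2e5, -1.5, 0.05, 10, seed=5, events=40)
        ev, _ = ps.generate_cohort(cfg)
        assert all((np.asarray(e) > 0).all() for e in ev.records["events"])
        keys = ev.records[["cell_type", "sample_id", "analyte"]]
        assert not keys.duplicated().any()

    def test_exponential_coupling_linearizes_on_truth(self):
        """With an exponential coupling the latent medians are near-perfectly
        linear on (x, ln y); expected bound from the direct Pearson formula
        on the truth table."""
        cfg = CohortConfig(
            cell_types=("ct",),
            n_samples={"ct": 100},
            analytes=("X", "Y"),
            events_per_peak_mean=20,
            baseline={("ct", "X"): (2.0, 0.5), ("ct", "Y"): (1.0, 0.5)},
            couplings=[Coupling("ct", "X", "Y", "exponential", 2.0, 0.5, 0.01)],
            seed=13,
        )
        _, truth = ps.generate_cohort(cfg)
        wide = truth.wide("ct")
        r = pearson_oracle(list(wide["X"]), list(np.log(wide["Y"])))
        assert r >= 0.95

    def test_event_median_converges_to_latent(self):
        """Median of ~6246 emitted events tracks the latent median to <=2%."""
        for seed in (1, 2, 3):
            cfg = small_config("linear", 0.6, 30.0, 0.05, 6, seed=seed)
            ev, truth = ps.generate_cohort(cfg)
            med = ps.summarise_medians(ev)["ct"]
            latent = truth.wide("ct")[med.columns].loc[med.index]
            rel = np.abs(med - latent) / latent
            assert float(rel.max().max()) <= 0.02

    def test_dropout_mask_removes_samples(self):
        cfg = small_config("linear", 0.6, 30.0, 0.05, 10, seed=3, events=40)
        from dataclasses import replace

        cfg = replace(cfg, dropout={"ct": ["ct_s000", "ct_s004"]})
        ev, truth = ps.generate_cohort(cfg)
        ids = set(ev.records["sample_id"])
        assert "ct_s000" not in ids and "ct_s004" not in ids
        assert len(ids) == 8
        assert set(truth.latents["sample_id"]) == ids


class TestGenerateTitration:
    def test_default_design_6_donors_6_doses(self):
        matrix, truth = ps.generate_titration(seed=4)
        assert matrix.shape[0] == 36
        assert list(matrix.index.names) == ["donor", "dose_uM"]
        doses = sorted(set(matrix.index.get_level_values("dose_uM")))
        assert doses == sorted(DEFAULT_DOSES_UM)
        # five 5-fold dilutions from 1 uM plus zero
        nonzero = sorted(d for d in doses if d > 0)
        for lo, hi in zip(nonzero, nonzero[1:]):
            assert hi / lo == pytest.approx(5.0)
        assert max(doses) == 1.0 and min(doses) == 0.0

    def test_zero_noise_root_strictly_monotone_in_dose(self):
        couplings = ps.simulate.default_titration_couplings(noise_sd=0.0)
        matrix, _ = ps.generate_titration(
            couplings=couplings, seed=9, noise_sd=0.0
        )
        for _, grp in matrix.groupby(level="donor"):
            root = grp.sort_index(level="dose_uM")["pSTING"].to_numpy()
            assert np.all(np.diff(root) > 0)

    def test_logarithmic_coupling_slope_recovered(self):
        """OLS of y on ln x over the 36 titration rows recovers the
        logarithmic slope within 10%; oracle is the closed-form OLS fit."""
        from _oracles import ols_oracle

        coup = [Coupling("PBMC", "pSTING", "pTBK1", "logarithmic", 3.0, 1.0, 0.05)]
        matrix, _ = ps.generate_titration(couplings=coup, seed=21)
        assert len(matrix) == 36
        _, slope = ols_oracle(np.log(matrix["pSTING"]), matrix["pTBK1"])
        assert slope == pytest.approx(3.0, rel=0.10)

    def test_empty_couplings_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            ps.generate_titration(couplings=[], seed=0)

    def test_invalid_doses_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            ps.generate_titration(doses=(1.0,), seed=0)
        with pytest.raises(ValueError, match="nonneg"):
            ps.generate_titration(doses=(-0.1, 1.0), seed=0)
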