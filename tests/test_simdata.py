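"""Cohort and intensity generator: distributional targets and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvsmoke.simdata import (
    SimulationConfig, calibrate_intercept, focal_region_panel,
    simulate_cohort, simulate_intensities, _mu_covariate_part,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_subjects": -1},
        {"carrier_frequency": 0.0},
        {"carrier_frequency": 1.0},
        {"noise_sd_lrr": -0.1},
        {"dependence": 1.0},
        {"alpha": 0.0},
        {"n_components": 3, "component_frequencies": [0.5, 0.5]},
        {"n_components": 2, "component_frequencies": [0.5, 1.5]},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_defaults_match_study_conditions(self):
        cfg = SimulationConfig()
        assert cfg.alpha == 0.05
        assert cfg.n_permutations == 10_000


class TestSimulateCohort:
    def test_empty_cohort(self):
        cfg = SimulationConfig(n_subjects=0, n_components=5)
        cohort = simulate_cohort(cfg)
        assert len(cohort.subjects) == 0
        assert cohort.copy_number.shape == (0, 6)

    def test_bit_reproducible(self):
        cfg = SimulationConfig(n_subjects=200, n_components=5, seed=7)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        np.testing.assert_array_equal(a.copy_number, b.copy_number)

    def test_cohort_hits_demographic_targets(self):
        """Mean pack-years within 2 SE of 38.1, current smokers of 80.5%."""
        cfg = SimulationConfig(n_subjects=2889, seed=1)
        cohort = simulate_cohort(cfg)
        py = cohort.subjects["pack_years"]
        se_py = py.std() / np.sqrt(len(py))
        assert abs(py.mean() - 38.1) < 2 * se_py
        cur = cohort.subjects["current_smoker"].mean()
        se_cur = np.sqrt(0.805 * 0.195 / len(py))
        assert abs(cur - 0.805) < 2 * se_cur

    def test_inclusion_criteria_and_ranges(self, small_cohort):
        _, cohort = small_cohort
        s = cohort.subjects
        assert (s["pack_years"] >= 10).all()
        assert s["age_years"].between(45, 90).all()
        assert s["admixture"].between(0, 1).all()
        assert (s["cigs_per_day"] > 0).all()

    def test_zero_noise_phenotype_is_deterministic_mu(self):
        cfg = SimulationConfig(n_subjects=300, sigma_log10_pack_years=0.0,
                               effect_beta=0.0, seed=3, n_components=2)
        cohort = simulate_cohort(cfg)
        male = (cohort.subjects["sex"] == "M").to_numpy()
        mu = calibrate_intercept(cfg) + _mu_covariate_part(
            cfg, male, cohort.subjects["age_years"].to_numpy(),
            cohort.subjects["admixture"].to_numpy())
        np.testing.assert_allclose(
            np.log10(cohort.subjects["pack_years"]), mu, rtol=0, atol=1e-12)

    def test_pack_years_ties_to_cigs_per_day(self, small_cohort):
        """pack_years = (cigs_per_day / 20) * smoking-years with plausible years."""
        _, cohort = small_cohort
        sy = 20 * cohort.subjects["pack_years"] / cohort.subjects["cigs_per_day"]
        assert (sy <= cohort.subjects["age_years"] - 14 + 1e-9).all()
        assert (sy >= 1.0 - 1e-9).all()

    def test_marginal_carrier_frequencies(self):
        """Each component's realized frequency in the binomial 99% CI."""
        freqs = np.array([0.02, 0.05, 0.10])
        cfg = SimulationConfig(n_subjects=10_000, carrier_frequency=0.027,
                               n_components=3, component_frequencies=freqs,
                               seed=5)
        cohort = simulate_cohort(cfg)
        for j, f in enumerate(np.concatenate([[0.027], freqs])):
            k = int((cohort.copy_number[:, j] != 2).sum())
            lo, hi = stats.binom.interval(0.99, 10_000, f)
            assert lo <= k <= hi

    def test_independent_components_uncorrelated(self):
        cfg = SimulationConfig(n_subjects=10_000, dependence=0.0,
                               n_components=5, seed=9)
        cohort = simulate_cohort(cfg)
        carrier = (cohort.copy_number != 2).astype(float)
        corr = np.corrcoef(carrier.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_dependence_induces_positive_correlation(self):
        cfg = SimulationConfig(n_subjects=10_000, dependence=0.5,
                               carrier_frequency=0.1, n_components=5,
                               component_frequencies=np.full(5, 0.1), seed=9)
        cohort = simulate_cohort(cfg)
        carrier = (cohort.copy_number != 2).astype(float)
        corr = np.corrcoef(carrier.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.mean(off) > 0.1


class TestSimulateIntensities:
    def test_zero_noise_diploid(self):
        cfg = SimulationConfig(n_subjects=10, noise_sd_lrr=0.0,
                               noise_sd_baf=0.0, seed=2, n_components=0)
        cn = np.full(10, 2)
        panel = simulate_intensities([f"S{i}" for i in range(10)], cn,
                                     ("chr1", 1000, 5000), 8, cfg)
        assert np.all(panel.lrr == 0.0)
        assert set(np.unique(panel.baf)) <= {0.0, 0.5, 1.0}

    def test_deletion_lrr_mean(self):
        """500 carriers: mean within-deletion LRR within 3 SE of -0.66."""
        cfg = SimulationConfig(n_subjects=500, seed=4, n_components=0)
        cn = np.full(500, 1)
        panel = simulate_intensities([f"S{i}" for i in range(500)], cn,
                                     ("chr3", 6_194_430, 6_214_264), 20, cfg)
        vals = panel.lrr.ravel()
        se = cfg.noise_sd_lrr / np.sqrt(vals.size)
        assert abs(vals.mean() - (-0.66)) < 3 * se

    def test_heterozygous_band_lost_in_carriers(self):
        """Mid-range BAF mass ~0 for hemizygous carriers, ~het rate for diploids."""
        cfg = SimulationConfig(n_subjects=400, seed=6, n_components=0)
        ids = [f"S{i}" for i in range(400)]
        region = ("chr3", 6_194_430, 6_214_264)
        hemi = simulate_intensities(ids, np.full(400, 1), region, 20, cfg)
        dipl = simulate_intensities(ids, np.full(400, 2), region, 20, cfg)
        frac_hemi = np.mean((hemi.baf > 0.25) & (hemi.baf < 0.75))
        frac_dipl = np.mean((dipl.baf > 0.25) & (dipl.baf < 0.75))
        assert frac_hemi < 0.01
        assert abs(frac_dipl - 0.5) < 0.05      # het rate at allele freq 0.5

    def test_homozygous_deletion_baf_uniform(self):
        cfg = SimulationConfig(n_subjects=300, seed=8, n_components=0)
        panel = simulate_intensities([f"S{i}" for i in range(300)],
                                     np.full(300, 0),
                                     ("chr1", 1, 100_000), 10, cfg)
        assert abs(panel.lrr.mean() - (-3.5)) < 0.05
        # uniform BAF: roughly half the mass in the central band
        assert abs(np.mean((panel.baf > 0.25) & (panel.baf < 0.75)) - 0.5) < 0.05

    def test_shape_mismatch_rejected(self):
        cfg = SimulationConfig(n_subjects=5, seed=1, n_components=0)
        with pytest.raises(ValueError, match="subjects"):
            simulate_intensities(["a", "b"], np.full(3, 2),
                                 ("chr1", 1, 1000), 4, cfg)

    def test_panel_reproducible_and_valid(self, small_cohort):
        cfg, cohort = small_cohort
        p1 = focal_region_panel(cohort, cfg)
        p2 = focal_region_panel(cohort, cfg)
        np.testing.assert_array_equal(p1.lrr, p2.lrr)
        np.testing.assert_array_equal(p1.baf, p2.baf)
        assert np.all(np.diff(p1.positions) > 0)
        assert p1.baf.min() >= 0 and p1.baf.max() <= 1
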