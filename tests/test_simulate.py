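"""Synthetic-cohort generator: determinism, calibration and ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glyconet import simulate as sim
from glyconet.datatypes import ConfigurationError
from glyconet.ggm import ShrinkagePartialCorrelation

from conftest import small_sim_config


class TestGenerateCohort:
    def test_sizes_and_groups(self):
        cohort = sim.generate_cohort(sim.CohortConfig(n_cases=188, n_controls=181, seed=1))
        assert len(cohort) == 369
        assert (cohort["diabetes"] == 1).sum() == 188

    def test_minimal_cohort(self):
        cohort = sim.generate_cohort(sim.CohortConfig(n_cases=1, n_controls=1, seed=99))
        assert len(cohort) == 2
        assert sorted(cohort["diabetes"]) == [0, 1]

    def test_byte_identical_determinism(self, tmp_path):
        cfg = sim.CohortConfig(n_cases=40, n_controls=40, seed=7)
        paths = []
        for k in range(2):
            path = tmp_path / f"cohort{k}.tsv"
            sim.generate_cohort(cfg).to_csv(path, sep="\t")
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_seed_changes_output(self):
        a = sim.generate_cohort(sim.CohortConfig(n_cases=30, n_controls=30, seed=1))
        b = sim.generate_cohort(sim.CohortConfig(n_cases=30, n_controls=30, seed=2))
        assert not a.equals(b)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_cases": 0},
            {"n_controls": -1},
            {"ethnicity_probs_case": (0.5, 0.5, 0.5, 0.5)},
            {"female_prob_case": 1.5},
            {"availability": {"urine": 0.0}},
        ],
    )
    def test_invalid_config(self, bad):
        with pytest.raises(ConfigurationError):
            sim.generate_cohort(sim.CohortConfig(**bad))

    def test_covariates_and_availability_columns(self, cohort369):
        assert set(cohort369["ethnicity"]) <= {"Arab", "South Asian", "Filipino", "Other"}
        for fluid in ("saliva", "plasma", "urine"):
            assert cohort369[f"has_{fluid}"].dtype == bool
        # osmolality present exactly where the fluid sample exists
        assert (
            cohort369["osmolality_urine"].notna() == cohort369["has_urine"]
        ).all()


class TestNetworkTruth:
    def test_single_edge_support(self):
        # find a seed giving exactly one edge on p=3, then check the implied
        # partial correlations are nonzero only on that pair
        for seed in range(50):
            truth = sim.generate_network_truth(3, 0.34, (0.3, 0.5), seed=seed)
            if len(truth.edges) == 1:
                break
        else:
            pytest.fail("no single-edge draw found")
        (i, j) = truth.edges[0]
        off = np.abs(truth.pcor[np.triu_indices(3, 1)])
        assert truth.pcor[i, j] != 0
        assert (off > 0).sum() == 1

    def test_edge_count_and_positive_definiteness(self):
        p, density = 50, 0.04
        truth = sim.generate_network_truth(p, density, (0.3, 0.45), seed=5)
        n_pairs = p * (p - 1) // 2
        mean, sd = density * n_pairs, np.sqrt(n_pairs * density * (1 - density))
        assert mean - 3 * sd <= len(truth.edges) <= mean + 3 * sd
        assert np.linalg.eigvalsh(truth.precision).min() > 0
        # recorded edge set is exactly the off-diagonal support
        iu = np.triu_indices(p, 1)
        support = {(i, j) for i, j in zip(*iu) if truth.precision[i, j] != 0}
        assert support == truth.edge_set()

    def test_zero_density_gives_diagonal(self):
        truth = sim.generate_network_truth(10, 0.0, seed=0)
        off = truth.pcor[np.triu_indices(10, 1)]
        assert np.all(off == 0)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            sim.generate_network_truth(2, 0.1)
        with pytest.raises(ConfigurationError):
            sim.generate_network_truth(10, 0.6)
        with pytest.raises(ConfigurationError):
            sim.generate_network_truth(10, 0.1, (0.0, 1.2))

    def test_pcor_convergence_to_truth(self):
        """Empirical partial correlations of noise-free latent data converge."""
        truth = sim.generate_network_truth(20, 0.1, (0.3, 0.6), seed=4)
        chol = np.linalg.cholesky(truth.correlation())
        X = np.random.default_rng(7).standard_normal((5000, 20)) @ chol.T
        est = ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)
        assert np.abs(est.pcor_ - truth.pcor).max() < 0.05


class TestGlycaemicMarkers:
    def test_glucosuria_prevalence_calibration(self):
        cohort = sim.generate_cohort(sim.CohortConfig(seed=3))
        lat = sim.generate_glycaemic_markers(cohort, seed=3)
        cases = cohort["diabetes"] == 1
        n_cases = int(cases.sum())
        rate = 66 / 188
        count = int(lat.glucosuria[cases].dropna().sum())
        sd = np.sqrt(n_cases * rate * (1 - rate))
        assert abs(count - n_cases * rate) < 3 * sd
        # controls: prevalence target 2/181
        n_ctrl_pos = int(lat.glucosuria[~cases].dropna().sum())
        assert n_ctrl_pos <= 8

    def test_no_glucosuria_when_threshold_infinite(self):
        cohort = sim.generate_cohort(sim.CohortConfig(seed=1))
        params = sim.MarkerConfig(case_shift_acute=0.0, glucosuria_threshold=np.inf)
        lat = sim.generate_glycaemic_markers(cohort, params, seed=1)
        assert lat.glucosuria.dropna().sum() == 0

    def test_short_term_latent_lowers_ag(self):
        cfg = sim.CohortConfig(n_cases=1000, n_controls=1000, seed=5)
        cohort = sim.generate_cohort(cfg)
        lat = sim.generate_glycaemic_markers(cohort, seed=5)
        rho = stats.spearmanr(lat.latents["short_term"], lat.ag_log_abundance).statistic
        assert rho < -0.3

    def test_hba1c_tracks_long_term_latent(self):
        cohort = sim.generate_cohort(sim.CohortConfig(seed=8))
        lat = sim.generate_glycaemic_markers(cohort, seed=8)
        r = np.corrcoef(lat.latents["long_term"], lat.hba1c)[0, 1]
        assert r > 0.7

    def test_markers_missing_without_urine(self):
        cohort = sim.generate_cohort(sim.CohortConfig(seed=2))
        lat = sim.generate_glycaemic_markers(cohort, seed=2)
        assert lat.glucosuria[~cohort["has_urine"]].isna().all()


class TestFluidMatrices:
    def test_qc_replicate_cv_matches_target(self):
        for fluid, target in (("saliva", 0.153), ("plasma", 0.158), ("urine", 0.098)):
            cv = sim.qc_replicate_cv(target, n_replicates=356, n_measures=877, seed=1)
            assert abs(cv.median() - target) < 0.02

    def test_censoring_disabled_at_zero_quantile(self):
        cfg = small_sim_config(seed=3)
        cfg.noise.censor_quantile = 0.0
        st = sim.simulate_study(cfg, seed=3)
        for fluid, fm in st.fluids.items():
            has = st.cohort[f"has_{fluid}"]
            sub = fm.data.loc[has]
            if fluid == "urine":
                sub = sub.drop(columns=[cfg.panel.glucose_measure])
            assert not sub.isna().any().any()

    def test_censoring_monotone_in_quantile(self):
        counts = []
        for q in (0.05, 0.15, 0.30):
            cfg = small_sim_config(seed=4)
            cfg.noise.censor_quantile = q
            st = sim.simulate_study(cfg, seed=4)
            counts.append(
                pd.concat([fm.data.isna().sum() for fm in st.fluids.values()])
            )
        assert (counts[1] >= counts[0]).all()
        assert (counts[2] >= counts[1]).all()

    def test_noise_free_effect_is_exact(self):
        """With noise, batch and censoring off, a +1 SD diabetes effect shifts
        the log intensity of exactly the affected cases by exactly 1."""
        cfg = small_sim_config(seed=6, edge_density=0.0)
        cfg.noise.cv_target = {f: 0.0 for f in cfg.noise.cv_target}
        cfg.noise.batch_sd = 0.0
        cfg.noise.censor_quantile = 0.0
        p = cfg.panel.total
        base = sim.EffectTruth.zeros(p)
        bumped = sim.EffectTruth.zeros(p)
        bumped.diabetes[5] = 1.0  # a saliva measure
        st0 = sim.simulate_study(cfg, seed=6, effects=base)
        st1 = sim.simulate_study(cfg, seed=6, effects=bumped)
        measure = st0.measure_index[5]
        has = st0.cohort["has_saliva"]
        delta = (
            np.log(st1.fluids["saliva"].data[measure])
            - np.log(st0.fluids["saliva"].data[measure])
        )[has]
        dm = st0.cohort.loc[has, "diabetes"].astype(float)
        assert np.allclose(delta, dm, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        cfg = small_sim_config(seed=1)
        truth = sim.generate_network_truth(10, 0.1, seed=0)
        with pytest.raises(sim.GenerationError):
            sim.simulate_study(cfg, seed=1, truth=truth)

    def test_study_determinism(self):
        a = sim.simulate_study(small_sim_config(seed=9), seed=9)
        b = sim.simulate_study(small_sim_config(seed=9), seed=9)
        for fluid in a.fluids:
            pd.testing.assert_frame_equal(a.fluids[fluid].data, b.fluids[fluid].data)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)

    def test_duplicate_groups_correlate(self):
        cfg = small_sim_config(seed=12, duplication=True)
        st = sim.simulate_study(cfg, seed=12)
        assert st.duplicate_groups
        group = st.duplicate_groups[0]
        log = np.log(
            pd.concat([fm.data for fm in st.fluids.values()], axis=1)[group]
        )
        r = log.corr().to_numpy()[np.triu_indices(len(group), 1)]
        assert (r > 0.4).all()

    def test_missing_fluid_rows_fully_missing(self, small_study):
        for fluid, fm in small_study.fluids.items():
            absent = ~small_study.cohort[f"has_{fluid}"]
            assert fm.data.loc[absent].isna().all().all()


def test_write_study_round_trip(tmp_path, small_study):
    sim.write_study(small_study, tmp_path)
    for name in (
        "phenotypes.tsv",
        "fluid_saliva.tsv",
        "fluid_plasma.tsv",
        "fluid_urine.tsv",
        "annotation.tsv",
        "truth_edges.tsv",
        "truth_effects.tsv",
        "config.yaml",
    ):
        assert (tmp_path / name).exists()
    loaded = pd.read_csv(tmp_path / "fluid_urine.tsv", sep="\t", index_col=0)
    orig = small_study.fluids["urine"].data
    assert loaded.shape == orig.shape
    assert loaded.isna().sum().sum() == orig.isna().sum().sum()
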