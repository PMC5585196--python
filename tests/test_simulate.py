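import numpy as np
import pandas as pd
import pytest

from inph_rsfc import denoise
from inph_rsfc.atlas import roi_average
from inph_rsfc.errors import InvalidConfigError, InvalidInputError
from inph_rsfc.simulate import (
    SimConfig,
    SubjectSpec,
    build_target_correlation,
    clinical_table,
    default_cohort_specs,
    simulate_cohort,
    simulate_subject,
    voxel_fixture,
    write_cohort,
    read_cohort,
)


class TestSubjectSpec:
    def test_hc_must_be_asymptomatic(self):
        with pytest.raises(InvalidInputError):
            SubjectSpec("x", "HC", gs_gait=1)

    def test_score_range_enforced(self):
        with pytest.raises(InvalidInputError):
            SubjectSpec("x", "iNPH", gs_gait=5)

    def test_gs_max(self):
        s = SubjectSpec("x", "iNPH", gs_gait=1, gs_cognition=3, gs_urinary=2)
        assert s.gs_max == 3


class TestTargetCorrelation:
    def test_healthy_homotopic_is_rho_homo(self, rois6):
        cfg = SimConfig(n_rois=6, rho_homo=0.55, rho_intra=0.0)
        target, _ = build_target_correlation(SubjectSpec("h", "HC"), cfg, rois6)
        for i, j in rois6.homotopic_pairs():
            assert target[i, j] == pytest.approx(0.55, abs=1e-9)

    def test_full_attenuation_zeroes_homotopic(self, rois6):
        cfg = SimConfig(n_rois=6, kappa=1.0, rho_intra=0.0)
        spec = SubjectSpec("p", "iNPH", gs_gait=4)
        target, prov = build_target_correlation(spec, cfg, rois6)
        # before repair the homotopic entry is exactly 0; the repaired
        # matrix may perturb it by at most the eigenvalue clipping
        assert prov["rho_homotopic"] == 0.0
        for i, j in rois6.homotopic_pairs():
            assert abs(target[i, j]) < 1e-6

    def test_plug_in_attenuation_arithmetic(self, rois6):
        cfg = SimConfig(n_rois=6, kappa=0.5, rho_homo=0.6, rho_intra=0.0)
        spec = SubjectSpec("p", "iNPH", gs_cognition=2)
        _, prov = build_target_correlation(spec, cfg, rois6)
        assert prov["rho_homotopic"] == pytest.approx(0.45, abs=1e-12)

    def test_symmetric_unit_diagonal_positive_definite(self, aal90):
        cfg = SimConfig()
        spec = SubjectSpec("p", "iNPH", gs_gait=3)
        target, _ = build_target_correlation(spec, cfg, aal90)
        assert np.allclose(target, target.T)
        assert np.allclose(np.diag(target), 1.0)
        assert np.linalg.eigvalsh(target).min() > 0

    def test_kappa_monotone_in_homotopic_strength(self, aal90):
        spec = SubjectSpec("p", "iNPH", gs_gait=2)
        prev = None
        for kappa in (0.0, 0.3, 0.6, 0.9):
            _, prov = build_target_correlation(
                spec, SimConfig(kappa=kappa), aal90
            )
            if prev is not None:
                assert prov["rho_homotopic"] <= prev
            prev = prov["rho_homotopic"]

    def test_invalid_parameters_rejected(self, rois6):
        with pytest.raises(InvalidConfigError):
            build_target_correlation(
                SubjectSpec("h", "HC"), SimConfig(n_rois=6, kappa=1.5), rois6
            )
        with pytest.raises(InvalidConfigError):
            build_target_correlation(
                SubjectSpec("h", "HC"), SimConfig(n_rois=6, rho_homo=1.0), rois6
            )


class TestSimulateSubject:
    def test_long_run_recovers_target_correlation(self, rois6):
        cfg = SimConfig(
            n_rois=6, n_volumes=20000, confound_loading=0.0, noise_sd=0.0, seed=5
        )
        spec = SubjectSpec("h", "HC")
        target, _ = build_target_correlation(spec, cfg, rois6)
        ts, _ = simulate_subject(spec, cfg, rois6)
        sample = np.corrcoef(ts.to_numpy().T)
        assert np.max(np.abs(sample - target)) < 0.03

    def test_same_seed_bitwise_identical(self, rois6):
        cfg = SimConfig(n_rois=6, n_volumes=40, seed=9)
        spec = SubjectSpec("p", "iNPH", gs_gait=2)
        ts1, cf1 = simulate_subject(spec, cfg, rois6)
        ts2, cf2 = simulate_subject(spec, cfg, rois6)
        assert ts1.equals(ts2) and cf1.equals(cf2)

    def test_confound_loading_inflates_raw_correlation(self, rois6):
        spec = SubjectSpec("h", "HC")
        base = SimConfig(n_rois=6, n_volumes=500, confound_loading=0.0, seed=3)
        loaded = SimConfig(n_rois=6, n_volumes=500, confound_loading=0.8, seed=3)
        def mean_offdiag(cfg):
            ts, _ = simulate_subject(spec, cfg, rois6)
            r = np.corrcoef(ts.to_numpy().T)
            return r[np.triu_indices(6, 1)].mean()
        assert mean_offdiag(loaded) > mean_offdiag(base)

    def test_confound_table_has_eight_channels(self, rois6):
        cfg = SimConfig(n_rois=6, n_volumes=40)
        _, cf = simulate_subject(SubjectSpec("h", "HC"), cfg, rois6)
        assert list(cf.columns) == [f"motion_{k}" for k in range(1, 7)] + ["wm", "csf"]


class TestSimulateCohort:
    def test_default_cohort_is_11_plus_11(self, aal90):
        specs = default_cohort_specs()
        assert len(specs) == 22
        groups = [s.group for s in specs]
        assert groups.count("iNPH") == 11 and groups.count("HC") == 11

    def test_gait_profile_mean_matches_clinical_table(self):
        specs = [s for s in default_cohort_specs() if s.group == "iNPH"]
        gait = [s.gs_gait for s in specs]
        assert gait == [3, 2, 2, 3, 3, 2, 2, 1, 1, 2, 2]
        assert np.mean(gait) == pytest.approx(2.0909, abs=1e-4)

    def test_empty_spec_list_rejected(self, rois6, small_config):
        with pytest.raises(InvalidInputError):
            simulate_cohort(specs=[], config=small_config, rois=rois6)

    def test_duplicate_subject_id_rejected(self, rois6, small_config):
        specs = [SubjectSpec("a", "HC"), SubjectSpec("a", "iNPH", gs_gait=1)]
        with pytest.raises(InvalidInputError):
            simulate_cohort(specs=specs, config=small_config, rois=rois6)

    def test_cohort_round_trip(self, rois6, small_config, small_specs, tmp_path):
        cohort = simulate_cohort(small_specs, small_config, rois6)
        write_cohort(cohort, tmp_path / "c")
        loaded = read_cohort(tmp_path / "c")
        assert [s.subject_id for s in loaded.specs] == [
            s.subject_id for s in cohort.specs
        ]
        for (_s, ts, cf), (_s2, ts2, cf2) in zip(cohort.subjects, loaded.subjects):
            assert np.allclose(ts.to_numpy(), ts2.to_numpy(), atol=1e-9)
            assert np.allclose(cf.to_numpy(), cf2.to_numpy(), atol=1e-9)

    def test_subject_streams_independent_of_cohort_composition(
        self, rois6, small_config
    ):
        spec = SubjectSpec("keep", "iNPH", gs_gait=2)
        other = SubjectSpec("other", "HC")
        a = simulate_cohort([spec, other], small_config, rois6)
        b = simulate_cohort(
            [SubjectSpec("extra", "HC"), spec, other], small_config, rois6
        )
        ts_a = dict((s.subject_id, ts) for s, ts, _ in a.subjects)["keep"]
        ts_b = dict((s.subject_id, ts) for s, ts, _ in b.subjects)["keep"]
        assert ts_a.equals(ts_b)


class TestClinicalTable:
    def test_patient_summary_means(self):
        df = clinical_table()
        patients = df[df.group == "iNPH"]
        assert len(patients) == 11
        assert patients.mmse.mean() == pytest.approx(22.8, abs=0.05)
        assert patients.fab.mean() == pytest.approx(11.2, abs=0.05)
        assert patients.gs_urinary.mean() == pytest.approx(1.27, abs=0.01)
        assert patients.gs_gait.mean() == pytest.approx(2.09, abs=0.01)


class TestVoxelFixture:
    def test_all_rois_present_and_averages_match(self, aal90):
        cfg = SimConfig(n_volumes=20, seed=2)
        labels, mask, series, designated, table = voxel_fixture(aal90, cfg)
        counts = labels.voxel_counts()
        assert set(counts) == set(aal90.ids)
        avg = roi_average(series, labels, aal90)
        assert np.max(np.abs(avg.to_numpy() - designated.to_numpy())) < 1e-10

    def test_mask_overlap_matches_construction_table(self, aal90):
        cfg = SimConfig(n_volumes=20, seed=2)
        labels, mask, _, _, table = voxel_fixture(aal90, cfg, n_mask_rois=3)
        overlap = {
            rid: int(np.sum((labels.grid == rid) & (mask.grid == 1)))
            for rid in aal90.ids
        }
        assert overlap == {rid: rec["mask_overlap"] for rid, rec in table.items()}

    def test_too_small_grid_rejected(self, aal90):
        with pytest.raises(InvalidConfigError):
            voxel_fixture(aal90, SimConfig(n_volumes=20), grid_shape=(4, 4, 4))


def test_qc_shift_holds_across_seeds(aal90):
    """Confound regression shrinks both the mean and the spread of raw
    pairwise correlations on the default cohort design (checked on a few
    seeds here; the 20-seed version runs in the acceptance suite)."""
    for seed in (0, 1):
        cohort = simulate_cohort(config=SimConfig(seed=seed), rois=aal90)
        resid = [denoise.regress_confounds(ts, cf) for _, ts, cf in cohort.subjects]
        qc = denoise.qc_correlation_shift(cohort.series(), resid)
        assert abs(qc.mean_after) < abs(qc.mean_before)
        assert qc.sd_after < qc.sd_before
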