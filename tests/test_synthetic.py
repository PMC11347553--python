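"""Phantom generation, response evolution, survival and cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from deltarad.delta import delta_features
from deltarad.errors import ConfigError
from deltarad.features import extract_all
from deltarad.synthetic import (
    CohortConfig,
    DEFAULT_RESPONSE_MODELS,
    PhantomConfig,
    ResponseModel,
    evolve_phantom,
    make_phantom,
    plan_cohort,
    simulate_clinical_table,
    simulate_cohort,
    simulate_survival,
)

SMALL = PhantomConfig(shape=(40, 40, 14), spacing=(3.3, 3.3, 6.0), tumor_radius_mm=18.0)


class TestMakePhantom:
    def test_deterministic_from_seed(self):
        v1, m1 = make_phantom(SMALL, 7)
        v2, m2 = make_phantom(SMALL, 7)
        assert (v1.voxels == v2.voxels).all()
        assert (m1.flags == m2.flags).all()

    def test_zero_texture_sd_gives_constant_tumor(self):
        cfg = PhantomConfig(shape=(30, 30, 10), tumor_radius_mm=12.0, tumor_adc_sd=0.0)
        vol, mask = make_phantom(cfg, 3)
        fv = extract_all(vol, mask)
        assert fv["original.glrlm.ShortRunEmphasis"] < 1.0
        assert fv["original.glcm.InverseDifferenceNormalized"] == 1.0
        assert fv["original.glszm.ZonePercentage"] == pytest.approx(1.0 / mask.voxel_count)

    def test_in_mask_moments_match_configuration(self):
        cfg = PhantomConfig(shape=(48, 48, 28), spacing=(1.0, 1.0, 1.0), tumor_radius_mm=12.0)
        vol, mask = make_phantom(cfg, 11)
        vals = vol.voxels[mask.flags]
        assert vals.mean() == pytest.approx(cfg.tumor_adc_mean, rel=0.05)
        assert vals.std() == pytest.approx(cfg.tumor_adc_sd, rel=0.05)

    def test_tumor_must_fit_grid(self):
        with pytest.raises(ConfigError):
            PhantomConfig(shape=(20, 20, 8), spacing=(1.0, 1.0, 1.0), tumor_radius_mm=50.0)

    def test_background_outside_mask(self):
        vol, mask = make_phantom(SMALL, 5)
        assert (vol.voxels[~mask.flags] == SMALL.background_adc).all()


class TestEvolvePhantom:
    def test_null_model_identity(self):
        vol, mask = make_phantom(SMALL, 2)
        null = ResponseModel(label="null", rescan_noise_sd=0.0)
        fu, m2 = evolve_phantom(vol, mask, null, 99)
        assert (fu.voxels == vol.voxels).all()
        assert (m2.flags == mask.flags).all()
        d = delta_features(extract_all(vol, mask), extract_all(fu, m2))
        finite = [v for v in d.values() if np.isfinite(v)]
        assert np.allclose(finite, 0.0)

    def test_responder_directionality(self):
        model = DEFAULT_RESPONSE_MODELS["responder_PR"]
        for seed in range(5):
            vol, mask = make_phantom(SMALL, seed)
            fu, m2 = evolve_phantom(vol, mask, model, 100 + seed)
            d = delta_features(extract_all(vol, mask), extract_all(fu, m2))
            assert d["original.glrlm.ShortRunEmphasis"] > 0
            assert d["original.glszm.ZonePercentage"] > 0
            assert d["original.glcm.InverseDifferenceNormalized"] < 0

    def test_nonresponder_directionality(self):
        model = DEFAULT_RESPONSE_MODELS["nonresponder_PD"]
        for seed in range(5):
            vol, mask = make_phantom(SMALL, seed)
            fu, m2 = evolve_phantom(vol, mask, model, 100 + seed)
            d = delta_features(extract_all(vol, mask), extract_all(fu, m2))
            assert d["original.glrlm.ShortRunEmphasis"] < 0
            assert d["original.glszm.ZonePercentage"] < 0
            assert d["original.glcm.InverseDifferenceNormalized"] > 0

    def test_growth_scales_minor_axis(self):
        vol, mask = make_phantom(SMALL, 4)
        model = ResponseModel(label="growth", growth_factor=1.10, rescan_noise_sd=0.0)
        fu, m2 = evolve_phantom(vol, mask, model, 0)
        from deltarad.features import shape_features

        d = delta_features(shape_features(mask), shape_features(m2))
        assert d["shape.MinorAxisLength"] == pytest.approx(0.10, abs=0.04)

    def test_effect_scale_zero_is_identity_modulo_noise(self):
        vol, mask = make_phantom(SMALL, 6)
        model = ResponseModel(
            label="pd0", homogenization_strength=1.0, growth_factor=1.2, rescan_noise_sd=0.0
        )
        fu, m2 = evolve_phantom(vol, mask, model, 0, effect_scale=0.0)
        assert (fu.voxels == vol.voxels).all()
        assert (m2.flags == mask.flags).all()


class TestSimulateSurvival:
    def test_median_recovery_large_n(self, rng):
        cfg = CohortConfig(pfs_censoring_fraction=0.0)
        t = [simulate_survival(True, cfg, rng)[0] for _ in range(100_000)]
        assert np.median(t) == pytest.approx(363, abs=5)

    def test_full_censoring_no_events(self, rng):
        cfg = CohortConfig(pfs_censoring_fraction=1.0, os_censoring_fraction=1.0)
        draws = [simulate_survival(False, cfg, rng) for _ in range(50)]
        assert all(d[1] == 0 and d[3] == 0 for d in draws)

    def test_censored_fraction_calibrated(self, rng):
        cfg = CohortConfig(pfs_censoring_fraction=0.25)
        events = [simulate_survival(True, cfg, rng)[1] for _ in range(20_000)]
        assert 1 - np.mean(events) == pytest.approx(0.25, abs=0.02)

    def test_os_after_pfs_in_expectation(self, rng):
        cfg = CohortConfig(pfs_censoring_fraction=0.0, os_censoring_fraction=0.0)
        draws = [simulate_survival(True, cfg, rng) for _ in range(2000)]
        assert all(d[2] > d[0] for d in draws)


class TestCohortPlan:
    def test_default_composition(self):
        cfg = CohortConfig()
        specs = plan_cohort(cfg)
        assert len(specs) == 130
        recist = pd.Series([s.recist for s in specs])
        assert recist.value_counts().to_dict() == {"SD": 80, "PR": 40, "PD": 10}
        arms = pd.Series([s.arm for s in specs])
        assert arms.value_counts().to_dict() == {"PBC": 66, "TKI": 64}
        # arm x class margins
        tki = [s for s in specs if s.arm == "TKI"]
        assert sum(s.recist == "PR" for s in tki) == 32
        assert sum(s.recist == "PD" for s in tki) == 5

    def test_latent_groups(self):
        specs = plan_cohort(CohortConfig())
        short = [s for s in specs if not s.long_pfs]
        assert all(s.recist in ("PD", "SD") for s in short)
        assert sum(s.recist == "PD" for s in short) == 10
        assert len(short) == 10 + round(0.525 * 80)

    def test_followup_scheduling(self):
        specs = plan_cohort(CohortConfig())
        tki = [s for s in specs if s.arm == "TKI"]
        assert all(s.followup_days == (7, 14) for s in tki)
        pbc = [s for s in specs if s.arm == "PBC"]
        fu2 = [s for s in pbc if len(s.followup_days) == 2]
        assert len(fu2) == 17
        assert all(s.followup_days == (1, 7) for s in fu2)

    def test_deterministic_plan(self):
        a = plan_cohort(CohortConfig(master_seed=5))
        b = plan_cohort(CohortConfig(master_seed=5))
        assert a == b

    def test_clinical_table_deterministic(self):
        cfg = CohortConfig(master_seed=3)
        t1 = simulate_clinical_table(cfg)
        t2 = simulate_clinical_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestProgrammedEffectRecovery:
    def test_guaranteed_panel_flags_response_groups(self):
        """On full default cohorts the PD-versus-rest Welch tests flag a
        clear majority of the guaranteed 14-feature panel at Holm
        p < 0.05 (>= 4 required, per replicate)."""
        from deltarad.cohort import apply_holm, group_ttest
        from deltarad.delta import DeltaMatrix
        from deltarad.features import MANDATORY_FEATURES
        from deltarad.model import delta_matrix_from_features
        from deltarad.synthetic import reduced_cohort_config, simulate_cohort_features

        for seed in (11000, 11001, 11002):
            cfg = reduced_cohort_config(master_seed=seed)
            features, clinical = simulate_cohort_features(cfg)
            dm = delta_matrix_from_features(features, "last")
            panel = DeltaMatrix(dm.data[list(MANDATORY_FEATURES)], timepoint=dm.timepoint)
            clin = clinical.set_index("patient_id")
            res = apply_holm(group_ttest(panel, ~(clin["recist"] == "PD")))
            assert sum(r.significant for r in res) >= 4


class TestCohortOnDisk:
    def test_directory_tree_and_roundtrip(self, tmp_path):
        cfg = CohortConfig(
            n_pr_tki=1, n_sd_tki=1, n_pd_tki=1, n_pr_pbc=0, n_sd_pbc=1, n_pd_pbc=0,
            n_pbc_fu2=0,
            phantom=PhantomConfig(shape=(24, 24, 10), tumor_radius_mm=10.0),
            master_seed=1,
        )
        clinical = simulate_cohort(cfg, tmp_path)
        assert len(clinical) == 4
        assert (tmp_path / "clinical.csv").exists()
        assert (tmp_path / "config.json").exists()
        # TKI patients: BL + FU1 + FU2; PBC: BL + FU1
        files = sorted(p.name for p in tmp_path.glob("*_adc.nii.gz"))
        assert len(files) == 3 * 3 + 2
        from deltarad.imaging import read_mask, read_volume

        vol = read_volume(tmp_path / files[0])
        mask = read_mask(tmp_path / files[0].replace("_adc", "_mask"))
        assert vol.shape == (24, 24, 10)
        assert mask.voxel_count > 0

    def test_same_seed_byte_identical_csv(self, tmp_path):
        cfg = CohortConfig(
            n_pr_tki=1, n_sd_tki=0, n_pd_tki=1, n_pr_pbc=0, n_sd_pbc=0, n_pd_pbc=0,
            n_pbc_fu2=0,
            phantom=PhantomConfig(shape=(20, 20, 8), tumor_radius_mm=8.0),
            master_seed=9,
        )
        simulate_cohort(cfg, tmp_path / "a")
        simulate_cohort(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "clinical.csv").read_bytes() == (tmp_path / "b" / "clinical.csv").read_bytes()
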