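"""Phantom generator: input function, tissue/bladder kinetics, cohort, voxels."""

from dataclasses import replace

import numpy as np
import pytest

from dynpet import phantom as ph
from dynpet.core import InputError, ParameterError
from dynpet.repeatability import lesion_volume

from conftest import brute_force_tissue

TIMES = np.arange(30) + 0.5


class TestAIF:
    def test_zero_before_and_at_appearance(self):
        p = ph.DEFAULT_AIF
        assert ph.aif_value(p, p.tau) == pytest.approx(0.0, abs=1e-12)
        assert ph.aif_value(p, p.tau - 1.0) == 0.0
        assert ph.aif_value(p, 0.0) == 0.0

    def test_default_continuous_peak_in_reported_arterial_band(self):
        # dense-grid search; first-pass peak must sit in the 3.6-5.4 SUL
        # band and occur within the first two minutes
        g = np.arange(0.0, 30.0001, 0.01)
        cp = ph.aif_value(ph.DEFAULT_AIF, g)
        i = int(np.argmax(cp))
        assert 3.6 <= cp[i] <= 5.4
        assert g[i] < 2.0

    def test_continuity_across_appearance(self):
        p = ph.DEFAULT_AIF
        eps = 1e-8
        assert abs(ph.aif_value(p, p.tau + eps)) < 1e-5

    @pytest.mark.parametrize("bad", [
        dict(lam1=0.4, lam2=0.6),   # ordering violated
        dict(lam3=-0.1, ),          # non-positive rate
        dict(tau=-1.0),
    ])
    def test_invalid_params_raise(self, bad):
        kw = dict(A1=13.8, A2=5.34, A3=1.21, lam1=3.6, lam2=0.603,
                  lam3=0.001, tau=0.05)
        kw.update(bad)
        with pytest.raises(ParameterError):
            ph.AIFParams(**kw)


class TestTissue:
    def test_blood_identity_limit(self):
        tp = ph.TissueParams(K1=0.0, k2=0.0, Ki=0.0, vb=1.0)
        got = ph.tissue_tac(tp, ph.DEFAULT_AIF, TIMES)
        want = ph.aif_value(ph.DEFAULT_AIF, TIMES)
        assert np.allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_zero_exchange_zero_blood_is_zero(self):
        tp = ph.TissueParams(K1=0.0, k2=0.0, Ki=0.0, vb=0.0)
        assert np.all(ph.tissue_tac(tp, ph.DEFAULT_AIF, TIMES) == 0.0)

    def test_matches_bruteforce_convolution_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(10):
            tp = ph.TissueParams(K1=rng.uniform(0, 2), k2=rng.uniform(0, 2),
                                 Ki=rng.uniform(0, 0.5), vb=rng.uniform(0, 0.3))
            impl = ph.tissue_tac(tp, ph.DEFAULT_AIF, TIMES)
            oracle = brute_force_tissue(tp, ph.DEFAULT_AIF, TIMES)
            worst = max(worst, np.max(np.abs(impl - oracle))
                        / np.max(np.abs(oracle)))
        assert worst <= 1e-3

    def test_reversible_lesion_is_bounded(self):
        # blood pool held essentially constant on this horizon so the
        # reversible compartment's finite plateau is visible in isolation
        aif = replace(ph.DEFAULT_AIF, lam3=1e-6)
        tp = ph.TissueParams(K1=1.3, k2=0.8, Ki=0.0, vb=0.08)
        far = ph.tissue_tac(tp, aif, np.array([500.0, 1000.0]))
        assert abs(far[1] - far[0]) / far[0] < 0.01

    def test_trapping_lesion_rises_after_arterial_peak(self):
        tp = ph.TissueParams(K1=0.15, k2=0.5, Ki=0.28, vb=0.10)
        t = np.arange(2.0, 30.0, 0.5)  # past the sub-minute bolus peak
        y = ph.tissue_tac(tp, ph.DEFAULT_AIF, t)
        assert np.all(np.diff(y) > 0)

    def test_unsorted_or_negative_times_raise(self):
        tp = ph.TissueParams(K1=0.1, k2=0.1)
        with pytest.raises(InputError):
            ph.tissue_tac(tp, ph.DEFAULT_AIF, np.array([2.0, 1.0]))
        with pytest.raises(InputError):
            ph.tissue_tac(tp, ph.DEFAULT_AIF, np.array([-1.0, 1.0]))


class TestBladder:
    def test_zero_before_onset_delay(self):
        bp = ph.BladderParams(t0=8.0, kexc=60.0, Vb0=100.0, inflow=1.5)
        y = ph.bladder_tac(bp, ph.DEFAULT_AIF, TIMES)
        assert np.all(y[TIMES < 8.0] == 0.0)
        assert np.all(y >= 0.0)

    def test_linear_accumulation_for_constant_input_no_inflow(self):
        # AIF shaped to be ~constant A3 after a fast transient: with
        # inflow = 0 the bladder is kexc*c*(t-t0)/Vb0
        aif = ph.AIFParams(A1=0.0, A2=1e-9, A3=2.0, lam1=8.0, lam2=4.0,
                           lam3=1e-7, tau=0.0)
        bp = ph.BladderParams(t0=5.0, kexc=30.0, Vb0=150.0, inflow=0.0)
        t = np.array([10.0, 20.0, 30.0])
        got = ph.bladder_tac(bp, aif, t)
        want = 30.0 * 2.0 * (t - 5.0) / 150.0
        assert np.allclose(got, want, rtol=1e-2)

    def test_nonpositive_initial_volume_rejected(self):
        with pytest.raises(ParameterError):
            ph.BladderParams(t0=8.0, kexc=60.0, Vb0=0.0, inflow=1.5)


class TestDecay:
    def test_reference_values(self):
        assert ph.decay_factor(0.0) == pytest.approx(1.0)
        assert ph.decay_factor(67.71) == pytest.approx(0.5, rel=1e-12)
        assert ph.decay_factor(30.0) == pytest.approx(0.7356, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            ph.decay_factor(10.0, half_life=0.0)
        with pytest.raises(ParameterError):
            ph.decay_factor(-1.0)

    def test_uncorrected_mode_scales_by_decay(self, noiseless_scene):
        raw = replace(noiseless_scene, decay_correct=False)
        t_cor = ph.simulate_scene_tacs(noiseless_scene)["muscle"]
        t_raw = ph.simulate_scene_tacs(raw)["muscle"]
        f = ph.decay_factor(t_cor.t_mid)
        assert np.allclose(t_raw.sul, t_cor.sul * f, rtol=1e-12)


class TestCohort:
    def test_bit_reproducible_and_seed_sensitive(self):
        a = ph.simulate_tac_cohort(ph.default_scene(), n_subjects=2, seed=5)
        b = ph.simulate_tac_cohort(ph.default_scene(), n_subjects=2, seed=5)
        c = ph.simulate_tac_cohort(ph.default_scene(), n_subjects=2, seed=6)
        key = ("sub-01", "test")
        assert np.array_equal(a.visits[key].tacs["artery"].sul,
                              b.visits[key].tacs["artery"].sul)
        assert not np.array_equal(a.visits[key].tacs["artery"].sul,
                                  c.visits[key].tacs["artery"].sul)

    def test_no_within_variation_makes_visits_identical(self):
        scene = ph.default_scene(alpha=0.0)
        cohort = ph.simulate_tac_cohort(scene, n_subjects=3,
                                        between_subject_cv=0.2,
                                        within_subject_cv=0.0, seed=1)
        for sid in cohort.subjects:
            t1 = cohort.tac(sid, "test", "tumor_rising").sul
            t2 = cohort.tac(sid, "retest", "tumor_rising").sul
            assert np.array_equal(t1, t2)

    def test_no_variation_makes_subjects_identical(self):
        scene = ph.default_scene(alpha=0.0)
        cohort = ph.simulate_tac_cohort(scene, n_subjects=3,
                                        between_subject_cv=0.0,
                                        within_subject_cv=0.0, seed=1)
        ref = cohort.tac("sub-01", "test", "muscle").sul
        for sid in cohort.subjects:
            for visit in ("test", "retest"):
                assert np.array_equal(cohort.tac(sid, visit, "muscle").sul, ref)

    def test_between_subject_cv_recovered_at_n20(self):
        scene = ph.default_scene(alpha=0.0)
        cohort = ph.simulate_tac_cohort(scene, n_subjects=20,
                                        between_subject_cv=0.10,
                                        within_subject_cv=0.0, seed=1)
        peaks = np.array([
            np.max(cohort.tac(sid, "test", "tumor_rising").sul)
            for sid in cohort.subjects
        ])
        cv = peaks.std(ddof=1) / peaks.mean()
        assert 0.06 <= cv <= 0.14  # +/-40% of the configured 10%

    def test_positive_concentrations_without_noise(self, noiseless_tacs):
        for tac in noiseless_tacs.values():
            assert np.all(np.isfinite(tac.sul))
            assert np.all(tac.sul >= 0.0)


class TestVoxelize:
    def test_region_means_reproduce_frame_averaged_tacs(
            self, noiseless_scene, noiseless_voxels, noiseless_tacs):
        img, labels = noiseless_voxels
        for rid, name in labels.names.items():
            mask = labels.labels == rid
            conc_img = img.values[mask].mean(axis=0)
            ref = noiseless_tacs[name].conc
            rel = np.max(np.abs(conc_img - ref) / np.maximum(np.abs(ref), 1e-12))
            assert rel <= 1e-9

    def test_deterministic_given_seed(self):
        scene = ph.default_scene(alpha=0.05, seed=9)
        a, _ = ph.voxelize_scene(scene)
        b, _ = ph.voxelize_scene(scene)
        assert np.array_equal(a.values, b.values)

    def test_overlapping_spheres_rejected(self, noiseless_scene):
        geo = dict(ph.DEFAULT_GEOMETRY)
        geo["muscle"] = ph.RegionGeometry(
            center_mm=geo["bladder"].center_mm, radius_mm=10.0)
        with pytest.raises(ParameterError):
            ph.voxelize_scene(replace(noiseless_scene, geometry=geo))

    def test_minimum_size_sphere_clears_roi_floor(self, noiseless_scene):
        # a 7.6 mm-radius sphere centered between voxel centers covers
        # >= 1.8 mL at 4 mm voxels, the minimum-ROI rule
        geo = dict(ph.DEFAULT_GEOMETRY)
        geo["tumor_stable"] = ph.RegionGeometry(center_mm=(96.0, 60.0, 84.0),
                                                radius_mm=7.6)
        _, labels = ph.voxelize_scene(replace(noiseless_scene, geometry=geo))
        assert lesion_volume(labels, "tumor_stable") >= 1.8

    def test_scene_json_roundtrip(self, noiseless_scene):
        text = ph.scene_to_json(noiseless_scene)
        back = ph.scene_from_json(text)
        assert back.aif == noiseless_scene.aif
        assert back.regions == dict(noiseless_scene.regions)
        assert back.geometry == dict(noiseless_scene.geometry)
        assert np.array_equal(back.schedule.start, noiseless_scene.schedule.start)
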