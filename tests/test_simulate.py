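"""Forward models, Rician noise statistics, and cohort generation."""

import numpy as np
import pytest

from prostate_qmri.fitting import fit_adc
from prostate_qmri.phantom import build_phantom
from prostate_qmri.simulate import (
    SimConfig,
    generate_cohort,
    rician,
    simulate_dwi_series,
    simulate_echo_series,
    simulate_trajectory_cohort,
    synthesize_t2w,
)

ECHO_TIMES = tuple(32.0 + 16.0 * i for i in range(12))


class TestForwardModels:
    def test_echo_signal_closed_form(self, flat_phantom):
        """Noiseless signal at TE=32 for T2=80 is S0*exp(-32/80) = 0.6703*S0."""
        series = simulate_echo_series(flat_phantom, [32.0], snr=None, rng=0)
        tumor = flat_phantom.roi_mask("tumor")  # tumor truth T2 is 80 ms
        vals = series.volumes[0].data[tumor] / 100.0  # prostate S0 = 100
        assert np.allclose(vals, np.exp(-32.0 / 80.0), rtol=1e-12)
        assert np.exp(-32.0 / 80.0) == pytest.approx(0.6703, abs=5e-5)

    def test_zero_noise_equals_forward_model(self, flat_phantom):
        a = simulate_echo_series(flat_phantom, ECHO_TIMES, snr=None, rng=0)
        b = simulate_echo_series(flat_phantom, ECHO_TIMES, snr=np.inf, rng=1)
        for va, vb in zip(a.volumes, b.volumes):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_rayleigh_floor_mean(self):
        """Pure-noise magnitude voxels average sigma*sqrt(pi/2)."""
        rng = np.random.default_rng(5)
        sigma = 3.0
        vals = rician(np.zeros(40000), sigma, rng)
        assert vals.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_dwi_signal_closed_form(self, flat_phantom):
        """S(b=800) = S0*exp(-0.8) = 0.4493*S0 at ADC = 1e-3 mm^2/s."""
        truth = build_phantom(baseline_adc={"CG": 1e-3, "PZ": 1e-3, "tumor": 1e-3})
        series = simulate_dwi_series(truth, [0.0, 800.0], snr=None, rng=0)
        prostate = truth.roi_mask("prostate")
        ratio = series.volume_at(800.0).data[prostate] / series.volume_at(0.0).data[prostate]
        assert np.allclose(ratio, np.exp(-0.8), rtol=1e-12)
        assert np.exp(-0.8) == pytest.approx(0.4493, abs=5e-5)

    def test_b0_equals_s0(self, flat_phantom):
        series = simulate_dwi_series(flat_phantom, [0.0, 200.0, 800.0], snr=None, rng=0)
        np.testing.assert_array_equal(
            series.volume_at(0.0).data, flat_phantom.s0_truth.data
        )

    def test_noiseless_two_point_roundtrip(self, flat_phantom):
        """fit_adc on a noiseless 2-b series recovers the truth map to 1e-10."""
        series = simulate_dwi_series(flat_phantom, [0.0, 200.0, 800.0], snr=None, rng=0)
        qmap = fit_adc(series, (200.0, 800.0))
        prostate = flat_phantom.roi_mask("prostate")
        truth = flat_phantom.adc_truth.values.data[prostate]
        fitted = qmap.values.data[prostate]
        ok = qmap.valid[prostate]
        assert ok.all()
        np.testing.assert_allclose(fitted, truth, rtol=1e-10)

    def test_input_validation(self, flat_phantom):
        with pytest.raises(ValueError):
            simulate_echo_series(flat_phantom, [48.0, 32.0], snr=None, rng=0)
        with pytest.raises(ValueError):
            simulate_echo_series(flat_phantom, ECHO_TIMES, snr=-5.0, rng=0)
        with pytest.raises(ValueError):
            simulate_dwi_series(flat_phantom, [-100.0, 800.0], snr=None, rng=0)
        with pytest.raises(ValueError):
            simulate_dwi_series(flat_phantom, [200.0, 800.0], snr=None, rng=0)  # no b=0


class TestCohortGeneration:
    def test_determinism(self, small_geometry):
        """The same configuration yields a bit-identical cohort."""
        cfg = SimConfig(n_patients=2, seed=9, missing_prob=0.2)
        a = generate_cohort(cfg, geometry=small_geometry)
        b = generate_cohort(cfg, geometry=small_geometry)
        assert [p.available_weeks() for p in a.patients] == [
            p.available_weeks() for p in b.patients
        ]
        for pa, pb in zip(a.patients, b.patients):
            for w in pa.available_weeks():
                np.testing.assert_array_equal(pa.exams[w].t2w.data, pb.exams[w].t2w.data)
                np.testing.assert_array_equal(
                    pa.exams[w].dwi.volumes[0].data, pb.exams[w].dwi.volumes[0].data
                )
                assert pa.exams[w].true_align == pb.exams[w].true_align

    def test_zero_misalignment_gives_identity_sidecars(self, small_geometry):
        cfg = SimConfig(
            n_patients=1, seed=2, misalignment_max_mm=0.0, misalignment_max_deg=0.0,
            missing_prob=0.0,
        )
        cohort = generate_cohort(cfg, geometry=small_geometry)
        for exam in cohort.patients[0].exams.values():
            assert exam.true_align.is_identity()

    def test_misalignment_bounded(self, small_geometry):
        cfg = SimConfig(n_patients=2, seed=4, missing_prob=0.0)
        cohort = generate_cohort(cfg, geometry=small_geometry)
        for p in cohort.patients:
            for w, exam in p.exams.items():
                assert np.all(np.abs(exam.true_align.rotation_deg) <= 5.0)
                assert np.all(np.abs(exam.true_align.translation_mm) <= 5.0)

    def test_forced_missing_flags_exclusion(self, small_geometry):
        """A patient with 4 of 5 follow-ups missing fails the >=3-exam rule."""
        from prostate_qmri.stats import apply_exclusions

        cfg = SimConfig(n_patients=2, seed=1, missing_prob=0.0)
        cohort = generate_cohort(
            cfg, geometry=small_geometry, forced_missing={0: [1, 2, 3, 4]}
        )
        report = apply_exclusions(cohort.manifest())
        assert "P000" not in report.adc_patients
        assert ("P000", "ADC", "insufficient exams") in report.excluded
        assert "P001" in report.adc_patients

    def test_dialect_a_has_no_echo_series(self, small_geometry):
        cfg = SimConfig(n_patients=1, dialect="A", seed=6, missing_prob=0.0)
        cohort = generate_cohort(cfg, geometry=small_geometry)
        exam = cohort.patients[0].exams[0]
        assert exam.echoes is None
        assert sorted(exam.dwi.index) == [0.0, 100.0, 300.0, 500.0, 800.0, 1000.0]

    def test_n_patients_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_patients=0)

    def test_cohort_disk_roundtrip(self, small_geometry, tmp_path):
        """save_cohort / load_cohort preserve exams, sidecars, and metadata."""
        from prostate_qmri.simulate import load_cohort, save_cohort

        cfg = SimConfig(n_patients=1, seed=3, missing_prob=0.3)
        cohort = generate_cohort(cfg, geometry=small_geometry)
        save_cohort(cohort, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort")
        orig = cohort.patients[0]
        loaded = back.patients[0]
        assert loaded.ht == orig.ht and loaded.dialect == orig.dialect
        assert loaded.available_weeks() == orig.available_weeks()
        w = orig.available_weeks()[-1]
        np.testing.assert_allclose(
            loaded.exams[w].t2w.data, orig.exams[w].t2w.data, rtol=1e-6
        )
        np.testing.assert_allclose(
            loaded.exams[w].true_align.rotation_deg,
            orig.exams[w].true_align.rotation_deg,
        )
        np.testing.assert_allclose(
            np.asarray(loaded.exams[w].dwi.index), np.asarray(orig.exams[w].dwi.index)
        )


class TestTrajectoryCohort:
    def test_effects_recovered_in_expectation(self):
        """Median-level generator reproduces the injected week-5 factors."""
        cfg = SimConfig(
            n_patients=60, seed=3, missing_prob=0.0, effect_jitter_sd=0.0,
            median_noise_sd=0.0, baseline_variation=0.0,
        )
        df = simulate_trajectory_cohort(cfg)
        ht = df[(df.ht) & (df.roi == "PZ") & (df.map_type == "T2")]
        w5 = ht[ht.week == 5]["median_value"].median()
        w0 = ht[ht.week == 0]["median_value"].median()
        assert w5 / w0 == pytest.approx(0.83, rel=1e-12)

    def test_schema_matches_imaging_path(self):
        cfg = SimConfig(n_patients=3, seed=3)
        df = simulate_trajectory_cohort(cfg)
        assert set(df.columns) == {
            "patient", "ht", "dialect", "roi", "map_type", "week",
            "median_value", "measured",
        }
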