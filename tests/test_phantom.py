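import numpy as np
import pandas as pd
import pytest

from dceradiomics.phantom import (PhantomSpec, gamma_variate_aif, generate_cohort,
                                  generate_patient, patient_seeds, tissue_curve)


class TestGammaVariate:
    def test_peak_value_is_amplitude_at_analytic_peak(self):
        assert gamma_variate_aif(10 + 3 * 4, t0=10, A=600, alpha=3, beta=4) == pytest.approx(600)

    def test_zero_before_arrival(self):
        t = np.array([0.0, 5.0, 10.0])
        assert np.all(gamma_variate_aif(t, t0=10, A=600, alpha=3, beta=4) == 0)

    def test_closed_form_value(self):
        # A*( (t-t0)/(alpha*beta) )^alpha * exp(alpha - (t-t0)/beta) at t=14
        expected = 600 * (4 / 12) ** 3 * np.exp(3 - 1)
        assert gamma_variate_aif(14, t0=10, A=600, alpha=3, beta=4) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha,beta", [(0, 4), (-1, 4), (3, 0)])
    def test_invalid_shape_parameters(self, alpha, beta):
        with pytest.raises(ValueError):
            gamma_variate_aif(5, t0=0, A=1, alpha=alpha, beta=beta)


class TestTissueCurve:
    def test_no_uptake_stays_at_baseline(self):
        t = np.linspace(0, 60, 10)
        out = tissue_curve(lambda s: np.ones_like(s), baseline=45, k_in=0, k_out=0.1, t=t)
        assert np.allclose(out, 45.0)

    def test_constant_aif_matches_analytic_convolution(self):
        k_in, k_out = 0.02, 0.05
        t = np.array([5.0, 20.0, 60.0, 120.0])
        out = tissue_curve(lambda s: np.ones_like(np.asarray(s, float)),
                           baseline=0.0, k_in=k_in, k_out=k_out, t=t)
        expected = (k_in / k_out) * (1 - np.exp(-k_out * t))
        assert np.allclose(out, expected, rtol=1e-3)

    def test_steady_state_is_kin_over_kout(self):
        out = tissue_curve(lambda s: np.ones_like(np.asarray(s, float)),
                           baseline=0.0, k_in=0.02, k_out=0.05, t=np.array([400.0]))
        assert out == pytest.approx(0.4, rel=1e-3)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            tissue_curve(lambda s: s, baseline=0, k_in=-1, k_out=1, t=np.array([1.0]))


class TestScanTiming:
    def test_fast_then_slow_intervals(self):
        times = PhantomSpec().scan_times()
        diffs = np.diff(times)
        assert np.allclose(diffs[:19], 1.5)
        assert np.allclose(diffs[19:], 3.0)
        assert times[0] == 0.0


class TestGeneratePatient:
    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec()
        a = generate_patient(spec, 123)
        b = generate_patient(spec, 123)
        for va, vb in zip(a.series.volumes, b.series.volumes):
            np.testing.assert_array_equal(va.voxels, vb.voxels)

    def test_noise_free_tumor_equals_ground_truth(self):
        spec = PhantomSpec(noise_sd=0.0, texture_amplitude=0.0, texture_enh_fraction=0.0)
        pat = generate_patient(spec, 3)
        m = pat.masks["tumor"].voxels
        for it, vol in enumerate(pat.series.volumes):
            assert np.allclose(vol.voxels[m], pat.ground_truth["curves"]["tumor"][it],
                               atol=1e-4)

    def test_measured_vessel_peak_times_in_spec_range(self):
        # the 15-26 s arrival window, allowing one slow scan interval of slack
        spec = PhantomSpec()
        for seed in range(20):
            pat = generate_patient(spec, seed)
            med = [float(np.median(v.voxels[pat.masks["vessel"].voxels]))
                   for v in pat.series.volumes]
            t_peak = pat.series.acquisition_times[int(np.argmax(med))]
            assert 15.0 - 3.0 <= t_peak <= 26.0 + 3.0

    def test_measured_vessel_peak_amplitude_in_spec_range(self):
        spec = PhantomSpec()
        lo, hi = spec.peak_amplitude_range
        for seed in range(10):
            pat = generate_patient(spec, seed)
            med = [float(np.median(v.voxels[pat.masks["vessel"].voxels]))
                   for v in pat.series.volumes]
            peak = max(med) - spec.vessel_baseline
            assert lo - 20 <= peak <= hi + 20  # noise on a ROI median is small

    def test_masks_disjoint(self):
        pat = generate_patient(PhantomSpec(), 0)
        total = sum(m.voxels.astype(int) for m in pat.masks.values())
        assert total.max() == 1


class TestGenerateCohort:
    def test_manifest_lists_all_patients(self, tmp_path):
        spec = PhantomSpec(n_patients=7, grid_shape=(16, 16, 16), n_scans=10)
        generate_cohort(spec, out_dir=tmp_path)
        manifest = pd.read_csv(tmp_path / "cohort_manifest.csv")
        assert len(manifest) == 7
        assert all((tmp_path / p).is_dir() for p in manifest["path"])

    def test_same_master_seed_gives_identical_manifests(self, tmp_path):
        spec = PhantomSpec(n_patients=3, grid_shape=(16, 16, 16), n_scans=10, seed=5)
        generate_cohort(spec, out_dir=tmp_path / "a")
        generate_cohort(spec, out_dir=tmp_path / "b")
        assert (tmp_path / "a/cohort_manifest.csv").read_bytes() == \
               (tmp_path / "b/cohort_manifest.csv").read_bytes()

    def test_arrival_times_differ_between_patients(self):
        spec = PhantomSpec(n_patients=7, grid_shape=(16, 16, 16), n_scans=10)
        pats = generate_cohort(spec)
        arrivals = {round(p.ground_truth["params"]["t0_s"], 6) for p in pats}
        assert len(arrivals) == 7

    def test_per_patient_seeds_are_stable(self):
        spec = PhantomSpec(seed=11)
        assert patient_seeds(spec) == patient_seeds(spec)
        assert patient_seeds(spec) != patient_seeds(PhantomSpec(seed=12))


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_scans": 5},
        {"tumor_k_in": -0.1},
        {"peak_time_range": (5.0, 26.0)},   # peak earlier than bolus transit
        {"peak_amplitude_range": (827.0, 520.0)},
        {"n_patients": 0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)
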