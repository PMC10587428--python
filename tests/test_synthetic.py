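import numpy as np
import pytest

from tackit.aif import FengInput
from tackit.kinetics import KineticParams, cumulative_integral, default_metabolite_model
from tackit.metrics import detect_peaks
from tackit.schedule import fine_time_grid, frame_average
from tackit.synthetic import (
    NoiseSpec,
    OrganTruth,
    SecondPeak,
    add_noise,
    generate_cohort,
    simulate_pelvis_tac,
    simulate_tissue_tac,
)
from tests.conftest import ode_oracle_tac


class TestSimulateTissueTac:
    def test_zero_uptake_is_scaled_blood(self, aif, schedule):
        truth = OrganTruth("myocardium", KineticParams(0.0, 0.1, Vb=0.4))
        tac = simulate_tissue_tac(truth, aif, schedule)
        t = fine_time_grid(schedule)
        np.testing.assert_allclose(tac.values, 0.4 * frame_average(t, aif(t), schedule), rtol=1e-12)

    def test_pure_trapping_is_cumulative_integral(self, aif, schedule):
        truth = OrganTruth("myocardium", KineticParams(0.5, 0.0, Vb=0.0))
        tac = simulate_tissue_tac(truth, aif, schedule)
        t = fine_time_grid(schedule)
        want = frame_average(t, 0.5 * cumulative_integral(t, aif(t)), schedule)
        np.testing.assert_allclose(tac.values, want, rtol=1e-10)

    def test_myocardial_means_match_ode_oracle(self, aif, schedule):
        # ketone-tracer myocardial means: K1 = 0.61, k2 = 0.063
        params = KineticParams(0.61, 0.063, Vb=0.3)
        metab = default_metabolite_model("acac")
        tac = simulate_tissue_tac(OrganTruth("myocardium", params), aif, schedule, metabolites=metab)

        def cp(t):
            return aif(t) * metab.parent_fraction(t)

        want = ode_oracle_tac(params, cp, aif, schedule)
        assert np.max(np.abs(tac.values - want)) < 1e-3 * np.max(want)

    def test_nonnegative_and_k1_linear(self, aif, schedule):
        a = simulate_tissue_tac(OrganTruth("myocardium", KineticParams(0.4, 0.2, Vb=0.0)), aif, schedule)
        b = simulate_tissue_tac(OrganTruth("myocardium", KineticParams(0.8, 0.2, Vb=0.0)), aif, schedule)
        assert np.all(a.values >= 0)
        np.testing.assert_allclose(b.values, 2.0 * a.values, rtol=1e-12)

    def test_oracle_agreement_over_random_draws(self, aif, schedule):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = KineticParams(
                K1=rng.uniform(0.1, 2.0),
                k2=rng.uniform(0.02, 1.0),
                k3=rng.uniform(0.0, 0.1),
                Vb=rng.uniform(0.0, 0.5),
            )
            tac = simulate_tissue_tac(OrganTruth("renal_cortex", params), aif, schedule)
            want = ode_oracle_tac(params, aif, aif, schedule)
            assert np.max(np.abs(tac.values - want)) < 1e-3 * np.max(np.abs(want))


class TestSimulatePelvisTac:
    def test_second_amplitude_zero_single_peak(self, aif, schedule):
        truth = OrganTruth("renal_pelvis", KineticParams(0, 0), early_fraction=0.3)
        tac = simulate_pelvis_tac(truth, aif, schedule)
        assert len(detect_peaks(tac, min_prominence=1.0)) == 1

    def test_double_peak_near_configured_mode(self, aif, schedule):
        truth = OrganTruth(
            "renal_pelvis",
            KineticParams(0, 0),
            early_fraction=0.3,
            second_peak=SecondPeak(amplitude=180.0, mode_min=7.0),
        )
        tac = simulate_pelvis_tac(truth, aif, schedule)
        peaks = detect_peaks(tac, min_prominence=1.0)
        assert len(peaks) == 2
        # dense-grid argmax of the generating gamma-variate sits at the mode;
        # the frame-level peak must land within one frame of it
        i = np.searchsorted(schedule.frame_start_s, 7.0 * 60.0) - 1
        frame_min = schedule.duration_min[i]
        assert abs(peaks[1].t_max_min - 7.0) <= frame_min

    def test_all_zero_components(self, aif, schedule):
        truth = OrganTruth("renal_pelvis", KineticParams(0, 0), early_fraction=0.0)
        tac = simulate_pelvis_tac(truth, aif, schedule)
        np.testing.assert_array_equal(tac.values, 0.0)

    def test_nonpositive_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            SecondPeak(amplitude=10.0, mode_min=0.0)

    def test_wrong_region_rejected(self, aif, schedule):
        with pytest.raises(ValueError, match="renal_pelvis"):
            simulate_pelvis_tac(OrganTruth("myocardium", KineticParams(0.5, 0.1)), aif, schedule)


class TestAddNoise:
    def test_zero_scale_identity(self, aif, schedule):
        tac = simulate_tissue_tac(OrganTruth("myocardium", KineticParams(0.6, 0.06, Vb=0.3)), aif, schedule)
        out = add_noise(tac, NoiseSpec(scale=0.0, seed=1))
        np.testing.assert_array_equal(out.values, tac.values)

    def test_seed_determinism(self, aif, schedule):
        tac = simulate_tissue_tac(OrganTruth("myocardium", KineticParams(0.6, 0.06, Vb=0.3)), aif, schedule)
        a = add_noise(tac, NoiseSpec(scale=0.05, seed=7))
        b = add_noise(tac, NoiseSpec(scale=0.05, seed=7))
        np.testing.assert_array_equal(a.values, b.values)

    def test_monte_carlo_sd_matches_formula(self, aif, schedule):
        tac = simulate_tissue_tac(OrganTruth("myocardium", KineticParams(0.6, 0.06, Vb=0.3)), aif, schedule)
        lam = np.log(2.0) / 20.364
        frame = 20  # a late 150-s frame
        want_sd = 0.05 * np.sqrt(
            tac.values[frame] * np.exp(lam * tac.t_mid_min[frame]) / tac.schedule.duration_min[frame]
        )
        rng = np.random.default_rng(3)
        draws = np.array(
            [add_noise(tac, NoiseSpec(scale=0.05), rng=rng).values[frame] for _ in range(1000)]
        )
        assert np.std(draws) == pytest.approx(want_sd, rel=0.05)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(scale=-0.1)


class TestGenerateCohort:
    def test_cohort_size_validation(self):
        with pytest.raises(ValueError, match=">= 1"):
            generate_cohort(0)

    def test_zero_variance_distributions_hit_means(self):
        from tackit.synthetic import reference_truth_distributions

        dists = reference_truth_distributions()
        for key in dists:
            if key == "vitals":
                continue
            dists[key] = {k: (m, 0.0) for k, (m, s) in dists[key].items()}
        dists["vitals"] = {k: (m, 0.0) for k, (m, s) in dists["vitals"].items()}
        c = generate_cohort(1, truth_distributions=dists, seed=0, noise_scale=0.0)
        truth = c.subjects[0].regions[("acac", "myocardium")].truth
        assert truth.params.K1 == pytest.approx(0.61)
        assert truth.params.k2 == pytest.approx(0.063)
        assert c.subjects[0].vitals.hr == pytest.approx(65.0)

    def test_truth_means_near_reference(self):
        c = generate_cohort(10, seed=5)
        k1s = np.array(
            [s.regions[("acac", "myocardium")].truth.params.K1 for s in c.subjects]
        )
        # sample mean within 2 SE of the 0.61 population mean (SD 0.07)
        assert abs(k1s.mean() - 0.61) < 2 * 0.07 / np.sqrt(10)

    def test_fixed_seed_bit_identical(self):
        a = generate_cohort(3, seed=11)
        b = generate_cohort(3, seed=11)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.vitals == sb.vitals
            for key in sa.regions:
                np.testing.assert_array_equal(sa.regions[key].tac.values, sb.regions[key].tac.values)

    def test_second_peak_only_for_acac_pelvis(self):
        c = generate_cohort(3, seed=2)
        for s in c.subjects:
            assert s.regions[("acac", "renal_pelvis")].truth.second_peak is not None
            assert s.regions[("ac", "renal_pelvis")].truth.second_peak is None
            assert s.regions[("ac", "myocardium")].truth.second_peak is None
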