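"""FCS fitting, QC cascade, volume conversions and method-comparison bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohesinquant import fcs
from cohesinquant import synthetic as syn
from cohesinquant.constants import AVOGADRO


@pytest.fixture(scope="module")
def calibration():
    """Dye calibration: N=15 at 50 nM gives V_eff ~ 0.5 fl."""
    dye_fit = fcs.AcfFit(
        n_particles=15.0, tau1=0.025, tau2=0.025, frac1=1.0, structure_param=5.0,
        offset=0.0, r_squared=1.0, chisq_per_point=0.0, cpm=40.0,
    )
    return fcs.calibrate_confocal_volume(dye_fit, known_concentration=50.0)


def make_fit(r2=0.99, chisq=0.5, cpm=30.0, success=True, n=10.0):
    return fcs.AcfFit(
        n_particles=n, tau1=0.5, tau2=50.0, frac1=0.6, structure_param=5.0,
        offset=0.0, r_squared=r2, chisq_per_point=chisq, cpm=cpm, success=success,
    )


class TestCorrelateTrace:
    def test_constant_trace_has_zero_acf(self):
        rec = fcs.correlate_trace(np.full(1000, 50.0), bin_width=0.1)
        np.testing.assert_allclose(rec.acf_values, 0.0, atol=1e-15)

    def test_iid_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        trace = rng.poisson(100, size=20_000).astype(float)
        rec = fcs.correlate_trace(trace, bin_width=0.1)
        assert np.all(np.abs(rec.acf_values) < 3 / np.sqrt(trace.size))

    def test_periodic_trace_matches_brute_force_autocovariance(self):
        t = np.arange(2000)
        trace = 100.0 * (1.0 + 0.5 * np.sin(2 * np.pi * t / 50))
        rec = fcs.correlate_trace(trace, bin_width=1.0)
        mean = trace.mean()
        for lag_ms, got in zip(rec.lags, rec.acf_values):
            k = int(round(lag_ms))
            # O(n^2)-style direct autocovariance oracle
            acc = 0.0
            for i in range(trace.size - k):
                acc += (trace[i] - mean) * (trace[i + k] - mean)
            expected = acc / (trace.size - k) / mean**2
            assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_mean_trace_rejected(self):
        with pytest.raises(ValueError):
            fcs.correlate_trace(np.zeros(100), bin_width=0.1)


class TestFitAcf:
    def test_noiseless_two_component_recovery(self):
        truth = syn.FcsTruth(
            n_particles=10, tau1=0.5, tau2=50.0, frac1=0.6, structure_param=5.0,
            offset=0.01, noise_sd_scale=0.0,
        )
        rec = syn.simulate_fcs_measurement(truth)
        fit = fcs.fit_acf(rec)
        assert fit.success
        assert fit.n_particles == pytest.approx(10.0, rel=1e-4)
        assert fit.tau1 == pytest.approx(0.5, rel=1e-4)
        assert fit.tau2 == pytest.approx(50.0, rel=1e-4)
        assert fit.frac1 == pytest.approx(0.6, rel=1e-4)
        assert fit.offset == pytest.approx(0.01, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
        assert fit.tau1 < fit.tau2  # component-exchange relabelling

    def test_noisy_ensemble_recovers_particle_number(self):
        truth = syn.FcsTruth(n_particles=10.0, noise_sd_scale=0.05, seed=21)
        fits = [
            fcs.fit_acf(syn.simulate_fcs_measurement(truth, index=i))
            for i in range(60)
        ]
        med = np.median([f.n_particles for f in fits if f.success])
        assert med == pytest.approx(10.0, rel=0.05)

    def test_pure_noise_curve_fails_qc(self):
        rng = np.random.default_rng(1)
        lags = syn.multiple_tau_lags()
        rec = fcs.AcfRecord(
            lags=lags, acf_values=rng.normal(0, 0.01, lags.size), mean_intensity=100.0,
        )
        fit = fcs.fit_acf(rec)
        retained, _ = fcs.qc_filter([fit], megfp_mean_cpm=30.0)
        assert fit.r_squared < 0.5
        assert retained == []

    def test_too_few_points_rejected(self):
        rec = fcs.AcfRecord(lags=np.arange(1, 6, dtype=float), acf_values=np.ones(5))
        with pytest.raises(ValueError):
            fcs.fit_acf(rec)


class TestVolumesAndConcentrations:
    def test_calibration_arithmetic(self, calibration):
        # V = 15 / (50e-9 * N_A)
        assert calibration.effective_volume == pytest.approx(
            15.0 / (50e-9 * AVOGADRO), rel=1e-12
        )
        assert calibration.effective_volume == pytest.approx(4.98e-16, rel=1e-3)

    def test_calibration_rejects_degenerate_fits(self):
        bad = make_fit(n=0.0)
        with pytest.raises(ValueError):
            fcs.calibrate_confocal_volume(bad, 50.0)
        with pytest.raises(ValueError):
            fcs.calibrate_confocal_volume(make_fit(), 0.0)

    def test_calibration_linearity(self):
        v1 = fcs.calibrate_confocal_volume(make_fit(n=10), 50.0).effective_volume
        v2 = fcs.calibrate_confocal_volume(make_fit(n=20), 50.0).effective_volume
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_concentration_calibration_identity(self, calibration):
        assert fcs.concentration_from_fit(make_fit(n=15.0), calibration) == (
            pytest.approx(50.0, rel=1e-12)
        )

    def test_concentration_arithmetic(self, calibration):
        conc = fcs.concentration_from_fit(make_fit(n=66.0), calibration)
        assert conc == pytest.approx(66.0 / (calibration.effective_volume * AVOGADRO) / 1e-9)
        assert conc == pytest.approx(220.0, rel=1e-3)
        assert fcs.concentration_from_fit(make_fit(n=0.0), calibration) == 0.0

    def test_concentration_requires_calibration(self):
        with pytest.raises(ValueError):
            fcs.concentration_from_fit(make_fit(), None)

    def test_copies_arithmetic(self):
        assert fcs.copies_from_concentration(0.0, 100.0) == 0.0
        # 330 nM in a 1262 µm³ nucleus: the published G1 nuclear SCC1 numbers
        copies = fcs.copies_from_concentration(330.0, 1262.0)
        assert copies == pytest.approx(330e-9 * 1262e-15 * AVOGADRO, rel=1e-12)
        assert copies == pytest.approx(250_755, rel=0.01)
        assert fcs.copies_from_concentration(330.0, 2 * 1262.0) == (
            pytest.approx(2 * copies, rel=1e-12)
        )

    def test_copies_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fcs.copies_from_concentration(-1.0, 100.0)
        with pytest.raises(ValueError):
            fcs.copies_from_concentration(1.0, 0.0)

    def test_cytoplasmic_volume(self):
        geom = fcs.CellGeometry("c1", v_nucleus=1000.0, v_ratio=3.04)
        assert fcs.cytoplasmic_volume(geom) == pytest.approx(2040.0)
        geom2 = fcs.CellGeometry("c2", v_nucleus=500.0, v_ratio=5.72)
        assert fcs.cytoplasmic_volume(geom2) == pytest.approx(2360.0)
        with pytest.raises(ValueError):
            fcs.CellGeometry("c3", v_nucleus=500.0, v_ratio=1.0)

    def test_copy_number_conservation_across_compartments(self, calibration):
        """Nuclear + cytoplasmic copies equal concentration x total volume."""
        geom = fcs.CellGeometry("c1", v_nucleus=1262.0, v_ratio=3.04)
        conc = 330.0
        nuc = fcs.copies_from_concentration(conc, geom.v_nucleus)
        cyt = fcs.copies_from_concentration(conc, fcs.cytoplasmic_volume(geom))
        total = fcs.copies_from_concentration(conc, geom.v_nucleus * geom.v_ratio)
        assert nuc + cyt == pytest.approx(total, rel=1e-12)


class TestQcFilter:
    def test_r_squared_threshold(self):
        retained, report = fcs.qc_filter([make_fit(r2=0.90)], megfp_mean_cpm=30.0)
        assert retained == [] and report.n_fail_r2 == 1

    def test_chisq_threshold(self):
        retained, report = fcs.qc_filter([make_fit(chisq=1.3)], megfp_mean_cpm=30.0)
        assert retained == [] and report.n_fail_chisq == 1

    def test_identical_passing_fits_all_retained(self):
        fits = [make_fit() for _ in range(10)]
        retained, report = fcs.qc_filter(fits, megfp_mean_cpm=30.0)
        assert report.retained_fraction == 1.0
        assert len(retained) == 10

    def test_cpm_cap_removes_bright_aggregates(self):
        fits = [make_fit(cpm=30.0) for _ in range(10)] + [make_fit(cpm=400.0)]
        retained, report = fcs.qc_filter(fits, megfp_mean_cpm=30.0)
        # 400 kHz >= 10 x 30 kHz reference; also a Tukey outlier
        assert len(retained) == 10
        assert report.n_cpm_outlier + report.n_cpm_cap == 1

    def test_failed_fits_counted_not_raised(self):
        retained, report = fcs.qc_filter(
            [make_fit(success=False), make_fit()], megfp_mean_cpm=30.0
        )
        assert report.n_failed_fit == 1 and len(retained) == 1

    def test_empty_input(self):
        retained, report = fcs.qc_filter([], megfp_mean_cpm=30.0)
        assert retained == [] and report.n_input == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        r2s=st.lists(st.floats(0.5, 1.0), min_size=1, max_size=20),
        loosen=st.floats(0.0, 0.3),
    )
    def test_loosening_thresholds_never_shrinks_retained_set(self, r2s, loosen):
        fits = [make_fit(r2=r2) for r2 in r2s]
        strict = fcs.QcThresholds()
        loose = fcs.QcThresholds(
            r2_min=strict.r2_min - loosen,
            chisq_max=strict.chisq_max + loosen,
            tukey_k=strict.tukey_k + loosen,
            cpm_cap=strict.cpm_cap + loosen,
        )
        kept_strict, _ = fcs.qc_filter(fits, 30.0, strict)
        kept_loose, _ = fcs.qc_filter(fits, 30.0, loose)
        assert set(id(f) for f in kept_strict) <= set(id(f) for f in kept_loose)


class TestSummaries:
    def test_percentiles_match_brute_force_interpolation(self):
        values = np.arange(1, 101, dtype=float)
        summary = fcs.summarize_condition(values)

        def brute_percentile(sorted_vals, q):
            # linear interpolation between order statistics
            pos = q / 100 * (len(sorted_vals) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (pos - lo) * (sorted_vals[hi] - sorted_vals[lo])

        assert summary.median == pytest.approx(50.5)
        assert summary.interval_68[0] == pytest.approx(brute_percentile(values, 16))
        assert summary.interval_68[1] == pytest.approx(brute_percentile(values, 84))
        assert summary.interval_68 == (pytest.approx(16.84), pytest.approx(84.16))

    def test_degenerate_summaries(self):
        s = fcs.summarize_condition([7.0, 7.0, 7.0])
        assert s.median == 7.0 and s.interval_68 == (7.0, 7.0)
        single = fcs.summarize_condition([3.0])
        assert single.interval_68 == (3.0, 3.0)
        with pytest.raises(ValueError):
            fcs.summarize_condition([])

    def test_cpm_stoichiometry(self):
        ref = [28.0, 30.0, 32.0]
        assert fcs.cpm_stoichiometry(ref, ref) == 1.0
        assert fcs.cpm_stoichiometry([2 * c for c in ref], ref) == 2.0
        rng = np.random.default_rng(2)
        protein = rng.normal(30, 3, 100)
        megfp = rng.normal(30, 3, 100)
        assert 0.9 <= fcs.cpm_stoichiometry(protein, megfp) <= 1.1
        with pytest.raises(ValueError):
            fcs.cpm_stoichiometry(ref, [0.0, 0.0, 0.0])


class TestBootstrap:
    def test_identical_constant_samples(self):
        result = fcs.bootstrap_method_ratio([5.0] * 4, [5.0] * 4, n_boot=100, seed=0)
        assert result.median == 1.0
        assert result.interval_68 == (1.0, 1.0)

    def test_constant_factor_two(self):
        result = fcs.bootstrap_method_ratio([8.0] * 4, [4.0] * 4, n_boot=100, seed=0)
        assert result.median == 2.0

    def test_normal_samples_ratio_near_analytic(self):
        rng = np.random.default_rng(3)
        a = rng.normal(150, 10, 100)
        b = rng.normal(100, 10, 100)
        result = fcs.bootstrap_method_ratio(a, b, n_boot=100_000, seed=4)
        assert result.median == pytest.approx(1.5, rel=0.02)

    def test_zero_denominator_pairs_redrawn(self):
        a = [1.0, 2.0]
        b = [0.0, 4.0]  # some resampled medians are zero
        result = fcs.bootstrap_method_ratio(a, b, n_boot=2000, seed=5)
        assert result.n_redrawn > 0
        assert np.isfinite(result.median)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fcs.bootstrap_method_ratio([], [1.0], n_boot=10)
        with pytest.raises(ValueError):
            fcs.bootstrap_method_ratio([1.0], [1.0], n_boot=0)
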