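"""iFRAP normalisation, exponential fitting, model selection and partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohesinquant import frap
from cohesinquant import synthetic as syn
from cohesinquant.constants import FCS_COPIES, FRAP_PARTITION_COPIES


def noiseless_curve(**kwargs) -> frap.FrapCurve:
    truth = syn.FrapTruth(noise_sd=0.0, n_cells=1, **kwargs)
    return syn.simulate_frap_experiment(truth)[0]


class TestNormalize:
    def test_anchor_is_exactly_one(self):
        norm = frap.normalize_ifrap(noiseless_curve(soluble_frac=0.3))
        assert norm.signal[0] == 1.0

    def test_fully_exchanged_tail_decays_to_zero(self):
        norm = frap.normalize_ifrap(
            noiseless_curve(k_off_dynamic=2.0, times=tuple(float(t) for t in range(31)))
        )
        assert norm.signal[-1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_generating_decay(self):
        truth = syn.FrapTruth(
            soluble_frac=0.27, stable_frac_of_bound=0.5, k_off_dynamic=0.1,
            noise_sd=0.0, n_cells=1,
        )
        curve = syn.simulate_frap_experiment(truth)[0]
        norm = frap.normalize_ifrap(curve)
        np.testing.assert_allclose(
            norm.signal, truth.difference_decay(norm.times), rtol=1e-10
        )

    def test_too_few_frames_rejected(self):
        curve = frap.FrapCurve(
            "c", times=[0.0, 1.0], bleached_signal=[0.1, 0.2],
            unbleached_signal=[0.9, 0.8], prebleach_mean=1.0,
        )
        with pytest.raises(ValueError):
            frap.normalize_ifrap(curve)


class TestExponentialFits:
    def test_single_exponential_exact_recovery(self):
        norm = frap.normalize_ifrap(noiseless_curve(k_off_dynamic=1 / 13.7))
        fit = frap.fit_single_exponential(norm)
        assert fit.residence_dynamic == pytest.approx(13.7, rel=1e-6)

    def test_constant_signal_pins_rate_at_lower_bound(self):
        norm = frap.NormalizedFrap(
            "c", "G1", np.arange(0.0, 30.0), np.ones(30)
        )
        with pytest.warns(UserWarning, match="no detectable recovery"):
            fit = frap.fit_single_exponential(norm)
        assert fit.k_off_1 <= 1.1e-6

    def test_noisy_cells_recover_g1_residence(self):
        truth = syn.FrapTruth(
            stable_frac_of_bound=0.0, k_off_dynamic=1 / 13.7, noise_sd=0.03,
            n_cells=19, seed=13,
        )
        residences = [
            frap.fit_single_exponential(frap.normalize_ifrap(c)).residence_dynamic
            for c in syn.simulate_frap_experiment(truth)
        ]
        assert np.mean(residences) == pytest.approx(13.7, rel=0.10)

    def test_double_exponential_exact_recovery(self):
        norm = frap.normalize_ifrap(
            noiseless_curve(
                stable_frac_of_bound=0.51, k_off_dynamic=0.1,
                k_off_stable=1 / (8.6 * 60),
            )
        )
        fit = frap.fit_double_exponential(norm)
        assert fit.a == pytest.approx(0.49, abs=1e-4)
        assert fit.residence_dynamic == pytest.approx(10.0, rel=1e-3)
        assert fit.residence_stable == pytest.approx(8.6, rel=1e-3)
        assert not fit.pinned
        assert fit.k_off_1 > fit.k_off_2

    def test_slow_residence_outside_box_is_pinned_and_flagged(self):
        norm = frap.normalize_ifrap(
            noiseless_curve(
                stable_frac_of_bound=0.5, k_off_dynamic=0.1,
                k_off_stable=1 / (30 * 60),  # 30 h truth, box ends at 15 h
            )
        )
        fit = frap.fit_double_exponential(norm)
        assert fit.residence_stable == pytest.approx(15.0, rel=1e-6)
        assert fit.pinned

    def test_double_reduces_to_single_for_pure_single_truth(self):
        norm = frap.normalize_ifrap(noiseless_curve(k_off_dynamic=1 / 13.7))
        single = frap.fit_single_exponential(norm)
        double = frap.fit_double_exponential(norm)
        assert double.a == pytest.approx(1.0, abs=1e-6)
        assert double.k_off_1 == pytest.approx(single.k_off_1, abs=1e-6)


class TestModelSelection:
    def test_single_truth_selects_single(self):
        truth = syn.FrapTruth(
            stable_frac_of_bound=0.0, k_off_dynamic=1 / 13.7, noise_sd=0.03,
            n_cells=10, seed=17,
        )
        n_single = 0
        for c in syn.simulate_frap_experiment(truth):
            norm = frap.normalize_ifrap(c)
            chosen = frap.select_model(
                frap.fit_single_exponential(norm), frap.fit_double_exponential(norm)
            )
            n_single += chosen.model == "single"
        assert n_single >= 7  # parsimony wins for single-exponential truth

    def test_double_truth_selects_double(self):
        truth = syn.FrapTruth(
            soluble_frac=0.27, stable_frac_of_bound=0.5, k_off_dynamic=0.1,
            k_off_stable=1 / (8.6 * 60), noise_sd=0.03, n_cells=10,
            condition="G2", seed=18,
        )
        for c in syn.simulate_frap_experiment(truth):
            norm = frap.normalize_ifrap(c)
            chosen = frap.select_model(
                frap.fit_single_exponential(norm), frap.fit_double_exponential(norm)
            )
            assert chosen.model == "double"

    def test_equal_scores_prefer_single(self):
        single = frap.FrapFit(model="single", k_off_1=0.1, aicc=-100.0)
        double = frap.FrapFit(
            model="double", k_off_1=0.1, k_off_2=0.01, a=0.5, aicc=-100.0
        )
        assert frap.select_model(single, double).model == "single"

    def test_both_failed_raises(self):
        single = frap.FrapFit(model="single", k_off_1=0.1, success=False)
        double = frap.FrapFit(
            model="double", k_off_1=0.1, k_off_2=0.01, a=0.5, success=False
        )
        with pytest.raises(ValueError):
            frap.select_model(single, double)


class TestSolubleFraction:
    def test_no_drop_gives_zero(self):
        assert frap.soluble_fraction(100.0, 100.0, 0.5) == 0.0

    def test_g2_example(self):
        assert frap.soluble_fraction(100.0, 86.5, 0.5) == pytest.approx(0.27)

    def test_full_drop_clips_to_one(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert frap.soluble_fraction(100.0, 40.0, 0.5) == 1.0
        assert frap.soluble_fraction(100.0, 50.0, 0.5) == pytest.approx(1.0)

    def test_negative_drop_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert frap.soluble_fraction(100.0, 110.0, 0.5) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            frap.soluble_fraction(0.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            frap.soluble_fraction(1.0, 1.0, 1.0)


class TestPartition:
    def test_g1_single_model_partition(self):
        fit = frap.FrapFit(model="single", k_off_1=1 / 13.7)
        fractions = frap.partition_populations(0.365, fit)
        assert fractions.soluble == pytest.approx(0.365)
        assert fractions.dynamic == pytest.approx(0.635)
        assert fractions.stable == pytest.approx(0.0, abs=1e-12)

    def test_g2_double_model_partition(self):
        fit = frap.FrapFit(model="double", k_off_1=0.1, k_off_2=0.002, a=0.493)
        fractions = frap.partition_populations(0.27, fit)
        assert fractions.dynamic == pytest.approx(0.36, abs=0.005)
        assert fractions.stable == pytest.approx(0.37, abs=0.005)

    def test_all_soluble(self):
        fit = frap.FrapFit(model="single", k_off_1=0.1)
        fractions = frap.partition_populations(1.0, fit)
        assert (fractions.soluble, fractions.dynamic, fractions.stable) == (1.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        soluble=st.floats(0.0, 1.0),
        a=st.floats(0.0, 1.0),
        copies=st.floats(1.0, 1e6),
    )
    def test_partition_conserves_copies_to_rounding(self, soluble, a, copies):
        fit = frap.FrapFit(model="double", k_off_1=0.1, k_off_2=0.002, a=a)
        fractions = frap.partition_populations(soluble, fit)
        part = frap.copy_number_partition(copies, fractions)
        ulp = np.spacing(part.total)
        assert abs(part.soluble + part.dynamic + part.stable - part.total) <= 2 * ulp

    def test_reproduces_published_g1_partition(self):
        nuclear = FCS_COPIES["SCC1"]["G1"]["nucleus"][0]
        fractions = frap.PopulationFractions(soluble=0.3642, dynamic=0.6358, stable=0.0)
        part = frap.copy_number_partition(nuclear, fractions)
        assert part.soluble == pytest.approx(
            FRAP_PARTITION_COPIES["G1"]["soluble"][0], rel=1e-3
        )
        assert part.dynamic == pytest.approx(
            FRAP_PARTITION_COPIES["G1"]["dynamic"][0], rel=1e-3
        )

    def test_reproduces_published_g2_partition(self):
        nuclear = FCS_COPIES["SCC1"]["G2"]["nucleus"][0]
        fractions = frap.PopulationFractions(soluble=0.27, dynamic=0.36, stable=0.37)
        part = frap.copy_number_partition(nuclear, fractions)
        for pool in ("soluble", "dynamic", "stable"):
            assert getattr(part, pool) == pytest.approx(
                FRAP_PARTITION_COPIES["G2"][pool][0], rel=0.01
            )

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            frap.PopulationFractions(soluble=0.5, dynamic=0.6, stable=0.2)


class TestExperimentPipeline:
    def test_g2_experiment_recovers_fractions(self):
        truth = syn.FrapTruth(
            soluble_frac=0.27, stable_frac_of_bound=0.5, k_off_dynamic=0.1,
            k_off_stable=1 / (8.6 * 60), noise_sd=0.03, n_cells=19,
            condition="G2", seed=4,
        )
        fractions, fits = frap.estimate_population_fractions(
            syn.simulate_frap_experiment(truth)
        )
        assert fractions.soluble == pytest.approx(0.27, abs=0.05)
        assert fractions.dynamic == pytest.approx(0.365, abs=0.05)
        assert fractions.stable == pytest.approx(0.365, abs=0.05)
        assert fractions.soluble_sd is not None

    def test_large_cohort_median_residence_recovery(self):
        """Published-style recovery: 200 noisy cells, 15% on residence times."""
        truth = syn.FrapTruth(
            soluble_frac=0.27, stable_frac_of_bound=0.5, k_off_dynamic=0.1,
            k_off_stable=1 / (8.6 * 60), noise_sd=0.03, n_cells=200,
            condition="G2", seed=9,
        )
        _, fits = frap.estimate_population_fractions(
            syn.simulate_frap_experiment(truth)
        )
        doubles = [f for f in fits if f.model == "double"]
        assert len(doubles) > 150
        assert np.median([f.residence_dynamic for f in doubles]) == pytest.approx(
            10.0, rel=0.15
        )
        assert np.median([f.residence_stable for f in doubles]) == pytest.approx(
            8.6, rel=0.15
        )
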