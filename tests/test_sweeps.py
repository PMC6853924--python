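import math

import numpy as np
import pytest

from clonesweep.ccf import annotate_sample
from clonesweep.data_io import assemble_tumor_sample
from clonesweep.sweeps import (
    Regime,
    SelectionFitConfig,
    SweepParams,
    adaptive_frequency,
    establishment_frequency,
    estimate_selection,
    fixation_grid,
    passenger_frequency,
    simulate_sweep_spectrum,
    subclone_fraction,
    subclone_fraction_general,
    time_to_frequency,
)
from clonesweep.synthetic import SimTumorConfig, simulate_cohort


def naive_subclone_fraction(s, t):
    return math.exp(s * t) / (math.exp(t) + math.exp(s * t))


def naive_adaptive(s, t, N):
    return math.exp(s * t) / (math.exp(s * t) + 2 * N * s)


class TestFixationModel:
    def test_half_at_time_zero_and_neutral(self):
        for s in (0.2, 1.0, 2.0, 7.3):
            assert subclone_fraction(s, 0.0) == 0.5
        for t in (0.0, 1.0, 50.0, 1e4):
            assert subclone_fraction(1.0, t) == 0.5

    def test_closed_form_value(self):
        # s=2, t=10: e^{2t}/(e^t + e^{2t}) = 1/(1 + e^{-10})
        assert subclone_fraction(2.0, 10.0) == pytest.approx(1 / (1 + math.exp(-10)), abs=1e-12)

    def test_matches_naive_where_naive_is_finite(self):
        for s in (0.5, 1.3, 2.0):
            for t in (0.1, 5.0, 50.0):
                assert subclone_fraction(s, t) == pytest.approx(
                    naive_subclone_fraction(s, t), abs=1e-10
                )

    def test_log_space_stable_for_large_st(self):
        assert subclone_fraction(5.0, 1000.0) == 1.0
        assert 0.0 <= subclone_fraction(0.01, 1000.0) <= 1.0

    def test_monotone_in_time(self):
        ts = np.linspace(0, 30, 50)
        rising = [subclone_fraction(1.5, t) for t in ts]
        falling = [subclone_fraction(0.7, t) for t in ts]
        assert np.all(np.diff(rising) > 0)
        assert np.all(np.diff(falling) < 0)


class TestGeneralizedFixation:
    def test_reduces_to_basic_form(self):
        for s in (0.5, 1.0, 2.0):
            for t in (0.0, 3.0, 20.0):
                assert subclone_fraction_general(s, t, 0.0, 0.5) == pytest.approx(
                    subclone_fraction(s, t), abs=1e-12
                )

    def test_neutral_keeps_initial_fraction(self):
        for t in (0.0, 10.0, 200.0):
            assert subclone_fraction_general(1.0, t, 0.0, 0.2) == pytest.approx(0.2)

    def test_rare_fit_clone_sweeps(self):
        assert subclone_fraction_general(2.0, 100.0, 0.0, 1e-6) == pytest.approx(1.0)

    def test_time_before_origin_rejected(self):
        with pytest.raises(ValueError):
            subclone_fraction_general(2.0, 1.0, 5.0, 0.5)


class TestFixationGrid:
    def test_neutral_row_never_fixes(self):
        _, fixed = fixation_grid([1.0], [0.0, 5.0, 50.0], tumor_age=100.0)
        assert not fixed.any()

    def test_flags_monotone_in_s(self):
        fracs, fixed = fixation_grid(
            [1.0, 1.02, 1.05, 1.1, 1.5, 2.0], [5.0], tumor_age=100.0
        )
        col = fixed[:, 0].astype(int)
        assert np.all(np.diff(col) >= 0)
        assert np.all(np.diff(fracs[:, 0]) >= 0)

    def test_high_fitness_fixes_at_study_ages(self):
        # tumor age 100 generations, subclone arising at generation 5
        fracs, fixed = fixation_grid([1.02, 2.0], [5.0], tumor_age=100.0)
        assert fixed[1, 0] and not fixed[0, 0]


class TestAdaptiveTrajectory:
    def test_establishment_values(self):
        assert establishment_frequency(500, 1.0) == pytest.approx(1e-3)
        assert establishment_frequency(500, 2.0) == pytest.approx(5e-4)
        assert establishment_frequency(500, 1e10) < 1e-12

    def test_initial_frequency(self):
        for N, s in ((500, 2.0), (1e6, 1.1)):
            assert adaptive_frequency(s, 0.0, N) == pytest.approx(
                1 / (1 + 2 * N * s), abs=1e-12
            )

    def test_asymptote_and_half_time(self):
        assert adaptive_frequency(2.0, 1e4, 500) == pytest.approx(1.0)
        t_half = math.log(2 * 500 * 2.0) / 2.0
        assert adaptive_frequency(2.0, t_half, 500) == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive(self):
        for t in (0.0, 3.0, 10.0):
            assert adaptive_frequency(1.5, t, 1e4) == pytest.approx(
                naive_adaptive(1.5, t, 1e4), abs=1e-10
            )

    def test_time_inversion_round_trip(self):
        for target in (0.1, 0.5, 0.95, 0.999):
            t = time_to_frequency(target, 2.0, 1e6)
            assert adaptive_frequency(2.0, t, 1e6) == pytest.approx(target, abs=1e-9)

    def test_unreachable_frequency_rejected(self):
        with pytest.raises(ValueError):
            time_to_frequency(1e-9, 2.0, 1e6)  # below establishment


class TestPassengerSpectrum:
    def test_mu_equals_s_collapses_to_decay(self):
        for i in (1, 5, 100):
            assert passenger_frequency(i, 7.0, 0.5, 0.5) == pytest.approx(
                math.exp(-0.5 * 7.0), abs=1e-12
            )

    def test_decreasing_in_rank(self):
        vals = [passenger_frequency(i, 5.0, 2.0, 0.001) for i in range(1, 50)]
        assert np.all(np.diff(vals) < 0)

    def test_printed_parameter_value(self):
        # i=1, s=2, mu=0.001, t=0: (0.0005)^0.9995
        expected = math.exp((1 - 0.001 / 2) * math.log(0.001 / 2))
        assert passenger_frequency(1, 0.0, 2.0, 0.001) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5.019e-4, rel=1e-3)

    def test_mu_above_s_rejected(self):
        with pytest.raises(ValueError):
            passenger_frequency(1, 1.0, 0.5, 1.0)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            passenger_frequency(0, 1.0, 2.0, 0.001)


class TestSweepSpectrumSimulation:
    def test_hard_sweep_is_faster(self):
        hard = simulate_sweep_spectrum(SweepParams(s=2.0), 20, 0.95)
        soft = simulate_sweep_spectrum(SweepParams(s=1.1), 20, 0.95)
        assert hard.t_obs < soft.t_obs

    def test_soft_spectrum_uniformly_higher(self):
        hard = simulate_sweep_spectrum(SweepParams(s=2.0), 50, 0.95)
        soft = simulate_sweep_spectrum(SweepParams(s=1.1), 50, 0.95)
        assert np.all(soft.passenger_freqs > hard.passenger_freqs)

    def test_driver_ccf_one_warns_and_clips(self):
        with pytest.warns(UserWarning):
            spec = simulate_sweep_spectrum(SweepParams(s=2.0), 5, 1.0)
        assert spec.driver_freq == pytest.approx(1.0 - 1e-9)

    def test_deterministic(self):
        a = simulate_sweep_spectrum(SweepParams(s=1.5), 10, 0.9)
        b = simulate_sweep_spectrum(SweepParams(s=1.5), 10, 0.9)
        np.testing.assert_array_equal(a.passenger_freqs, b.passenger_freqs)


class TestSelectionEstimation:
    def test_exact_recovery_from_noise_free_spectra(self):
        for s_true, regime in ((2.0, Regime.HARD), (1.1, Regime.SOFT)):
            spec = simulate_sweep_spectrum(SweepParams(s=s_true), 50, 0.95)
            est = estimate_selection(spec.passenger_freqs, 0.95)
            assert est.s_hat == pytest.approx(s_true, abs=0.01)
            assert est.regime is regime

    def test_structureless_ccfs_go_neutral(self):
        rng = np.random.default_rng(1)
        est = estimate_selection(rng.uniform(0.05, 0.9, 60), 0.95)
        assert est.regime is Regime.NEUTRAL

    def test_too_few_passengers_flagged(self):
        est = estimate_selection([0.3, 0.2], 0.95)
        assert est.regime is None and est.flag is not None

    def test_recovery_with_read_noise_at_resolvable_frequencies(self):
        """Hard/soft separation works once hitch-hikers are deep enough to see.

        With mu large enough that passenger frequencies sit well above the
        read-sampling floor, the rank-spectrum fit separates s=2.0 from
        s=1.1 reliably.
        """
        cfg = SelectionFitConfig(mu=0.05, N=1000)
        correct = 0
        s_hats = {"HARD": [], "SOFT": []}
        n = 15
        cohort = simulate_cohort(
            {"HARD": n, "SOFT": n},
            SimTumorConfig(mu=0.05, N=1000, mean_depth=10_000.0,
                           n_background_mutations=20, purity=1.0, driver_ccf=0.9),
            seed=202,
        )
        for sample, truth in cohort:
            joined = assemble_tumor_sample(
                sample.mutations, sample.segments, sample.purity, sample.sample_id
            )
            records = annotate_sample(joined)
            passengers = [r for r in records if r.mutation.gene is None]
            driver = max(r.ccf for r in records if r.mutation.gene)
            est = estimate_selection(passengers, driver, cfg)
            correct += est.regime is not None and est.regime.value == truth.regime.value
            if est.s_hat is not None:
                s_hats[truth.regime.value].append(est.s_hat)
        assert correct / (2 * n) >= 0.9
        assert np.median(s_hats["HARD"]) == pytest.approx(2.0, rel=0.25)
        assert np.median(s_hats["SOFT"]) == pytest.approx(1.1, rel=0.25)
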