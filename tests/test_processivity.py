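"""Ladder algebra: P_i, survival, processivity, amplitudes, partitions."""

import numpy as np
import pandas as pd
import pytest

from tlsquant.processivity import (
    Amplitude,
    BandLadder,
    InsertionProfile,
    KineticPartition,
    LadderError,
    ProcessivityModel,
    amplitude_from_timecourse,
    fold_stimulation,
    holoenzyme_fraction_remaining,
    insertion_probabilities,
    partition_rates,
    processivity_length,
    subtract_preincubation,
    tls_complex_survival,
)

from conftest import monte_carlo_ladder


def make_ladder(conc_by_pos, time=30.0, **kw):
    positions = np.arange(len(conc_by_pos))
    return BandLadder.from_arrays(np.full(positions.size, time), positions,
                                  np.asarray(conc_by_pos, dtype=float), **kw)


class TestSubtractPreincubation:
    def bg_frame(self, conc_by_pos):
        return pd.DataFrame({
            "time_s": 0.0,
            "position": np.arange(len(conc_by_pos)),
            "concentration_nM": conc_by_pos,
        })

    def test_zero_background_is_identity(self):
        lad = make_ladder([40, 60, 20, 15, 5])
        lad.background = self.bg_frame([0, 0, 0, 0, 0])
        out = subtract_preincubation(lad)
        np.testing.assert_allclose(out.data["concentration_nM"],
                                   lad.data["concentration_nM"])

    def test_background_equal_to_band_zeroes_it(self):
        lad = make_ladder([40, 60, 20, 15, 5])
        lad.background = self.bg_frame([0, 60, 0, 0, 0])
        out = subtract_preincubation(lad)
        assert out.bands(30.0)[1] == 0.0
        assert out.bands(30.0)[2] == 20.0

    def test_excess_background_clamps_with_warning(self):
        lad = make_ladder([40, 60, 20, 15, 5])
        lad.background = self.bg_frame([0, 60.1, 0, 0, 0])
        with pytest.warns(UserWarning, match="clamped"):
            out = subtract_preincubation(lad)
        assert out.bands(30.0)[1] == 0.0

    def test_primer_band_never_subtracted(self):
        lad = make_ladder([40, 60, 20, 15, 5])
        lad.background = self.bg_frame([39, 0, 0, 0, 0])
        out = subtract_preincubation(lad)
        assert out.bands(30.0)[0] == 40.0

    def test_mismatched_positions_rejected(self):
        lad = make_ladder([40, 60, 20])
        lad.background = self.bg_frame([0, 0, 0, 0, 5])
        with pytest.raises(LadderError):
            subtract_preincubation(lad)


class TestInsertionProbabilities:
    def test_hand_computed_example(self):
        # B1..B4 = 60, 20, 15, 5 nM
        lad = make_ladder([0, 60, 20, 15, 5])
        prof = insertion_probabilities(lad, 30.0)
        np.testing.assert_allclose(prof.p_i, [0.400, 0.500, 0.250], atol=1e-12)
        assert prof.p2 == pytest.approx(0.400)

    def test_monte_carlo_oracle_cross_check(self, rng):
        # molecule-level chain with the same termination probabilities
        p_true = {2: 0.4, 3: 0.5, 4: 0.25}
        counts = monte_carlo_ladder(p_true, 200_000, rng)
        lad = make_ladder(counts.astype(float))
        prof = insertion_probabilities(lad, 30.0)
        for step, p in zip(prof.step, prof.p_i):
            assert p == pytest.approx(p_true[step], abs=0.01)

    def test_all_product_at_position_one_gives_zero_p2(self):
        prof = insertion_probabilities(make_ladder([10, 90]), 30.0)
        np.testing.assert_allclose(prof.p_i, [0.0])
        assert prof.p2 == 0.0

    def test_all_product_at_max_position(self):
        prof = insertion_probabilities(make_ladder([0, 0, 0, 0, 50]), 30.0)
        np.testing.assert_allclose(prof.p_i, [1.0, 1.0, 1.0])

    def test_exact_distribution_round_trip(self):
        # expected band pattern from known {P_i} returns them exactly
        p_true = {2: 0.215, 3: 0.30, 4: 0.45, 5: 0.30, 6: 0.15}
        jmax = max(p_true)
        conc = np.zeros(jmax + 1)
        surv = 1.0
        for j in range(1, jmax + 1):
            p_next = p_true.get(j + 1, 0.0)
            conc[j] = surv * (1 - p_next)
            surv *= p_next
        lad = make_ladder(conc * 10.0)
        prof = insertion_probabilities(lad, 30.0, noise_floor_fraction=0.0)
        np.testing.assert_allclose(
            prof.p_i, [p_true[i] for i in range(2, jmax + 1)], atol=1e-12)

    def test_noise_floor_truncates_sparse_tail(self):
        lad = make_ladder([0, 99.5, 0.3, 0.15, 0.05])
        prof = insertion_probabilities(lad, 30.0, noise_floor_fraction=0.01)
        assert prof.step.max() == 2  # denominators past i=2 are sub-floor

    def test_all_unextended_is_error(self):
        with pytest.raises(LadderError):
            insertion_probabilities(make_ladder([100, 0, 0]), 30.0)


class TestSurvival:
    def test_methods_formula_instance(self):
        # y after 2 further insertions = P3 * P4 = 0.5 * 0.25
        prof = InsertionProfile(np.array([2, 3, 4]), np.array([0.4, 0.5, 0.25]))
        surv = tls_complex_survival(prof)
        np.testing.assert_allclose(surv.fraction_remaining, [1.0, 0.5, 0.125])

    def test_all_ones_survive_fully(self):
        prof = InsertionProfile(np.arange(2, 7), np.ones(5))
        np.testing.assert_allclose(
            tls_complex_survival(prof).fraction_remaining, 1.0)

    def test_zero_step_kills_downstream(self):
        prof = InsertionProfile(np.array([2, 3, 4, 5]),
                                np.array([0.5, 0.4, 0.0, 0.9]))
        surv = tls_complex_survival(prof)
        np.testing.assert_allclose(surv.fraction_remaining[2:], 0.0)

    def test_survival_identity_against_band_tails(self):
        # y(i) equals the tail-sum ratio of the noise-free distribution
        conc = np.array([0.0, 60.0, 20.0, 15.0, 5.0])
        lad = make_ladder(conc)
        prof = insertion_probabilities(lad, 30.0, noise_floor_fraction=0.0)
        surv = tls_complex_survival(prof)
        tail = np.array([conc[i:].sum() for i in surv.step])
        np.testing.assert_allclose(surv.fraction_remaining,
                                   tail / conc[2:].sum(), atol=1e-12)

    def test_non_contiguous_profile_rejected(self):
        with pytest.raises(ValueError):
            InsertionProfile(np.array([2, 4]), np.array([0.5, 0.5]))


class TestProcessivityLength:
    def test_replicative_polymerase_plateau(self):
        out = processivity_length(0.999, 0.010)
        assert out.rounded == 4600
        assert 0.999 ** 4600 == pytest.approx(0.010, abs=5e-4)

    def test_simple_cases(self):
        assert processivity_length(0.5, 0.5).raw == pytest.approx(1.0)
        assert processivity_length(0.99, 0.010).raw == pytest.approx(458.2, abs=0.5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_probability_rejected(self, p):
        with pytest.raises(ValueError):
            processivity_length(p)


class TestAmplitude:
    def test_constant_series(self):
        t = np.array([2.0, 15.0, 30.0, 60.0])
        amp = amplitude_from_timecourse(t, np.full(4, 0.42))
        assert amp.value == pytest.approx(0.42)
        assert amp.sd == pytest.approx(0.0)

    def test_mean_of_post_cutoff_points(self):
        amp = amplitude_from_timecourse([5.0, 15.0, 30.0], [0.1, 0.40, 0.44])
        assert amp.value == pytest.approx(0.42)
        assert amp.n_points == 2

    def test_no_qualifying_points_is_error(self):
        with pytest.raises(ValueError):
            amplitude_from_timecourse([1.0, 5.0, 9.0], [0.1, 0.2, 0.3])


class TestFoldStimulation:
    def test_simple_ratio(self):
        fold, sd = fold_stimulation(0.84, 0.42)
        assert fold == pytest.approx(2.0)
        assert sd == 0.0

    def test_equal_amplitudes(self):
        assert fold_stimulation(0.37, 0.37)[0] == pytest.approx(1.0)

    def test_uncertainty_quadrature(self):
        a = Amplitude(0.8, 0.08, 3)
        b = Amplitude(0.4, 0.02, 3)
        fold, sd = fold_stimulation(a, b)
        assert fold == pytest.approx(2.0)
        assert sd == pytest.approx(2.0 * np.hypot(0.1, 0.05), rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_stimulation(0.5, 0.0)


class TestHoloenzymeFraction:
    def test_all_full_length(self):
        lad = make_ladder([10, 0, 0, 0, 90], full_length_position=4)
        assert holoenzyme_fraction_remaining(lad) == pytest.approx(1.0)

    def test_partial_full_length(self):
        lad = make_ladder([0, 30, 25, 15, 30], full_length_position=4)
        assert holoenzyme_fraction_remaining(lad) == pytest.approx(0.30)

    def test_requires_full_length_position(self):
        with pytest.raises(LadderError):
            holoenzyme_fraction_remaining(make_ladder([0, 50, 50]))


class TestKineticPartition:
    def test_high_processivity_partition(self):
        part = partition_rates(0.999, 100.0)
        assert part.k_off == pytest.approx(0.1001, abs=1e-4)
        assert part.k_pol / part.k_off > 700.0

    def test_even_partition(self):
        part = partition_rates(0.5, 10.0)
        assert part.k_off == pytest.approx(10.0)

    def test_inverse_identity(self):
        part = partition_rates(0.73, 42.0)
        back = KineticPartition.from_rates(part.k_pol, part.k_off)
        assert back.p == pytest.approx(0.73, abs=1e-12)

    def test_identity_enforced_on_construction(self):
        with pytest.raises(ValueError):
            KineticPartition(k_pol=10.0, k_off=10.0, p=0.9)


class TestProcessivityModel:
    def test_end_to_end_with_background(self):
        data = pd.DataFrame({
            "time_s": [30.0] * 5 + [60.0] * 5,
            "position": list(range(5)) * 2,
            "concentration_nM": [40, 61, 20.5, 15, 5, 40, 61, 20.5, 15, 5],
        })
        bg = pd.DataFrame({
            "time_s": 0.0, "position": range(5),
            "concentration_nM": [0, 1.0, 0.5, 0, 0],
        })
        res = ProcessivityModel(BandLadder(data, background=bg)).fit()
        np.testing.assert_allclose(res.profile.p_i, [0.4, 0.5, 0.25],
                                   atol=1e-12)
        assert res.survival.fraction_remaining[-1] == pytest.approx(0.125)
        assert "P_2" in res.summary()

    def test_ladder_validation(self):
        with pytest.raises(LadderError):
            BandLadder(pd.DataFrame({
                "time_s": [1.0, 1.0], "position": [0, 2],
                "concentration_nM": [1.0, 1.0]}))
        with pytest.raises(LadderError):
            BandLadder(pd.DataFrame({"time_s": [1.0], "position": [0]}))
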