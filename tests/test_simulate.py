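"""Synthetic generators: determinism, round trips, statistical calibration."""


import numpy as np
import pytest

from tlsquant.binding import OneSiteBindingModel
from tlsquant.competition import CompetitionCurve, DoseResponseModel, KiContext
from tlsquant.processivity import ProcessivityModel, holoenzyme_fraction_remaining
from tlsquant.simulate import (
    SimulationConfig,
    resolve_config,
    simulate_competition_curve,
    simulate_equilibrium_titration,
    simulate_exchange_series,
    simulate_single_turnover_ladder,
)
from tlsquant import io as tio


class TestDeterminism:
    @pytest.mark.parametrize("gen", [
        simulate_equilibrium_titration,
        simulate_competition_curve,
        simulate_single_turnover_ladder,
    ])
    def test_same_seed_same_output(self, gen):
        a = gen(SimulationConfig(seed=42))
        b = gen(SimulationConfig(seed=42))
        if hasattr(a, "signal"):
            np.testing.assert_array_equal(a.signal, b.signal)
        else:
            np.testing.assert_array_equal(a.data["concentration_nM"],
                                          b.data["concentration_nM"])

    def test_different_seed_differs(self):
        a = simulate_equilibrium_titration(SimulationConfig(seed=1))
        b = simulate_equilibrium_titration(SimulationConfig(seed=2))
        assert not np.array_equal(a.signal, b.signal)

    def test_csv_round_trip_is_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            curve = simulate_equilibrium_titration(SimulationConfig(seed=9))
            tio.write_titration_csv(curve, tmp_path / f"{run}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_written_files_parse_back(self, tmp_path):
        curve = simulate_equilibrium_titration(SimulationConfig(seed=3))
        tio.write_titration_csv(curve, tmp_path / "t.csv")
        back = tio.read_titration_csv(tmp_path / "t.csv", 20.0)
        np.testing.assert_allclose(back.signal, curve.signal)

        lad = simulate_single_turnover_ladder(SimulationConfig(seed=3))
        tio.write_ladder_csv(lad, tmp_path / "l.csv", tmp_path / "b.csv")
        back = tio.read_ladder_csv(tmp_path / "l.csv", tmp_path / "b.csv")
        np.testing.assert_allclose(back.data["concentration_nM"],
                                   lad.data["concentration_nM"])


class TestTitrationGenerator:
    def test_noiseless_round_trip(self):
        curve = simulate_equilibrium_titration(SimulationConfig(seed=0, noise="none"))
        res = OneSiteBindingModel(curve).fit(tol=1e-10)
        truth = resolve_config("titration", SimulationConfig())["truth"]
        assert res.kd == pytest.approx(truth["kd_nM"], rel=1e-6)

    def test_vanishing_substrate_matches_plain_hyperbola(self):
        cfg = SimulationConfig(seed=0, noise="none",
                               design={"substrate_total_nM": 1e-9})
        curve = simulate_equilibrium_titration(cfg)
        lt = curve.ligand_total
        expected = 0.05 + 1.0 * lt / (120.0 + lt)
        np.testing.assert_allclose(curve.signal, expected, rtol=1e-6)


class TestCompetitionGenerator:
    def test_flat_at_zero_competitor_grid(self):
        cfg = SimulationConfig(seed=0, noise="none",
                               design={"competitor_grid": [0.0] * 6})
        curve = simulate_competition_curve(cfg)
        # uninhibited signal C + R everywhere
        np.testing.assert_allclose(curve.signal, 1.0, rtol=1e-12)

    def test_noiseless_ki_round_trip_mild_depletion(self):
        # exchange-like conditions: shared species (10 nM) far below the
        # transition midpoint, so the logistic midpoint is faithful
        cfg = SimulationConfig(seed=0, noise="none",
                               design={"lt_nM": 10.0, "partner_nM": 50.0},
                               truth={"kd_nM": 7.1, "ki_nM": 31.7})
        curve = simulate_competition_curve(cfg)
        res = DoseResponseModel(curve).fit()
        ctx = KiContext.from_labeled_ligand(labeled_total=50.0,
                                            binder_total=10.0, kd_complex=7.1)
        assert res.ki(ctx).ki == pytest.approx(31.7, rel=0.05)

    def test_doubling_ki_doubles_ic50_to_first_order(self):
        base = dict(design={"lt_nM": 10.0, "partner_nM": 50.0,
                            "competitor_max_nM": 50000.0, "n_points": 14},
                    noise="none")
        ic = []
        for ki in (31.7, 63.4):
            cfg = SimulationConfig(seed=0, truth={"kd_nM": 7.1, "ki_nM": ki},
                                   **base)
            ic.append(DoseResponseModel(simulate_competition_curve(cfg)).fit().ic50)
        assert ic[1] / ic[0] == pytest.approx(2.0, rel=0.05)


class TestLadderGenerator:
    def test_all_ones_chain_puts_product_at_max(self):
        cfg = SimulationConfig(seed=0, noise="none",
                               truth={"p_i": {2: 1.0, 3: 1.0, 4: 1.0},
                                      "background_fractions": {}})
        lad = simulate_single_turnover_ladder(cfg)
        bands = lad.bands(60.0)
        assert bands[4] > 0
        np.testing.assert_allclose(bands[[1, 2, 3]], 0.0, atol=1e-12)

    def test_multinomial_recovery_within_three_se(self):
        p_true = {2: 0.4, 3: 0.5, 4: 0.25}
        n = 100_000
        cfg = SimulationConfig(seed=11, n_molecules=n,
                               truth={"p_i": p_true, "amplitude": 0.5})
        lad = simulate_single_turnover_ladder(cfg)
        res = ProcessivityModel(lad).fit()
        primer = 10.0
        bands = res.corrected_ladder.bands(res.time_point)
        for step, p_hat in zip(res.profile.step, res.profile.p_i):
            denom_n = bands[bands.index >= step - 1].sum() / primer * n
            se = np.sqrt(p_true[step] * (1 - p_true[step]) / denom_n)
            assert abs(p_hat - p_true[step]) < 3 * se + 1e-12

    def test_amplitude_factor_two_recovered(self):
        a = ProcessivityModel(simulate_single_turnover_ladder(
            SimulationConfig(seed=5))).fit().amplitude
        b = ProcessivityModel(simulate_single_turnover_ladder(
            SimulationConfig(seed=6, truth={"amplitude": 0.8}))).fit().amplitude
        from tlsquant.processivity import fold_stimulation
        fold, _ = fold_stimulation(b, a)
        assert fold == pytest.approx(2.0, rel=0.05)


class TestExchangeGenerator:
    def test_zero_competitor_full_survival(self):
        ladders, grid = simulate_exchange_series(
            SimulationConfig(seed=0, noise="none"))
        assert grid[0] == 0.0
        assert holoenzyme_fraction_remaining(ladders[0]) == pytest.approx(1.0)

    def test_saturating_competitor_kills_survival(self):
        cfg = SimulationConfig(seed=0, noise="none",
                               design={"competitor_max_nM": 5e6})
        ladders, grid = simulate_exchange_series(cfg)
        assert holoenzyme_fraction_remaining(ladders[-1]) < 0.02

    def test_noiseless_pipeline_recovers_exchange_ki(self):
        ladders, grid = simulate_exchange_series(
            SimulationConfig(seed=0, noise="none"))
        frac = np.array([holoenzyme_fraction_remaining(l) for l in ladders])
        res = DoseResponseModel(CompetitionCurve(grid, frac)).fit()
        ctx = KiContext.from_labeled_ligand(labeled_total=50.0,
                                            binder_total=10.0, kd_complex=7.1)
        assert res.ki(ctx).ki == pytest.approx(31.7, rel=0.05)


class TestStatisticalCalibration:
    def test_reported_se_matches_empirical_sd(self):
        # over many seeds at 2% noise the fit-reported K_D standard
        # error should track the empirical scatter within a factor 1.5
        kds, ses = [], []
        for seed in range(500):
            curve = simulate_equilibrium_titration(SimulationConfig(seed=seed))
            res = OneSiteBindingModel(curve).fit()
            kds.append(res.kd)
            ses.append(res.kd_stderr)
        empirical = np.std(kds, ddof=1)
        reported = np.median(ses)
        assert 1 / 1.5 < reported / empirical < 1.5
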