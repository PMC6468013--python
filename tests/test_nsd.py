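"""Displacement, movement-model classification, and migration characteristics."""

import numpy as np
import pandas as pd
import pytest

from herdtrack import nsd
from herdtrack import synthetic as syn
from herdtrack.nsd import DisplacementSeries
from tests.conftest import straight_track, year_track


def _series(t, nd, animal="x"):
    nd = np.abs(np.asarray(nd, dtype=float))
    return DisplacementSeries(animal, (0.0, 0.0), np.asarray(t, dtype=float), nd, nd**2)


def logistic(t, d, th, ph):
    return d / (1 + np.exp((th - t) / ph))


class TestComputeDisplacement:
    def test_constant_location_is_zero(self):
        tr = straight_track(n=10, speed_kmh=0.0)
        s = nsd.compute_displacement(tr)
        assert np.all(s.nd == 0)

    def test_three_four_five(self):
        ts = pd.date_range("2010-01-01", periods=2, freq="2h", tz="UTC")
        tr = syn.Track(
            "p", "F", "b",
            pd.DataFrame({"timestamp": ts, "x_km": [0.0, 3.0], "y_km": [0.0, 4.0]}),
        )
        s = nsd.compute_displacement(tr)
        assert s.nd[1] == pytest.approx(5.0)
        assert s.nsd[1] == pytest.approx(25.0)

    def test_matches_per_point_formula_on_random_fixes(self):
        rng = np.random.default_rng(8)
        xy = rng.normal(0, 5, size=(10, 2))
        ts = pd.date_range("2010-01-01", periods=10, freq="2h", tz="UTC")
        tr = syn.Track(
            "r", "F", "b",
            pd.DataFrame({"timestamp": ts, "x_km": xy[:, 0], "y_km": xy[:, 1]}),
        )
        s = nsd.compute_displacement(tr)
        brute = [np.sqrt((x - xy[0, 0]) ** 2 + (y - xy[0, 1]) ** 2) for x, y in xy]
        np.testing.assert_allclose(s.nd, brute)

    def test_empty_track_rejected(self):
        tr = straight_track(n=5)
        empty = syn.replace_track_fixes(tr, tr.fixes.iloc[0:0])
        with pytest.raises(ValueError):
            nsd.compute_displacement(empty)


class TestMovementModels:
    t = np.arange(1, 366, 1 / 12)

    def test_noiseless_migrant_recovered_exactly(self):
        nd = logistic(self.t, 30, 124, 3) - logistic(self.t, 30, 260, 5)
        fits = {f.model: f for f in nsd.fit_movement_models(_series(self.t, nd))}
        best = min(fits.values(), key=lambda f: f.aicc)
        assert best.model == "migrant"
        for name, true in [
            ("delta", 30), ("theta_s", 124), ("phi_s", 3), ("theta_a", 260), ("phi_a", 5),
        ]:
            assert abs(best.params[name] - true) < 1e-3

    def test_constant_series_prefers_resident(self):
        rng = np.random.default_rng(1)
        nd = 1.0 + rng.normal(0, 0.05, len(self.t))
        fits = nsd.fit_movement_models(_series(self.t, nd))
        cls = nsd.classify_tactic(fits, t_span=(1.0, 365.0))
        assert cls.tactic == "resident"

    def test_monotone_logistic_prefers_disperser_over_migrant(self):
        rng = np.random.default_rng(3)
        nd = logistic(self.t, 20, 130, 4) + rng.normal(0, 0.3, len(self.t))
        fits = {f.model: f for f in nsd.fit_movement_models(_series(self.t, nd))}
        assert fits["migrant"].aicc - fits["disperser"].aicc > 2.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            nsd.fit_movement_models(_series(np.linspace(1, 100, 60), np.ones(60)))

    def test_aicc_ranking_matches_grid_search_oracle(self):
        # 3-candidate toy: resident / nomad / disperser, against brute-force
        # least squares on parameter grids
        rng = np.random.default_rng(12)
        t = np.linspace(1, 365, 300)
        nd = np.abs(logistic(t, 12, 150, 6) + rng.normal(0, 0.4, len(t)))
        fits = {f.model: f for f in nsd.fit_movement_models(_series(t, nd))}

        def gauss_aicc(rss, n, k_model):
            ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
            k = k_model + 1
            return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)

        n = len(t)
        oracle = {}
        oracle["resident"] = gauss_aicc(np.sum((nd - nd.mean()) ** 2), n, 1)
        s = np.sqrt(t - t.min())
        beta = np.sum(nd * s) / np.sum(s * s)
        oracle["nomad"] = gauss_aicc(np.sum((nd - beta * s) ** 2), n, 1)
        best = np.inf
        for d in np.linspace(8, 16, 33):
            for th in np.linspace(130, 170, 41):
                for ph in np.linspace(2, 12, 41):
                    rss = np.sum((logistic(t, d, th, ph) - nd) ** 2)
                    best = min(best, rss)
        oracle["disperser"] = gauss_aicc(best, n, 3)

        rank_pkg = sorted(["resident", "nomad", "disperser"], key=lambda m: fits[m].aicc)
        rank_orc = sorted(oracle, key=oracle.get)
        assert rank_pkg == rank_orc
        for m in ("resident", "nomad"):
            assert fits[m].aicc == pytest.approx(oracle[m], rel=1e-9)
        assert fits["disperser"].aicc <= oracle["disperser"] + 1e-6


class TestClassifyTactic:
    def test_borderline_migrant_is_flagged(self):
        t = np.arange(1, 366, 1 / 12)
        nd = logistic(t, 3.1, 124, 3) - logistic(t, 3.1, 260, 5)
        fits = nsd.fit_movement_models(_series(t, nd))
        cls = nsd.classify_tactic(fits, min_delta_km=3.0, t_span=(1.0, 365.0))
        assert cls.tactic in ("migrant", "mixed_migrant")
        assert cls.review_flag

    def test_sub_threshold_shift_classified_resident(self):
        t = np.arange(1, 366, 1 / 12)
        rng = np.random.default_rng(9)
        nd = logistic(t, 1.5, 124, 3) - logistic(t, 1.5, 260, 5) + rng.normal(0, 0.2, len(t))
        fits = nsd.fit_movement_models(_series(t, nd))
        cls = nsd.classify_tactic(fits, min_delta_km=3.0, t_span=(1.0, 365.0))
        assert nsd.binary_tactic(cls.tactic) == "resident"


class TestSeasonalLogistic:
    def test_noiseless_recovery_exact(self):
        t = np.linspace(60, 200, 400)
        nd = logistic(t, 20, 130, 4)
        fit = nsd.fit_seasonal_logistic(_series(t, nd), "spring", noise_floor=False)
        assert abs(fit.delta - 20) < 1e-6
        assert abs(fit.theta - 130) < 1e-6
        assert abs(fit.phi - 4) < 1e-6

    def test_noise_floor_variant_matches_on_clean_data(self):
        t = np.linspace(60, 200, 400)
        nd = logistic(t, 20, 130, 4)
        fit = nsd.fit_seasonal_logistic(_series(t, nd), "spring")
        assert abs(fit.delta - 20) < 1e-4
        assert abs(fit.phi - 4) < 1e-4

    def test_mid_date_estimate_is_sharp_under_noise(self):
        # Gaussian noise sd 0.5 km on 360 fixes; median mid-date error < 0.5 d
        rng = np.random.default_rng(12)
        t = np.linspace(60, 180, 360)
        errs = []
        for _ in range(60):
            nd = logistic(t, 20, 130, 4) + rng.normal(0, 0.5, len(t))
            fit = nsd.fit_seasonal_logistic(_series(t, nd), "spring")
            errs.append(abs(fit.theta - 130))
        assert np.median(errs) < 0.5

    def test_fitted_curve_is_half_asymptote_at_theta(self):
        t = np.linspace(60, 200, 400)
        fit = nsd.fit_seasonal_logistic(_series(t, logistic(t, 20, 130, 4)), "spring")
        assert fit.predict(np.array([fit.theta]))[0] == pytest.approx(fit.delta / 2)

    def test_curve_reaches_75pct_at_theta_plus_phi_ln3(self):
        t = np.linspace(60, 200, 400)
        fit = nsd.fit_seasonal_logistic(_series(t, logistic(t, 20, 130, 4)), "spring")
        t75 = fit.theta + fit.phi * np.log(3.0)
        assert fit.predict(np.array([t75]))[0] == pytest.approx(0.75 * fit.delta, rel=1e-6)


class TestMigrationEvent:
    def test_window_identities(self):
        fit = nsd.SeasonalLogisticFit("autumn", 20.0, 260.0, 12.5, 0.0, 100, True)
        tr = straight_track(n=800, speed_kmh=0.2, start="2010-08-10")
        ev = nsd.extract_migration_event(fit, tr)
        assert ev.departure == pytest.approx(235.0)
        assert ev.arrival == pytest.approx(285.0)
        assert ev.duration == pytest.approx(50.0)
        assert ev.duration == pytest.approx(4 * fit.phi)

    def test_distance_and_speed_on_known_steps(self):
        ts = pd.date_range("2010-05-03", periods=5, freq="2h", tz="UTC")
        tr = syn.Track(
            "v", "F", "b",
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "x_km": [0, 0, 3, 6, 6],
                    "y_km": [0, 0, 4, 8, 8],
                }
            ),
        )
        t = tr.julian_days()
        theta = float(t[2])
        phi = float((t[3] - t[1]) / 4.0) + 1e-6  # window holds fixes 1..3
        fit = nsd.SeasonalLogisticFit("spring", 10.0, theta, phi, 0.0, 3, True)
        ev = nsd.extract_migration_event(fit, tr)
        assert ev.distance_roamed == pytest.approx(10.0)
        assert ev.mean_speed == pytest.approx(2.5)

    def test_straight_migration_distance_equals_net_displacement(self):
        tr = straight_track(n=200, speed_kmh=0.5, start="2010-05-01")
        t = tr.julian_days()
        fit = nsd.SeasonalLogisticFit("spring", 20.0, float(t.mean()), 2.0, 0.0, 10, True)
        ev = nsd.extract_migration_event(fit, tr)
        s = nsd.compute_displacement(tr)
        inside = (s.times >= ev.departure) & (s.times <= ev.arrival)
        net = s.nd[inside][-1] - s.nd[inside][0]
        assert ev.distance_roamed == pytest.approx(net, rel=1e-9)

    def test_window_outside_track_rejected(self):
        tr = straight_track(n=50, start="2010-05-01")
        fit = nsd.SeasonalLogisticFit("spring", 10.0, 300.0, 5.0, 0.0, 10, True)
        with pytest.raises(ValueError, match="outside the"):
            nsd.extract_migration_event(fit, tr)

    def test_distance_roamed_bounds_net_displacement_on_simulated_events(
        self, migrant_truth
    ):
        tr = year_track(migrant_truth, seed=21)
        res = nsd.analyze_track(tr)
        assert nsd.binary_tactic(res["classification"].tactic) == "migrant"
        for season in ("spring", "autumn"):
            fit = res[f"{season}_fit"]
            assert fit is not None
            ev = nsd.extract_migration_event(fit, tr)
            s = nsd.compute_displacement(tr)
            inside = (s.times >= ev.departure) & (s.times <= ev.arrival)
            xy = tr.xy()[inside]
            net = float(np.hypot(*(xy[-1] - xy[0])))
            assert ev.distance_roamed >= net - 1e-9
            assert ev.duration == pytest.approx(4 * fit.phi)
            assert ev.departure == pytest.approx(fit.theta - 2 * fit.phi)
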