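"""Brownian-bridge variance, utilization distributions, and stopovers."""

import numpy as np
import pandas as pd
import pytest

from herdtrack import bbmm
from herdtrack import synthetic as syn
from tests.conftest import straight_track


def _track(xy, interval_h=2.0):
    ts = pd.date_range(
        "2010-05-01", periods=len(xy), freq=pd.Timedelta(hours=interval_h), tz="UTC"
    )
    return syn.Track(
        "t", "F", "b",
        pd.DataFrame({"timestamp": ts, "x_km": xy[:, 0], "y_km": xy[:, 1]}),
        fix_interval_h=interval_h,
    )


class TestBridgeVariance:
    def test_marginal_variance_closed_form_spot_checks(self):
        s2, sloc, T = 0.7, 0.1, 4.0
        # endpoints: pure location error; midpoint: maximum bridge spread
        v0 = bbmm._bridge_var(s2, sloc, np.array([0.0]), T)[0]
        vT = bbmm._bridge_var(s2, sloc, np.array([T]), T)[0]
        vm = bbmm._bridge_var(s2, sloc, np.array([T / 2]), T)[0]
        assert v0 == pytest.approx(sloc**2)
        assert vT == pytest.approx(sloc**2)
        assert vm == pytest.approx(s2 * T / 4 + sloc**2 / 2)
        grid = bbmm._bridge_var(s2, sloc, np.linspace(0, T, 101), T)
        assert np.argmax(grid) == 50

    def test_straight_constant_velocity_gives_zero_motion_variance(self):
        tr = straight_track(n=50, speed_kmh=2.0)
        v = bbmm.estimate_bb_variance(tr, sigma_loc=0.0)
        assert v.sigma_m2 < 1e-8

    def test_brownian_motion_variance_recovered(self):
        rng = np.random.default_rng(5)
        n, dt = 200, 2.0
        steps = rng.normal(0, np.sqrt(0.5 * dt), size=(n - 1, 2))
        tr = _track(np.vstack([[0, 0], np.cumsum(steps, axis=0)]))
        v = bbmm.estimate_bb_variance(tr, sigma_loc=0.0)
        assert 0.35 < v.sigma_m2 < 0.65

    def test_larger_location_error_does_not_raise_motion_variance(self):
        rng = np.random.default_rng(6)
        steps = rng.normal(0, np.sqrt(0.2 * 2.0), size=(99, 2))
        tr = _track(np.vstack([[0, 0], np.cumsum(steps, axis=0)]))
        v1 = bbmm.estimate_bb_variance(tr, sigma_loc=0.02)
        v2 = bbmm.estimate_bb_variance(tr, sigma_loc=0.04)
        assert v2.sigma_m2 <= v1.sigma_m2 + 1e-12

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError):
            bbmm.estimate_bb_variance(straight_track(n=4))


class TestUD:
    def test_stationary_point_mass_limit(self):
        xy = np.zeros((2, 2)) + 5.0
        tr = _track(xy)
        var = bbmm.BBVariance(sigma_m2=0.0, sigma_loc=0.0, loglik=0.0)
        grid = bbmm.UDGridSpec(x0=4.0, y0=4.0, cell_km=0.1, nx=20, ny=20)
        ud = bbmm.compute_bbmm_ud(tr, var, grid)
        i, j = grid.cell_of(5.0, 5.0)
        assert ud.probs[i, j] == pytest.approx(1.0)

    def test_probabilities_sum_to_one_and_non_negative(self):
        rng = np.random.default_rng(2)
        xy = np.cumsum(rng.normal(0, 0.5, size=(40, 2)), axis=0)
        tr = _track(xy)
        var = bbmm.estimate_bb_variance(tr, sigma_loc=0.02)
        grid = bbmm.make_grid_for_segment(tr, var, cell_m=150)
        ud = bbmm.compute_bbmm_ud(tr, var, grid)
        assert abs(ud.probs.sum() - 1.0) < 1e-6
        assert np.all(ud.probs >= 0)

    def test_grid_coverage_enforced(self):
        tr = _track(np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]]))
        var = bbmm.BBVariance(sigma_m2=0.5, sigma_loc=0.02, loglik=0.0)
        small = bbmm.UDGridSpec(x0=0.0, y0=-1.0, cell_km=0.2, nx=10, ny=10)
        with pytest.raises(ValueError, match="cover"):
            bbmm.compute_bbmm_ud(tr, var, small)

    def test_ud_matches_monte_carlo_bridge_simulation(self):
        # 3-fix toy segment vs a sampled-path oracle; total variation < 0.02
        xy3 = np.array([[0.0, 0.0], [1.0, 0.3], [1.8, 1.2]])
        seg = _track(xy3)
        var = bbmm.BBVariance(sigma_m2=0.3, sigma_loc=0.05, loglik=0.0)
        grid = bbmm.make_grid_for_segment(seg, var, cell_m=200)
        ud = bbmm.compute_bbmm_ud(seg, var, grid, quad_per_interval=30)

        rng = np.random.default_rng(0)
        N = 500_000
        iv = rng.integers(0, 2, N)
        tt = rng.random(N) * 2.0
        a, b, T = xy3[iv], xy3[iv + 1], 2.0
        mu = a + (tt / T)[:, None] * (b - a)
        varr = 0.3 * tt * (T - tt) / T + 0.05**2 * ((1 - tt / T) ** 2 + (tt / T) ** 2)
        pts = mu + rng.normal(size=(N, 2)) * np.sqrt(varr)[:, None]
        spec = ud.spec
        ix = np.clip(((pts[:, 0] - spec.x0) / spec.cell_km).astype(int), 0, spec.nx - 1)
        iy = np.clip(((pts[:, 1] - spec.y0) / spec.cell_km).astype(int), 0, spec.ny - 1)
        acc = np.zeros_like(ud.probs)
        np.add.at(acc, (iy, ix), 1.0)
        acc /= acc.sum()
        tv = 0.5 * np.abs(acc - ud.probs).sum()
        assert tv < 0.02


class TestStopovers:
    def _detect(self, truth, seed, season="spring"):
        start = pd.Timestamp(year=truth.year, month=1, day=1, tz="UTC")
        end = pd.Timestamp(year=truth.year, month=12, day=31, hour=22, tz="UTC")
        tr = syn.simulate_track(truth, None, start, end, seed=seed)
        t = tr.julian_days()
        theta = truth.spring_theta if season == "spring" else truth.autumn_theta
        phi = truth.spring_phi if season == "spring" else truth.autumn_phi
        mask = (t >= theta - 2 * phi - 0.5) & (t <= theta + 2 * phi + 0.5)
        seg = syn.replace_track_fixes(tr, tr.fixes.loc[mask])
        var = bbmm.estimate_bb_variance(seg)
        grid = bbmm.make_grid_for_segment(seg, var, cell_m=150)
        ud = bbmm.compute_bbmm_ud(seg, var, grid)
        d = truth.range_distance
        excl = [
            (*truth.winter_center, 0.15 * d + 1.0),
            (*truth.summer_center, 0.15 * d + 1.0),
        ]
        return bbmm.identify_stopovers(ud, seg, exclude_ranges=excl)

    def test_no_pauses_no_stopovers(self, migrant_truth):
        stops = self._detect(migrant_truth, seed=9)
        assert stops.n_stopovers == 0

    def test_single_24h_dwell_found_at_its_location(self, migrant_truth):
        import dataclasses

        truth = dataclasses.replace(
            migrant_truth,
            stopovers=(syn.Stopover((17.0, 14.0), 123.0, 24.0, "spring"),),
        )
        stops = self._detect(truth, seed=9)
        assert stops.n_stopovers == 1
        cx, cy = stops.clusters[0].centroid
        assert np.hypot(cx - 17.0, cy - 14.0) < 1.0
        assert stops.clusters[0].residence_h >= 12.0

    def test_two_distant_dwells_give_two_clusters(self):
        truth = syn.TrackTruth(
            "two", "F", "migrant", (0.0, 0.0), (30.0, 0.0), 124.0, 260.0, 4.0, 3.0,
            stopovers=(
                syn.Stopover((10.0, 0.5), 119.0, 24.0, "spring"),
                syn.Stopover((20.0, -0.5), 126.0, 24.0, "spring"),
            ),
            ou_sd=0.5,
        )
        stops = self._detect(truth, seed=9)
        assert stops.n_stopovers == 2
        (x1, _), (x2, _) = (c.centroid for c in stops.clusters)
        assert abs(x1 - 10.0) < 1.5 and abs(x2 - 20.0) < 1.5

    def test_top_mass_selection_is_smallest_covering_set(self):
        probs = np.array([[0.5, 0.2], [0.2, 0.1]])
        mask = bbmm._top_mass_mask(probs, 0.25)
        assert mask.sum() == 1 and mask[0, 0]
        mask = bbmm._top_mass_mask(probs, 0.6)
        assert mask.sum() == 2
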