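"""Position screening, step building, tentative gamma, strata, seasons."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from chamois_issf import steps as sp
from chamois_issf.steps import (GammaKernel, assign_season, build_steps,
                                build_strata, filter_individuals,
                                fit_tentative_gamma, sample_random_steps,
                                screen_positions, season_days, standardize)


def fixes_frame(xy, start="2019-06-01 00:00", interval_h=4, individual="a"):
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "individual": individual,
        "timestamp": [t0 + pd.Timedelta(hours=interval_h * k)
                      for k in range(len(xy))],
        "x": [p[0] for p in xy],
        "y": [p[1] for p in xy],
    })


class TestScreen:
    def test_spike_fix_removed(self):
        xy = [(0, 0), (100, 0), (50200, 0), (300, 0), (400, 0)]
        cleaned, report = screen_positions(fixes_frame(xy), 3000.0)
        assert len(report) == 1
        assert report.iloc[0]["x"] == 50200
        assert len(cleaned) == 4

    def test_stationary_track_untouched(self):
        xy = [(10, 10)] * 6
        cleaned, report = screen_positions(fixes_frame(xy), 3000.0)
        assert len(report) == 0 and len(cleaned) == 6

    def test_two_fix_track_never_removes(self):
        xy = [(0, 0), (1e6, 1e6)]
        cleaned, report = screen_positions(fixes_frame(xy), 1.0)
        assert len(report) == 0 and len(cleaned) == 2

    def test_fast_oneway_travel_kept(self):
        # fast in, fast onward: no out-and-back evidence at the same point
        xy = [(0, 0), (30000, 0), (60000, 0)]
        cleaned, report = screen_positions(fixes_frame(xy), 3000.0)
        assert len(report) == 1  # middle fix has both legs > ceiling


class TestBuildSteps:
    def test_collinear_turn_zero(self):
        xy = [(0, 0), (100, 0), (200, 0)]
        st = build_steps(fixes_frame(xy))
        assert len(st) == 2
        assert st["turn"].isna().tolist() == [True, False]
        assert st["turn"].iloc[1] == pytest.approx(0.0)

    def test_right_angle_east_then_north(self):
        xy = [(0, 0), (100, 0), (100, 100)]
        st = build_steps(fixes_frame(xy))
        assert st["turn"].iloc[1] == pytest.approx(np.pi / 2)

    def test_gap_splits_burst(self):
        t0 = pd.Timestamp("2019-06-01")
        times = [t0, t0 + pd.Timedelta(hours=4), t0 + pd.Timedelta(hours=16),
                 t0 + pd.Timedelta(hours=20)]
        df = pd.DataFrame({"individual": "a", "timestamp": times,
                           "x": [0, 100, 200, 300], "y": 0.0})
        st = build_steps(df, 4.0, 60.0)
        assert len(st) == 2  # the 12-h gap produces no step
        assert st["burst"].nunique() == 2
        assert st["turn"].isna().all()  # no previous step within either burst

    def test_turn_range_property(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 100, size=(50, 2)), axis=0)
        st = build_steps(fixes_frame([tuple(p) for p in xy]))
        turns = st["turn"].dropna()
        assert ((turns > -np.pi) & (turns <= np.pi)).all()


class TestTentativeGamma:
    def test_recovers_known_parameters(self):
        x = np.random.default_rng(1).gamma(2.0, 50.0, 100_000)
        k = fit_tentative_gamma(x)
        assert abs(k.shape - 2.0) / 2.0 < 0.02
        assert abs(k.scale - 50.0) / 50.0 < 0.02

    def test_score_equation_identity(self):
        x = np.random.default_rng(2).gamma(1.3, 120.0, 500)
        k = fit_tentative_gamma(x, floor=1e-9)
        from scipy.special import digamma

        lhs = digamma(k.shape) - np.log(k.shape)
        rhs = np.log(x).mean() - np.log(x.mean())
        assert abs(lhs - rhs) < 1e-8

    def test_matches_scipy_mle(self):
        x = np.random.default_rng(3).gamma(0.8, 200.0, 2000)
        k = fit_tentative_gamma(x, floor=1e-9)
        a, _, scale = stats.gamma.fit(x, floc=0)
        assert k.shape == pytest.approx(a, rel=1e-4)
        assert k.scale == pytest.approx(scale, rel=1e-4)

    def test_matches_bruteforce_maximizer(self):
        x = np.random.default_rng(4).gamma(1.5, 80.0, 40)
        k = fit_tentative_gamma(x)

        def nll(p):
            return -stats.gamma.logpdf(x, a=p[0], scale=p[1]).sum()

        res = optimize.minimize(nll, [1.0, x.mean()], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert k.shape == pytest.approx(res.x[0], rel=1e-3)
        assert k.scale == pytest.approx(res.x[1], rel=1e-3)

    def test_zero_lengths_floored(self):
        x = np.concatenate([[0.0, 0.0], np.random.default_rng(5).gamma(2, 50, 50)])
        k = fit_tentative_gamma(x, floor=1.0)
        assert k.shape > 0

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_tentative_gamma([10.0] * 5)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            GammaKernel(shape=-1.0, scale=10.0, n=10)


class TestRandomSteps:
    def make_step(self):
        st = build_steps(fixes_frame([(800, 800), (900, 800), (900, 900)],
                                     start="2019-06-02 00:00"))
        return st.iloc[1]

    def test_stratum_of_eleven(self, small_landscape):
        kern = GammaKernel(shape=1.0, scale=100.0, n=50)
        strat = sample_random_steps(self.make_step(), kern, small_landscape,
                                    n=10, seed=1)
        assert len(strat) == 11
        assert strat["used"].sum() == 1

    def test_turning_angles_uniform(self, small_landscape):
        # pool angles over many sampled strata and KS-test against U(-pi, pi]
        kern = GammaKernel(shape=1.0, scale=60.0, n=50)
        step = self.make_step()
        angles = []
        for s in range(40):
            strat = sample_random_steps(step, kern, small_landscape,
                                        n=250, seed=s)
            avail = strat[strat["used"] == 0]
            dx = avail["x"].to_numpy() - step["x0"]
            dy = avail["y"].to_numpy() - step["y0"]
            ref = step["direction"] - step["turn"]
            angles.append(sp._wrap_angle(np.arctan2(dy, dx) - ref))
        angles = np.concatenate(angles)
        assert len(angles) == 10_000
        ks = stats.kstest(angles, stats.uniform(-np.pi, 2 * np.pi).cdf)
        assert ks.pvalue > 0.01

    def test_lengths_follow_kernel(self, small_landscape):
        kern = GammaKernel(shape=1.4, scale=80.0, n=50)
        strat = sample_random_steps(self.make_step(), kern, small_landscape,
                                    n=5000, seed=3)
        avail = strat[strat["used"] == 0]
        ks = stats.kstest(avail["step_length"],
                          stats.gamma(a=1.4, scale=80.0).cdf)
        assert ks.pvalue > 0.01

    def test_seed_determinism(self, small_landscape):
        kern = GammaKernel(shape=1.0, scale=100.0, n=50)
        a = sample_random_steps(self.make_step(), kern, small_landscape, seed=7)
        b = sample_random_steps(self.make_step(), kern, small_landscape, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_undefined_reference_rejected(self, small_landscape):
        st = build_steps(fixes_frame([(800, 800), (900, 800)]))
        kern = GammaKernel(shape=1.0, scale=100.0, n=50)
        with pytest.raises(ValueError):
            sample_random_steps(st.iloc[0], kern, small_landscape)


class TestAnnotate:
    def test_cell_values_and_epoch_rule(self, small_landscape, summer_weather):
        L = small_landscape
        # endpoint at the centre of a known cell
        row, col = 10, 12
        ny = L.shape[0]
        x = L.x0 + (col + 0.5) * L.cell_size
        y = L.y0 + (ny - row - 0.5) * L.cell_size
        strata = pd.DataFrame({
            "stratum_id": [0, 0], "individual": "a",
            "t": pd.Timestamp("2019-06-05 12:00"),
            "used": [1, 0], "x": x, "y": y, "step_length": 50.0,
        })
        ann = sp.annotate_covariates(strata, L, summer_weather)
        assert ann["elevation"].iloc[0] == L.elevation[row, col]
        # a 2019 fix is closest to the 2018 tcd epoch
        assert ann["tcd"].iloc[0] == L.tcd[2018][row, col]
        # weather and day flag stratum-constant
        assert ann.groupby("stratum_id")[["temperature", "wind", "day"]] \
                  .nunique().max().max() == 1

    def test_epoch_nearest_year(self, small_landscape, summer_weather):
        from chamois_issf.landscape import nearest_epoch

        assert nearest_epoch(2014) == 2015
        assert nearest_epoch(2010) == 2012

    def test_off_raster_rejected(self, small_landscape, summer_weather):
        strata = pd.DataFrame({
            "stratum_id": [0], "individual": "a",
            "t": pd.Timestamp("2019-06-05"), "used": [1],
            "x": [-1e6], "y": [0.0], "step_length": [1.0]})
        with pytest.raises(ValueError):
            sp.annotate_covariates(strata, small_landscape, summer_weather)


class TestSeasonsAndCompleteness:
    @pytest.mark.parametrize("month,expected", [
        (6, "summer"), (7, "summer"), (10, "summer"),
        (12, "winter"), (1, "winter"), (4, "winter"),
        (5, "excluded"), (11, "excluded"),
    ])
    def test_assign_season(self, month, expected):
        assert assign_season(pd.Timestamp(2019, month, 15)) == expected

    def test_summer_window_arithmetic(self):
        assert season_days("summer", 2019) == 153
        # 153 days x 6 fixes/day = 918 possible; threshold 734.4
        counts = {"a": 918, "b": 700, "c": 735}
        kept = filter_individuals(counts, "summer", year=2019)
        assert sorted(kept) == ["a", "c"]

    def test_winter_leap_year(self):
        assert season_days("winter", 2019) == 152  # Feb 2020 has 29 days
        assert season_days("winter", 2018) == 151


class TestStandardize:
    def make_annotated(self, n=500, season="summer", seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "stratum_id": np.repeat(np.arange(n // 11 + 1), 11)[:n],
            "used": 0,
            "step_length": rng.gamma(1, 100, n),
            "elevation": rng.uniform(1400, 3000, n),
            "slope": rng.uniform(0, 60, n),
            "tcd": rng.uniform(0, 100, n),
            "northness": rng.uniform(-1, 1, n),
            "eastness": rng.uniform(-1, 1, n),
            "temperature": rng.normal(10, 5, n),
            "wind": rng.gamma(2, 6, n),
            "precipitation": rng.exponential(1, n),
            "snow": rng.uniform(0, 100, n) if season == "winter" else 0.0,
            "day": rng.integers(0, 2, n),
        })
        return df

    def test_zero_mean_unit_sd(self):
        df = self.make_annotated()
        z, std = standardize(df, "summer")
        for c in std.means:
            assert abs(z[c].mean()) < 1e-12
            assert z[c].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_inverse_roundtrip(self):
        df = self.make_annotated()
        z, std = standardize(df, "summer")
        for c in std.means:
            back = std.inverse(c, z[c].to_numpy())
            assert np.allclose(back, df[c].to_numpy())

    def test_constant_covariate_named_in_error(self):
        df = self.make_annotated()
        df["tcd"] = 42.0
        with pytest.raises(ValueError, match="tcd"):
            standardize(df, "summer")

    def test_snow_excluded_in_summer(self):
        df = self.make_annotated()
        z, std = standardize(df, "summer")
        assert "snow" not in std.means

    def test_json_roundtrip(self, tmp_path):
        _, std = standardize(self.make_annotated(), "summer")
        p = tmp_path / "std.json"
        std.to_json(p)
        back = sp.Standardization.from_json(p)
        assert back.means == std.means and back.sds == std.sds
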