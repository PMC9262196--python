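"""Chronobiology statistics: WZT map, filtering, rhythmicity, profiles,
window fractions, niche distances and the saturation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chronotrap.chrono import (CaptureSeries, WztParams, diel_profile,
                               filter_span_minutes, lowpass, niche_mds,
                               profile_distance_matrix, rate_series,
                               rhythmicity, saturation_test, sun_times,
                               window_fraction, wzt, wzt_hours, wzt_inverse)


# ---------------------------------------------------------------------------
# Warped Zeitgeber time
# ---------------------------------------------------------------------------

class TestWzt:
    @pytest.mark.parametrize("d", [0.2, 0.35, 0.5, 0.64, 0.8])
    def test_sunset_maps_to_half_day(self, d):
        p = WztParams(sunrise_frac=0.3, day_frac=d)
        t_sunset = (0.3 + d) % 1.0
        assert wzt(t_sunset, p) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("d", [0.2, 0.5, 0.8])
    def test_solar_noon_and_midnight(self, d):
        p = WztParams(sunrise_frac=0.1, day_frac=d)
        noon = (0.1 + d / 2) % 1.0
        midnight = (0.1 + d + (1 - d) / 2) % 1.0
        assert wzt(noon, p) == pytest.approx(0.25, abs=1e-12)
        assert wzt(midnight, p) == pytest.approx(0.75, abs=1e-12)

    def test_equinox_is_identity(self):
        p = WztParams(sunrise_frac=0.0, day_frac=0.5)
        z = np.linspace(0, 0.999, 50)
        assert np.allclose(wzt(z, p), z, atol=1e-12)

    def test_invalid_day_length(self):
        with pytest.raises(ValueError):
            WztParams(sunrise_frac=0.2, day_frac=1.0)

    @given(d=st.floats(0.05, 0.95), s=st.floats(0, 1),
           t=st.floats(0, 1, exclude_max=True))
    def test_bijective_roundtrip(self, d, s, t):
        p = WztParams(sunrise_frac=s, day_frac=d)
        assert wzt_inverse(wzt(t, p), p) == pytest.approx(t % 1.0, abs=1e-9)

    @given(d=st.floats(0.05, 0.95))
    def test_continuous_and_increasing_in_zt(self, d):
        p = WztParams(sunrise_frac=0.0, day_frac=d)
        z = np.linspace(0, 0.9999, 2000)
        w = np.asarray(wzt(z, p))
        assert np.all(np.diff(w) > 0)
        max_slope = 1.0 / (2.0 * min(d, 1 - d))
        # steps bounded by the steeper branch slope: no jump at the knot
        assert np.all(np.diff(w) <= max_slope * np.diff(z).max() * 1.01)

    def test_sun_times_equator_equinox(self):
        p = sun_times(0.0, 0.0, day_of_year=80)
        assert p.day_frac == pytest.approx(0.5, abs=0.01)
        assert p.sunrise_frac == pytest.approx(0.25, abs=0.02)

    def test_sun_times_polar_night_raises(self):
        with pytest.raises(ValueError):
            sun_times(85.0, 0.0, day_of_year=355)


# ---------------------------------------------------------------------------
# Rate series and low-pass filtering
# ---------------------------------------------------------------------------

class TestRateSeries:
    def test_no_events_gives_zero_series(self):
        s = rate_series([], start=0.0, end=7200.0, bin_minutes=60)
        assert np.all(s.values == 0)

    def test_ten_events_in_one_hour_bin(self):
        s = rate_series(np.full(10, 1800.0), start=0.0, end=3600.0, bin_minutes=60)
        assert s.values[0] == pytest.approx(10.0)

    def test_counts_require_frame_times(self):
        with pytest.raises(ValueError):
            rate_series(counts=[1, 2, 3])

    def test_non_monotone_frame_times_rejected(self):
        with pytest.raises(ValueError):
            rate_series(counts=[1, 2], frame_times=[10.0, 5.0])


class TestLowpass:
    def _counts(self, values):
        t = np.arange(len(values)) * 1200.0      # 20-min frames
        return CaptureSeries(t, np.asarray(values, float), 20.0, "counts")

    def test_constant_counts_zero_rate(self):
        _, rate = lowpass(self._counts([4] * 30))
        assert np.allclose(rate.values, 0.0)

    def test_single_frame_spike_removed_by_median(self):
        vals = [2] * 10 + [3] + [2] * 10
        filt, rate = lowpass(self._counts(vals))
        assert np.allclose(filt.values, 2.0)
        assert np.allclose(rate.values, 0.0)

    def test_unit_step_conserves_one_insect(self):
        vals = [0] * 15 + [1] * 15
        _, rate = lowpass(self._counts(vals))
        dt_h = 20.0 / 60.0
        assert rate.values.sum() * dt_h == pytest.approx(1.0, abs=1e-9)

    def test_short_series_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            _, rate = lowpass(self._counts([1, 2, 3]))
        assert getattr(rate, "flag", None) == "too-short"

    def test_span_of_width5_filter_at_20min(self):
        assert filter_span_minutes(5, 20.0) == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# Rhythmicity
# ---------------------------------------------------------------------------

def _rate(values, bin_minutes=60.0):
    t = np.arange(len(values)) * bin_minutes * 60.0
    return CaptureSeries(t, values, bin_minutes, "rate")


class TestRhythmicity:
    def test_periodic_signal_has_high_acf(self):
        t = np.arange(240)
        series = [_rate(np.cos(2 * np.pi * t / 24.0) + 0.01 * k) for k in range(3)]
        res = rhythmicity(series, lag_hours=24.0)
        assert res.lag_bins == 24
        assert np.all(res.acf >= 0.95)
        assert res.p_value < 1e-3

    def test_crepuscular_population_is_rhythmic(self):
        from chronotrap.chrono import wzt_hours as _wh
        from chronotrap.pipeline import default_taxa, default_wzt
        from chronotrap.synthetic import simulate_capture_times

        crep = [t for t in default_taxa() if t.name == "crepuscula"]
        crep[0] = type(crep[0])(crep[0].name, 5.0, crep[0].diel)
        series = []
        for k in range(4):
            ev = simulate_capture_times(crep, 0.0, 24.0 * 6, default_wzt(),
                                        seed=100 + k)
            s = rate_series([t for _, t in ev], start=0.0, end=24 * 6 * 3600.0,
                            bin_minutes=60)
            series.append(s)
        res = rhythmicity(series)
        assert res.mean > 0.2
        assert res.p_value < 0.05

    def test_lag_outside_span_rejected(self):
        with pytest.raises(ValueError):
            rhythmicity([_rate(np.ones(10)), _rate(np.ones(10))], lag_hours=24.0)

    def test_single_series_rejected(self):
        with pytest.raises(ValueError):
            rhythmicity([_rate(np.ones(50))])


# ---------------------------------------------------------------------------
# Diel profiles and window fractions
# ---------------------------------------------------------------------------

class TestDielProfile:
    def test_all_events_in_one_hour(self):
        prof = diel_profile(np.full(40, 6.5), ["r1"] * 40,
                            exposure_days={"r1": 5})
        assert prof.peak_hour == 6
        assert np.count_nonzero(prof.mean) == 1

    def test_uniform_events_near_flat(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 24, 6000)
        keys = np.where(np.arange(6000) < 3000, "a", "b")
        prof = diel_profile(w, keys, exposure_days={"a": 7, "b": 7})
        assert prof.mean.std() / prof.mean.mean() < 0.15

    def test_simulator_peak_recovered(self):
        from chronotrap.pipeline import default_wzt
        from chronotrap.synthetic import DielShape, TaxonSpec, simulate_capture_times

        taxon = TaxonSpec("x", 25.0, DielShape(peaks=((6.0, 1.5, 5.0),), floor=0.1))
        ev = simulate_capture_times([taxon], 0.0, 24.0 * 14, default_wzt(), seed=5)
        w = wzt_hours((np.array([t for _, t in ev]) / 86400.0) % 1.0, default_wzt())
        prof = diel_profile(w, ["r"] * len(w), exposure_days={"r": 14})
        assert abs(prof.peak_hour - 6) <= 1


class TestWindowFraction:
    def test_half_day_window_null_is_half(self):
        res = window_fraction([1.0, 5.0, 13.0], [(0, 12)], n_boot=100, seed=0)
        assert res.null == pytest.approx(0.5)
        assert res.observed == pytest.approx(2 / 3)

    def test_eight_hours_null_is_third(self):
        res = window_fraction([1.0], [(8, 12), (22, 24), (0, 2)], n_boot=100, seed=0)
        assert res.null == pytest.approx(8 / 24)

    def test_empty_window_set(self):
        res = window_fraction([1.0, 2.0], [], n_boot=10, seed=0)
        assert res.observed == 0.0 and res.null == 0.0

    def test_overlapping_windows_merged(self):
        res = window_fraction([1.0], [(0, 6), (4, 10)], n_boot=10, seed=0)
        assert res.null == pytest.approx(10 / 24)

    def test_wrapping_window(self):
        res = window_fraction([23.5, 0.5, 12.0], [(22, 2)], n_boot=200, seed=0)
        assert res.null == pytest.approx(4 / 24)
        assert res.observed == pytest.approx(2 / 3)

    def test_bootstrap_ci_brackets_observed(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 24, 400)
        res = window_fraction(w, [(0, 12)], n_boot=2000, seed=1)
        assert res.ci_low <= res.observed <= res.ci_high
        assert res.ci_low < res.null < res.ci_high     # uniform events


# ---------------------------------------------------------------------------
# Temporal-niche distances and MDS
# ---------------------------------------------------------------------------

class TestNicheDistance:
    def test_identical_profiles_distance_zero(self):
        p = np.sin(np.linspace(0, 2 * np.pi, 24)) + 2
        d = profile_distance_matrix({"a": p, "b": p.copy(), "c": -p + 4})
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-6)

    def test_antiphase_profiles_distance_one(self):
        p = np.sin(np.linspace(0, 2 * np.pi, 24))
        d = profile_distance_matrix({"a": p, "b": -p})
        assert d.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_linear_variant(self):
        p = np.sin(np.linspace(0, 2 * np.pi, 24))
        d = profile_distance_matrix({"a": p, "b": -p}, distance="linear")
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_distance_matrix({"a": np.ones(24), "b": np.arange(24.0)})

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        profs = {f"t{k}": rng.uniform(0, 1, 24) for k in range(6)}
        d = profile_distance_matrix(profs).to_numpy()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNicheMds:
    @pytest.fixture(scope="class")
    def community(self):
        rng = np.random.default_rng(11)
        ev = {}
        for k in range(2):
            ev[f"day{k}"] = rng.normal(6 + 0.3 * k, 1.5, 300) % 24
            ev[f"night{k}"] = rng.normal(18 - 0.3 * k, 1.5, 300) % 24
        return ev

    def test_groups_separate_on_map(self, community):
        res = niche_mds(community, n_boot=60, seed=2)
        day = res.coords.loc[["day0", "day1"]].to_numpy()
        night = res.coords.loc[["night0", "night1"]].to_numpy()
        within = max(np.linalg.norm(day[0] - day[1]),
                     np.linalg.norm(night[0] - night[1]))
        across = min(np.linalg.norm(a - b) for a in day for b in night)
        assert across > within

    def test_constant_taxon_excluded(self):
        rng = np.random.default_rng(0)
        ev = {"a": rng.uniform(0, 24, 200), "b": rng.normal(6, 2, 200) % 24,
              "c": rng.normal(18, 2, 200) % 24,
              "bad": np.repeat(np.arange(24) + 0.5, 2)}   # flat: r undefined
        with pytest.warns(UserWarning):
            res = niche_mds(ev, n_boot=10, seed=0)
        assert res.excluded == ["bad"]

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            niche_mds({"a": np.arange(10.0), "b": np.arange(10.0)}, n_boot=5)

    def test_ellipse_polygon_contains_cloud_center(self, community):
        res = niche_mds(community, n_boot=60, seed=2)
        from shapely.geometry import Point

        for i, t in enumerate(res.taxa):
            center = res.boot_coords[:, i, :].mean(axis=0)
            assert res.ellipse_polygon(t).contains(Point(center))


# ---------------------------------------------------------------------------
# Saturation test
# ---------------------------------------------------------------------------

def _poisson_trap_weeks(rng, n_reps=10, taxa=("a", "b"), rate_per_day=6.0):
    rows = []
    for r in range(n_reps):
        for taxon in taxa:
            n = rng.poisson(rate_per_day * 6)
            for d in rng.uniform(0, 6, n):
                rows.append({"replicate": f"rep{r}", "taxon": taxon, "day": d})
    return pd.DataFrame(rows)


class TestSaturation:
    def test_all_events_in_first_half_give_share_one(self):
        rng = np.random.default_rng(0)
        df = _poisson_trap_weeks(rng)
        df["day"] = df["day"] / 2.1          # squeeze all into [0, 3)
        res = saturation_test(df)
        assert (res["intercept"] + res["slope"] *
                df.groupby("replicate").size().mean()).min() > 0.8

    def test_linear_capture_recovers_half(self):
        rng = np.random.default_rng(42)
        df = _poisson_trap_weeks(rng, n_reps=30)
        res = saturation_test(df)
        mean_load = df.groupby("replicate").size().mean()
        fitted_at_mean = res["intercept"] + res["slope"] * mean_load
        assert np.allclose(fitted_at_mean, 0.5, atol=0.08)
        assert (res["p_intercept_vs_half"] > 0.05).all()
        assert (res["p_slope"] > 0.05).all()

    def test_saturating_trap_detected(self):
        # capture probability decays with accumulated load: early events
        # over-represented, so the first-half share rises above 1/2
        rng = np.random.default_rng(7)
        rows = []
        for r in range(40):
            n = rng.poisson(60)
            d = np.sort(rng.uniform(0, 6, n))
            keep = rng.uniform(size=n) < np.exp(-np.arange(n) / 25.0)
            for day in d[keep]:
                rows.append({"replicate": f"r{r}", "taxon": "x", "day": day})
        res = saturation_test(pd.DataFrame(rows))
        assert res.loc["x", "intercept"] > 0.5
        assert res.loc["x", "p_intercept_vs_half"] < 0.05

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            saturation_test(pd.DataFrame({"taxon": ["a"], "day": [1.0]}))
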