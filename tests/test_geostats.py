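"""Great-circle geometry, outlier fences, variogram estimators and WLS fit."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import zincgeo as zg
from zincgeo.geostats import EARTH_RADIUS_KM, _bin_gamma

from conftest import DENSE_WINDOW, TRUE_MODEL, field_frame


coord = st.tuples(
    st.floats(-179.0, 179.0), st.floats(-85.0, 85.0)
)


class TestGreatCircle:
    def test_zero_for_identical_points(self):
        assert zg.great_circle_distance(39.0, 8.0, 39.0, 8.0) == 0.0

    def test_quarter_circle(self):
        d = zg.great_circle_distance(0.0, 0.0, 90.0, 0.0)
        assert d == pytest.approx(np.pi * EARTH_RADIUS_KM / 2.0, rel=1e-12)
        assert d == pytest.approx(10007.56, abs=0.01)

    def test_antipodal_maximum(self):
        d = zg.great_circle_distance(0.0, 0.0, 180.0, 0.0)
        assert d == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-12)
        assert d == pytest.approx(20015.11, abs=0.01)

    @given(a=coord, b=coord, c=coord)
    @settings(max_examples=150, deadline=None)
    def test_metric_properties(self, a, b, c):
        dab = zg.great_circle_distance(a[0], a[1], b[0], b[1])
        dba = zg.great_circle_distance(b[0], b[1], a[0], a[1])
        dac = zg.great_circle_distance(a[0], a[1], c[0], c[1])
        dcb = zg.great_circle_distance(c[0], c[1], b[0], b[1])
        assert dab == pytest.approx(dba, rel=1e-12, abs=1e-9)
        assert dab >= 0.0
        assert dab <= dac + dcb + 1e-6

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            zg.great_circle_distance(0.0, 95.0, 0.0, 0.0)


class TestBearing:
    def test_due_north_and_east(self):
        assert zg.bearing(39.0, 5.0, 39.0, 10.0) == pytest.approx(0.0, abs=1e-9)
        assert zg.bearing(10.0, 0.0, 20.0, 0.0) == pytest.approx(90.0, abs=1e-9)

    def test_equatorial_reversal_differs_by_180(self):
        fwd = zg.bearing(10.0, 0.0, 20.0, 0.0)
        rev = zg.bearing(20.0, 0.0, 10.0, 0.0)
        assert (rev - fwd) % 360.0 == pytest.approx(180.0, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            zg.bearing(39.0, 8.0, 39.0, 8.0)


class TestTukey:
    def test_single_extreme_value_flagged(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        mask, (lo, hi) = zg.tukey_outliers(x)
        assert mask.sum() == 1 and mask[-1]
        # Q1=3.25, Q3=7.75 under linear-interpolation quartiles
        assert hi == pytest.approx(7.75 + 3 * 4.5)

    def test_clean_sample_unflagged(self):
        rng = np.random.default_rng(0)
        mask, _ = zg.tukey_outliers(rng.normal(size=200))
        assert mask.sum() == 0

    def test_constant_data_warns(self):
        with pytest.warns(UserWarning, match="IQR"):
            mask, _ = zg.tukey_outliers(np.ones(10))
        assert not mask.any()


class TestEstimators:
    def test_constant_field_gives_zero(self):
        rng = np.random.default_rng(1)
        locs = np.column_stack([rng.uniform(37, 41, 30), rng.uniform(6, 10, 30)])
        agg = field_frame(np.full(30, 5.0), locs)
        for est in zg.geostats.VALID_ESTIMATORS:
            vg = zg.estimate_variogram(agg, zg.make_lag_bins(50, 1000), estimator=est)
            assert np.allclose(vg.nonempty["gamma"], 0.0)

    def test_single_pair_closed_forms(self):
        d = np.array([2.0])
        assert _bin_gamma(d, "matheron") == pytest.approx(2.0)
        assert _bin_gamma(d, "dowd") == pytest.approx(2.198 * 4.0 / 2.0)
        # (|2|^(1/2))^4 / (2 (0.457 + 0.494)) = 4 / 1.902
        assert _bin_gamma(d, "cressie_hawkins") == pytest.approx(4.0 / 1.902)

    def test_brute_force_oracle_on_small_field(self):
        """Binned estimates on 20 points match an independent O(n^2) loop."""
        rng = np.random.default_rng(7)
        n = 20
        locs = np.column_stack([rng.uniform(37, 39, n), rng.uniform(6, 8, n)])
        z = rng.normal(50, 8, n)
        edges = zg.make_lag_bins(25, 250)
        agg = field_frame(z, locs)

        for est in zg.geostats.VALID_ESTIMATORS:
            vg = zg.estimate_variogram(agg, edges, estimator=est)
            # oracle: explicit double loop, then the printed formulas
            per_bin = {b: [] for b in range(len(edges) - 1)}
            for i in range(n):
                for j in range(i + 1, n):
                    h = zg.great_circle_distance(
                        locs[i, 0], locs[i, 1], locs[j, 0], locs[j, 1]
                    )
                    b = int(h // 25)
                    if b < len(edges) - 1:
                        per_bin[b].append(z[i] - z[j])
            for b, row in vg.bins.iterrows():
                diffs = np.array(per_bin[b])
                assert row["n_pairs"] == len(diffs)
                if len(diffs) == 0:
                    assert np.isnan(row["gamma"])
                    continue
                if est == "matheron":
                    expect = np.sum(diffs**2) / (2 * len(diffs))
                elif est == "cressie_hawkins":
                    expect = np.mean(np.sqrt(np.abs(diffs))) ** 4 / (
                        2 * (0.457 + 0.494 / len(diffs))
                    )
                else:
                    expect = 2.198 * np.median(np.abs(diffs)) ** 2 / 2
                assert row["gamma"] == pytest.approx(expect, rel=1e-12)

    def test_matheron_iid_noise_converges_to_variance(self):
        """White noise with variance sigma^2 has a flat variogram at sigma^2."""
        rng = np.random.default_rng(12)
        n, sigma2 = 60, 4.0
        locs = np.column_stack([rng.uniform(37, 41, n), rng.uniform(6, 10, n)])
        edges = zg.make_lag_bins(100, 700)
        acc = []
        for _ in range(200):
            z = rng.normal(0, np.sqrt(sigma2), n)
            vg = zg.estimate_variogram(field_frame(z, locs), edges)
            acc.append(vg.bins["gamma"].to_numpy())
        mean_gamma = np.nanmean(np.array(acc), axis=0)
        ok = ~np.isnan(mean_gamma)
        assert np.all(np.abs(mean_gamma[ok] - sigma2) < 0.05 * sigma2)

    def test_directional_sectors_partition_pairs(self):
        rng = np.random.default_rng(3)
        n = 40
        locs = np.column_stack([rng.uniform(37, 41, n), rng.uniform(6, 10, n)])
        agg = field_frame(rng.normal(size=n), locs)
        edges = zg.make_lag_bins(50, 800)
        sectors = zg.estimate_variogram(agg, edges, directional=True)
        assert [s.sector for s in sectors] == [0.0, 45.0, 90.0, 135.0]
        total = sum(int(s.bins["n_pairs"].sum()) for s in sectors)
        iso = zg.estimate_variogram(agg, edges)
        assert total == int(iso.bins["n_pairs"].sum())

    def test_unknown_estimator_rejected(self):
        agg = field_frame(np.zeros(3), np.array([[37.0, 6.0], [38, 7], [39, 8]]))
        with pytest.raises(ValueError, match="unknown estimator"):
            zg.estimate_variogram(agg, estimator="kendall")


class TestWLSFit:
    def test_noise_free_recovery(self):
        """Bin values computed exactly from (27.0, 39.62, 14.79) are
        recovered to ~1e-4 relative error."""
        mids = np.arange(5.0, 200.0, 10.0)
        bins = pd.DataFrame({
            "lower": mids - 5, "upper": mids + 5, "mid": mids,
            "n_pairs": 100, "gamma": TRUE_MODEL(mids),
        })
        est = zg.VariogramEstimate(estimator="matheron", bins=bins)
        m = zg.fit_exponential_wls(est)
        assert m.c0 == pytest.approx(27.0, rel=1e-4, abs=1e-3)
        assert m.c1 == pytest.approx(39.62, rel=1e-4, abs=1e-3)
        assert m.a == pytest.approx(14.79, rel=1e-4, abs=1e-3)

    def test_pure_nugget_degrades_gracefully(self):
        mids = np.arange(5.0, 200.0, 10.0)
        bins = pd.DataFrame({
            "lower": mids - 5, "upper": mids + 5, "mid": mids,
            "n_pairs": 50, "gamma": 10.0,
        })
        est = zg.VariogramEstimate(estimator="matheron", bins=bins)
        with pytest.warns(UserWarning, match="pure nugget"):
            m = zg.fit_exponential_wls(est)
        assert m.c0 == pytest.approx(10.0, rel=1e-3)
        assert m.c1 == pytest.approx(0.0, abs=1e-3)

    def test_spatially_dependent_fraction(self):
        m = zg.VariogramModel(c0=27.0, c1=39.62, a=14.79)
        assert 100 * m.spatially_dependent_fraction == pytest.approx(59.47, abs=0.01)
        assert m.effective_range == pytest.approx(44.37)

    def test_too_few_bins_rejected(self):
        bins = pd.DataFrame({"lower": [0, 10], "upper": [10, 20], "mid": [5, 15],
                             "n_pairs": [5, 5], "gamma": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 non-empty bins"):
            zg.fit_exponential_wls(zg.VariogramEstimate("matheron", bins))

    def test_end_to_end_parameter_recovery_single_replicate(self):
        """One simulate->aggregate->estimate->fit pass lands in the right
        neighbourhood (the multi-replicate median check is the stronger
        acceptance test)."""
        cfg = zg.SimulationConfig(
            seed=4, n_ea=315, within_ea_sdlog=0.0, beta_crp=0.0, beta_agp=0.0,
            demographic_mix={"WRA": 1.0}, missingness_rates={},
            n_analytical_outliers=0, **DENSE_WINDOW,
        )
        df, _ = zg.simulate_survey(cfg)
        agg = zg.aggregate_by_ea(df, value_col="zn")
        vg = zg.estimate_variogram(agg, zg.make_lag_bins())
        m = zg.fit_exponential_wls(vg)
        assert 14.79 / 3 < m.a < 14.79 * 3
        assert m.sill == pytest.approx(66.62, rel=0.35)


class TestAggregation:
    def test_single_record_identity(self):
        df = pd.DataFrame({"ea_id": ["A"], "lon": [39.0], "lat": [8.0],
                           "zn_adjusted": [55.0]})
        agg = zg.aggregate_by_ea(df)
        assert agg["mean_zn"].iloc[0] == 55.0 and agg["n_records"].iloc[0] == 1

    def test_two_record_mean(self):
        df = pd.DataFrame({
            "ea_id": ["A", "A"], "lon": [39.0, 39.01], "lat": [8.0, 8.0],
            "zn_adjusted": [50.0, 60.0],
        })
        agg = zg.aggregate_by_ea(df)
        assert agg["mean_zn"].iloc[0] == pytest.approx(55.0)
        assert agg["mean_lon"].iloc[0] == pytest.approx(39.005)

    def test_ea_count_preserved(self, working_table):
        working, _, _ = working_table
        wra = working[working["group"] == "WRA"]
        agg = zg.aggregate_by_ea(wra)
        assert len(agg) == wra["ea_id"].nunique()

    def test_wide_ea_warns(self):
        df = pd.DataFrame({
            "ea_id": ["A", "A"], "lon": [39.0, 40.0], "lat": [8.0, 8.0],
            "zn_adjusted": [50.0, 60.0],
        })
        with pytest.warns(UserWarning, match="spread"):
            zg.aggregate_by_ea(df, sanity_radius_km=25.0)
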