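import numpy as np
import pandas as pd
import pytest

from packstep import territory


def _gaussian_fixes(n=500, center=(0.0, 0.0), sd=1500.0, seed=0, pack="p1",
                    start="2021-01-01"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "pack_id": pack,
            "timestamp": pd.date_range(start, periods=n, freq="3h"),
            "x": rng.normal(center[0], sd, n),
            "y": rng.normal(center[1], sd, n),
        }
    )


@pytest.fixture(scope="module")
def gaussian_ud():
    fixes = _gaussian_fixes()
    ud = territory.rolling_ud(
        fixes, "p1", fixes["timestamp"].max() + pd.Timedelta(hours=1), 90,
        bandwidth=500.0, resolution=250.0,
    )
    assert ud is not None
    return ud


class TestRollingUD:
    def test_mass_normalized_and_window_filter(self, gaussian_ud):
        assert gaussian_ud.grid.sum() == pytest.approx(1.0, abs=1e-6)
        assert (gaussian_ud.grid >= 0).all()

    def test_degenerate_cluster_peaks_at_point(self):
        fixes = _gaussian_fixes(n=30, sd=1e-6)
        ud = territory.rolling_ud(
            fixes, "p1", "2021-02-01", 90, bandwidth=400.0, resolution=200.0
        )
        iy, ix = np.unravel_index(ud.grid.argmax(), ud.grid.shape)
        xs, ys = ud.cell_centers()
        assert abs(xs[ix]) < 200.0 and abs(ys[iy]) < 200.0

    def test_two_equal_clusters_split_mass(self):
        a = _gaussian_fixes(n=250, center=(-5000, 0), sd=300.0, seed=1)
        b = _gaussian_fixes(n=250, center=(5000, 0), sd=300.0, seed=2,
                            start="2021-01-01 01:00")
        ud = territory.rolling_ud(
            pd.concat([a, b]), "p1", "2021-04-01", 90, bandwidth=400.0,
            resolution=250.0,
        )
        xs, _ = ud.cell_centers()
        left = ud.grid[:, xs < 0].sum()
        assert left == pytest.approx(0.5, abs=0.01)

    def test_exact_kernel_sum_oracle(self):
        """Grid equals the brute-force Gaussian kernel sum at every cell."""
        fixes = _gaussian_fixes(n=80)
        ud = territory.rolling_ud(
            fixes, "p1", "2021-02-01", 90, bandwidth=600.0, resolution=400.0
        )
        sub = fixes[fixes["timestamp"] < pd.Timestamp("2021-02-01")]
        fx, fy = sub["x"].to_numpy(), sub["y"].to_numpy()
        xs, ys = ud.cell_centers()
        brute = np.zeros((ud.ny, ud.nx))
        for j, yv in enumerate(ys):
            for i, xv in enumerate(xs):
                brute[j, i] = np.sum(
                    np.exp(-0.5 * (((xv - fx) ** 2 + (yv - fy) ** 2) / 600.0**2))
                )
        brute /= brute.sum()
        assert np.max(np.abs(brute - ud.grid)) < 1e-10

    def test_too_few_fixes_undefined(self):
        fixes = _gaussian_fixes(n=10)
        assert (
            territory.rolling_ud(fixes, "p1", "2021-02-01", 7, resolution=250.0)
            is None
        )

    def test_temporal_causality(self):
        """Perturbing fixes at/after the reference date never changes the
        field for that date."""
        fixes = _gaussian_fixes(n=400)
        ref = pd.Timestamp("2021-01-20")
        ud1 = territory.rolling_ud(fixes, "p1", ref, 14, bandwidth=500.0,
                                   extent=(-8000, -8000, 8000, 8000))
        bumped = fixes.copy()
        after = bumped["timestamp"] >= ref
        bumped.loc[after, "x"] += 50_000.0
        ud2 = territory.rolling_ud(bumped, "p1", ref, 14, bandwidth=500.0,
                                   extent=(-8000, -8000, 8000, 8000))
        np.testing.assert_array_equal(ud1.grid, ud2.grid)


class TestIsopleth:
    def test_mass_calibration(self, gaussian_ud):
        """Enclosed mass within one cell's maximal density of the level."""
        for level in (50, 95):
            iso = territory.isopleth_signed_distance(gaussian_ud, level)
            delta = gaussian_ud.grid.max()
            assert level / 100.0 <= iso.enclosed_mass <= level / 100.0 + delta

    def test_sign_agrees_with_point_in_region(self, gaussian_ud):
        rng = np.random.default_rng(5)
        iso = territory.isopleth_signed_distance(gaussian_ud, 95)
        ud = gaussian_ud
        x = rng.uniform(ud.x0, ud.x0 + ud.nx * ud.resolution, 1000)
        y = rng.uniform(ud.y0, ud.y0 + ud.ny * ud.resolution, 1000)
        d = iso.distance(x, y)
        ix = np.floor((x - ud.x0) / ud.resolution).astype(int)
        iy = np.floor((y - ud.y0) / ud.resolution).astype(int)
        inside = iso.mask[iy, ix]
        assert (d[inside] < 0).all()
        assert (d[~inside] >= 0).all()

    def test_nesting_monotonicity(self, gaussian_ud):
        """50% region nests in 95% => signed distance to 50% >= to 95%."""
        rng = np.random.default_rng(6)
        iso50 = territory.isopleth_signed_distance(gaussian_ud, 50)
        iso95 = territory.isopleth_signed_distance(gaussian_ud, 95)
        ud = gaussian_ud
        x = rng.uniform(ud.x0 - 2000, ud.x0 + ud.nx * ud.resolution + 2000, 500)
        y = rng.uniform(ud.y0 - 2000, ud.y0 + ud.ny * ud.resolution + 2000, 500)
        assert (iso50.distance(x, y) >= iso95.distance(x, y) - 1e-9).all()

    def test_center_magnitude_matches_analytic_radius(self):
        """For an isotropic-Gaussian UD the 50% super-level set is a disk
        of radius r with mass(r) = 1 - exp(-r^2 / (2 s^2)); the signed
        distance at the center is -r within a cell."""
        fixes = _gaussian_fixes(n=4000, sd=2000.0, seed=7)
        ud = territory.rolling_ud(
            fixes, "p1", fixes["timestamp"].max() + pd.Timedelta(hours=1), 5000,
            bandwidth=300.0, resolution=200.0,
        )
        iso = territory.isopleth_signed_distance(ud, 50)
        s_eff = np.hypot(2000.0, 300.0)  # sample SD convolved with kernel
        r_expected = s_eff * np.sqrt(-2.0 * np.log(0.5))
        d_center = iso.distance([fixes["x"].mean()], [fixes["y"].mean()])[0]
        assert d_center < 0
        assert abs(-d_center - r_expected) < 3 * 200.0  # Monte-Carlo + grid

    def test_contour_point_near_zero(self, gaussian_ud):
        iso = territory.isopleth_signed_distance(gaussian_ud, 95)
        bx, by = iso._boundary_centers()
        d = iso.distance(bx[:50], by[:50])
        cell_diag = gaussian_ud.resolution * np.sqrt(2)
        assert (np.abs(d) <= cell_diag + 1e-9).all()

    def test_edge_touching_isopleth_raises(self):
        fixes = _gaussian_fixes(n=100, sd=3000.0)
        ud = territory.rolling_ud(
            fixes, "p1", "2021-02-01", 90, bandwidth=1000.0, resolution=250.0,
            extent=(-2000, -2000, 2000, 2000),
        )
        with pytest.raises(ValueError, match="touches the grid edge"):
            territory.isopleth_signed_distance(ud, 95)


@pytest.fixture(scope="module")
def three_pack_source():
    packs = [
        _gaussian_fixes(400, center=(0, 0), seed=1, pack="a"),
        _gaussian_fixes(400, center=(9000, 0), seed=2, pack="b"),
        _gaussian_fixes(400, center=(0, 9000), seed=3, pack="c"),
    ]
    return territory.UDTerritorySource(
        pd.concat(packs), windows=(7, 30), levels=(50, 95),
        resolution=400.0, bandwidth=600.0,
    )


class TestNeighborCovariates:
    def test_neighbor_is_min_over_packs(self, three_pack_source):
        """Aggregated neighbor value equals brute-force per-pack signed
        distance followed by the minimum."""
        src = three_pack_source
        rng = np.random.default_rng(8)
        x = rng.uniform(-3000, 12000, 40)
        y = rng.uniform(-3000, 12000, 40)
        when = pd.DatetimeIndex(["2021-01-20"] * 40)
        vals = src.values(np.array(["a"] * 40), when, x, y)
        date = pd.Timestamp("2021-01-20")
        for w in (7, 30):
            for lv in (50, 95):
                brute = np.minimum(
                    src.isopleth("b", date, w, lv).distance(x, y),
                    src.isopleth("c", date, w, lv).distance(x, y),
                ) / 1000.0
                np.testing.assert_allclose(
                    vals[f"dist_{w}_neigh_{lv}"], brute, atol=1e-9
                )
                own = src.isopleth("a", date, w, lv).distance(x, y) / 1000.0
                np.testing.assert_allclose(vals[f"dist_{w}_own_{lv}"], own, atol=1e-9)

    def test_completeness_requires_all_timescales(self, three_pack_source):
        src = three_pack_source
        # early date: windows have no fixes -> everything undefined
        vals = src.values(
            np.array(["a"]), pd.DatetimeIndex(["2021-01-01"]), [0.0], [0.0]
        )
        assert vals["territory_complete"].iloc[0] == 0.0
        vals2 = src.values(
            np.array(["a"]), pd.DatetimeIndex(["2021-02-01"]), [0.0], [0.0]
        )
        assert vals2["territory_complete"].iloc[0] == 1.0


class TestNearestConcurrentNeighbor:
    def _tracks(self):
        return pd.DataFrame(
            {
                "pack_id": ["b", "b"],
                "timestamp": pd.to_datetime(
                    ["2021-01-01 00:00", "2021-01-01 12:00"]
                ),
                "x": [3000.0, 0.0],
                "y": [4000.0, 0.0],
            }
        )

    def test_pythagorean_distance(self):
        d = territory.nearest_concurrent_neighbor(
            self._tracks(), "a", pd.DatetimeIndex(["2021-01-01 00:00"]), [0.0], [0.0]
        )
        assert d[0] == pytest.approx(5000.0)

    def test_lag_cutoff_excludes(self):
        d = territory.nearest_concurrent_neighbor(
            self._tracks(), "a", pd.DatetimeIndex(["2021-01-01 03:01"]), [0.0], [0.0]
        )
        assert np.isnan(d[0])  # nearest fix is 3 h 1 min away

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(11)
        n = 200
        tracks = pd.DataFrame(
            {
                "pack_id": rng.choice(["a", "b", "c"], n),
                "timestamp": pd.Timestamp("2021-01-01")
                + pd.to_timedelta(np.sort(rng.uniform(0, 72, n)), unit="h"),
                "x": rng.uniform(0, 10_000, n),
                "y": rng.uniform(0, 10_000, n),
            }
        )
        times = pd.Timestamp("2021-01-01") + pd.to_timedelta(
            rng.uniform(0, 72, 50), unit="h"
        )
        qx = rng.uniform(0, 10_000, 50)
        qy = rng.uniform(0, 10_000, 50)
        ours = territory.nearest_concurrent_neighbor(
            tracks, "a", pd.DatetimeIndex(times), qx, qy
        )
        others = tracks[tracks["pack_id"] != "a"]
        for i in range(50):
            dt = np.abs(others["timestamp"] - times[i]) <= pd.Timedelta(hours=3)
            if dt.any():
                brute = np.hypot(
                    others.loc[dt, "x"] - qx[i], others.loc[dt, "y"] - qy[i]
                ).min()
                assert ours[i] == pytest.approx(brute)
            else:
                assert np.isnan(ours[i])
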