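"""Occurrence partition, cell deduplication, Moran's I, thinning, boundaries."""

import numpy as np
import pandas as pd
import pytest

from nichemap.grids import Grid, GridStack
from nichemap.occurrences import (
    ThinningError,
    boundary_summary,
    dedupe_to_cells,
    morans_i,
    partition_datasets,
    thin_by_morans,
)


def rec(lon, lat, year, greenhouse=False, summer_only=False, elevation=np.nan):
    return dict(lon=lon, lat=lat, year=year, greenhouse=greenhouse, summer_only=summer_only, elevation=elevation)


def brute_force_morans(lons, lats, values, max_weight=1e6):
    """Independent O(n^2) double-sum evaluation with explicit loops."""
    n = len(values)
    z = np.asarray(values, float) - np.mean(values)
    num = s0 = 0.0
    R = 6371.0088
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p1 = np.deg2rad([lats[i], lons[i]])
            p2 = np.deg2rad([lats[j], lons[j]])
            a = np.sin((p2[0] - p1[0]) / 2) ** 2 + np.cos(p1[0]) * np.cos(p2[0]) * np.sin((p2[1] - p1[1]) / 2) ** 2
            d = 2 * R * np.arcsin(np.sqrt(a))
            w = max_weight if d == 0 else min(1.0 / d, max_weight)
            num += w * z[i] * z[j]
            s0 += w
    return (n / s0) * num / np.sum(z**2)


class TestPartition:
    def test_window_and_flag_rules(self):
        df = pd.DataFrame(
            [
                rec(0, 0, 1995),  # basic
                rec(1, 0, 2018),  # expanded_only
                rec(2, 0, 2000, greenhouse=True),  # excluded by flag
                rec(3, 0, 2023, summer_only=True),  # excluded by flag
            ]
        )
        out = partition_datasets(df)
        assert out["partition"].tolist() == ["basic", "expanded_only", "excluded", "excluded"]

    def test_exhaustive_and_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            [
                rec(float(x), float(y), int(yr), gh, so)
                for x, y, yr, gh, so in zip(
                    rng.uniform(-10, 10, 50),
                    rng.uniform(-10, 10, 50),
                    rng.integers(1950, 2030, 50),
                    rng.random(50) < 0.2,
                    rng.random(50) < 0.2,
                )
            ]
        )
        with pytest.warns(UserWarning):
            out = partition_datasets(df)
        counts = out["partition"].value_counts()
        assert counts.sum() == len(df)
        with pytest.warns(UserWarning):
            again = partition_datasets(out)
        assert again["partition"].tolist() == out["partition"].tolist()

    def test_year_window_edges(self):
        df = pd.DataFrame([rec(0, 0, 1981), rec(0, 1, 2010), rec(0, 2, 2011), rec(0, 3, 2024)])
        out = partition_datasets(df)
        assert out["partition"].tolist() == ["basic", "basic", "expanded_only", "expanded_only"]

    def test_missing_year_excluded_with_warning(self):
        df = pd.DataFrame([rec(0, 0, np.nan)])
        with pytest.warns(UserWarning):
            out = partition_datasets(df)
        assert out["partition"].tolist() == ["excluded"]


class TestDedupe:
    grid = Grid(np.zeros((10, 10)), np.zeros((10, 10), bool), 0.0, 0.0, 1.0)

    def test_five_records_three_cells(self):
        df = pd.DataFrame(
            [
                rec(0.5, 9.5, 2000),
                rec(0.6, 9.6, 1999),  # same cell as above, earlier year -> kept
                rec(1.5, 9.5, 2000),
                rec(1.4, 9.4, 2005),
                rec(2.5, 9.5, 2001),
            ]
        )
        out = dedupe_to_cells(df, self.grid)
        assert len(out) == 3
        assert 1999 in out["year"].values and 2005 not in out["year"].values

    def test_distinct_cells_unchanged(self):
        df = pd.DataFrame([rec(0.5 + i, 0.5, 2000) for i in range(5)])
        out = dedupe_to_cells(df, self.grid)
        assert len(out) == 5

    def test_outside_extent_dropped_with_warning(self):
        df = pd.DataFrame([rec(0.5, 0.5, 2000), rec(50.0, 0.5, 2000)])
        with pytest.warns(UserWarning, match="outside"):
            out = dedupe_to_cells(df, self.grid)
        assert len(out) == 1


class TestMoransI:
    def test_two_point_antithesis(self):
        s = morans_i([0.0, 1.0], [0.0, 0.0], [0.0, 1.0])
        assert np.isclose(s.morans_i, -1.0, atol=1e-12)

    def test_null_expectation_random_values(self):
        rng = np.random.default_rng(42)
        lons = rng.uniform(-10, 10, 200)
        lats = rng.uniform(-10, 10, 200)
        s = morans_i(lons, lats, rng.standard_normal(200))
        assert abs(s.morans_i) < 0.1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            lons = rng.uniform(-5, 5, 12)
            lats = rng.uniform(-5, 5, 12)
            vals = rng.standard_normal(12)
            mine = morans_i(lons, lats, vals).morans_i
            assert np.isclose(mine, brute_force_morans(lons, lats, vals), atol=1e-12)

    def test_unit_square_fixture(self):
        lons = [0.0, 1.0, 0.0, 1.0]
        lats = [0.0, 0.0, 1.0, 1.0]
        vals = [1.0, 1.0, 0.0, 0.0]
        mine = morans_i(lons, lats, vals).morans_i
        assert np.isclose(mine, brute_force_morans(lons, lats, vals), atol=1e-12)

    def test_constant_values_error(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i([0, 1], [0, 1], [2.0, 2.0])

    def test_duplicate_coordinates_capped(self):
        with pytest.warns(UserWarning, match="capped"):
            s = morans_i([0, 0, 1], [0, 0, 0], [0.0, 1.0, 0.5])
        assert np.isfinite(s.morans_i)


def clustered_world(n_scatter=25, n_cluster=10, seed=0):
    """A gradient-valued layer and a point set with a tight cluster, so that
    Moran's I at the points starts above 0.2."""
    rng = np.random.default_rng(seed)
    nr = nc = 40
    lat_grad = np.linspace(10, -10, nr)[:, None] * np.ones((1, nc))
    vals = lat_grad + 0.01 * rng.standard_normal((nr, nc))
    g = Grid(vals, np.zeros((nr, nc), bool), -10.0, -10.0, 0.5)
    stack = GridStack({"v": g})
    lon_s = rng.uniform(-9, 9, n_scatter)
    lat_s = rng.uniform(-9, 9, n_scatter)
    lon_c = 5.0 + 0.3 * rng.standard_normal(n_cluster)
    lat_c = 5.0 + 0.3 * rng.standard_normal(n_cluster)
    df = pd.DataFrame(
        [rec(x, y, 2000 + i) for i, (x, y) in enumerate(zip(np.r_[lon_s, lon_c], np.r_[lat_s, lat_c]))]
    )
    return df, stack, n_scatter


class TestThinning:
    def test_noop_when_already_below_target(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame([rec(x, y, 2000) for x, y in zip(rng.uniform(-9, 9, 30), rng.uniform(-9, 9, 30))])
        g = Grid(rng.standard_normal((40, 40)), np.zeros((40, 40), bool), -10, -10, 0.5)
        stack = GridStack({"v": g})
        out, final_i, _ = thin_by_morans(df, stack, target=0.9, min_records=5)
        assert len(out) == len(df)

    def test_reaches_target_and_matches_oracle(self):
        df, stack, _ = clustered_world()
        out, final_i, log = thin_by_morans(df, stack, target=0.2, min_records=10)
        assert len(out) < len(df)
        assert max(final_i.values()) < 0.2
        vals = stack.values_at(out["lon"].to_numpy(), out["lat"].to_numpy())[:, 0]
        oracle = brute_force_morans(out["lon"].to_numpy(), out["lat"].to_numpy(), vals)
        assert np.isclose(max(final_i.values()), oracle, atol=1e-12)

    def test_cluster_depleted_first_and_closest_pair_replay(self):
        import re

        df, stack, n_scatter = clustered_world()
        _, _, log = thin_by_morans(df, stack, target=0.2, min_records=10)
        order = [int(m.group(1)) for m in (re.match(r"removed record (\d+)", l) for l in log) if m]
        assert order, "nothing was thinned"
        # the tight cluster is depleted first
        assert all(i >= n_scatter for i in order[:5])
        # oracle replay: every removal is a member of the then-closest pair
        lons = df["lon"].to_numpy()
        lats = df["lat"].to_numpy()
        keep = np.ones(len(df), bool)
        for drop in order:
            idx = np.flatnonzero(keep)
            best, pair = np.inf, None
            for ii in range(len(idx)):
                for jj in range(ii + 1, len(idx)):
                    i, j = idx[ii], idx[jj]
                    p1, p2 = np.deg2rad([lats[i], lons[i]]), np.deg2rad([lats[j], lons[j]])
                    h = np.sin((p2[0] - p1[0]) / 2) ** 2 + np.cos(p1[0]) * np.cos(p2[0]) * np.sin((p2[1] - p1[1]) / 2) ** 2
                    d = 2 * np.arcsin(np.sqrt(h))
                    if d < best:
                        best, pair = d, (i, j)
            assert drop in pair
            keep[drop] = False

    def test_output_is_subset(self):
        df, stack, _ = clustered_world(seed=3)
        out, _, _ = thin_by_morans(df, stack, target=0.2, min_records=10)
        merged = df.merge(out, on=["lon", "lat", "year"])
        assert len(merged) == len(out)

    def test_unreachable_target_raises(self):
        df, stack, _ = clustered_world()
        with pytest.raises(ThinningError):
            thin_by_morans(df, stack, target=1e-6, min_records=30)


class TestBoundary:
    def test_identical_datasets_zero(self):
        df = pd.DataFrame([rec(0, 0, 2000, elevation=100.0), rec(5, 5, 2001, elevation=200.0)])
        out = boundary_summary(df, df)
        assert all(v == 0 for v in out.values())

    def test_eastward_extension(self):
        a = pd.DataFrame([rec(0, 0, 2000), rec(5, 5, 2001)])
        b = pd.concat([a, pd.DataFrame([rec(15.0, 2, 2020)])], ignore_index=True)
        out = boundary_summary(a, b)
        assert out["delta_max_lon"] == 10.0
        assert out["delta_min_lon"] == 0.0

    def test_matches_direct_scan(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame([rec(x, y, 2000, elevation=e) for x, y, e in zip(rng.uniform(-20, 20, 30), rng.uniform(-20, 20, 30), rng.uniform(0, 3000, 30))])
        b = pd.DataFrame([rec(x, y, 2020, elevation=e) for x, y, e in zip(rng.uniform(-30, 30, 40), rng.uniform(-30, 30, 40), rng.uniform(0, 4000, 40))])
        out = boundary_summary(a, b)
        assert out["delta_max_lat"] == b["lat"].max() - a["lat"].max()
        assert out["delta_min_lat"] == b["lat"].min() - a["lat"].min()
        assert out["delta_max_elevation"] == b["elevation"].max() - a["elevation"].max()
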