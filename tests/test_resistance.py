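"""Resistance surfaces and circuit-theory effective resistance."""

import numpy as np
import pandas as pd
import pytest

from urbanscape.resistance import (
    AsciiGrid,
    CostScheme,
    ResistanceSurface,
    _build_laplacian,
    build_surface,
    effective_resistance,
    read_ascii_grid,
)
from urbanscape.synthetic import LAND_COVER_CODES, write_ascii_grid


def focal_frame(points):
    return pd.DataFrame(
        {"colony_id": [f"f{i}" for i in range(len(points))],
         "lon": [p[0] for p in points], "lat": [p[1] for p in points]}
    )


def laplacian_pinv_resistance(surface, points, neighbourhood=8):
    """Dense eigendecomposition pseudo-inverse oracle: R_ij = L+_ii + L+_jj - 2 L+_ij."""
    lap, node = _build_laplacian(surface, neighbourhood)
    L = lap.toarray()
    w, v = np.linalg.eigh(L)
    inv_w = np.where(w > 1e-9 * w.max(), 1.0 / np.where(w == 0, 1, w), 0.0)
    Lp = (v * inv_w) @ v.T
    out = []
    for (x1, y1), (x2, y2) in points:
        a = node[surface.grid.cell_of(x1, y1)]
        b = node[surface.grid.cell_of(x2, y2)]
        out.append(Lp[a, a] + Lp[b, b] - 2 * Lp[a, b])
    return out


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path):
        grid = np.array([[1.0, 2.0, np.nan], [4.0, 5.0, 6.0]])
        p = tmp_path / "g.asc"
        write_ascii_grid(p, grid, 10.0, 20.0, 0.5)
        back = read_ascii_grid(p)
        np.testing.assert_allclose(back.data, grid)
        assert (back.xll, back.yll, back.cellsize) == (10.0, 20.0, 0.5)

    def test_cell_lookup_row_zero_is_north(self):
        g = AsciiGrid(np.zeros((3, 4)), 0.0, 0.0, 1.0)
        assert g.cell_of(0.5, 2.5) == (0, 0)  # top-left
        assert g.cell_of(3.5, 0.5) == (2, 3)  # bottom-right
        with pytest.raises(ValueError):
            g.cell_of(10.0, 0.0)


class TestBuildSurface:
    def layers(self, light=None, tree=None, land=None, orchard=None, shape=(5, 5)):
        mk = lambda a: AsciiGrid(np.asarray(a, dtype=float), 0, 0, 1.0)
        if orchard is None:
            orchard = np.zeros(shape)
            orchard[0, 0] = 1.0
        return {
            "light": mk(light if light is not None else np.zeros(shape)),
            "tree_cover": mk(tree if tree is not None else np.zeros(shape)),
            "land_cover": mk(land if land is not None else np.full(shape, 1.0)),
            "orchard": mk(orchard),
        }

    def test_zero_light_gives_uniform_minimum_cost(self):
        s = build_surface(CostScheme("light"), self.layers())
        np.testing.assert_allclose(s.grid.data, 1.0)

    def test_tree_cover_endpoints(self):
        tree = np.zeros((5, 5))
        tree[0, 0] = 100.0
        s = build_surface(CostScheme("tree_cover"), self.layers(tree=tree))
        assert s.grid.data[0, 0] == pytest.approx(1.0)
        assert s.grid.data[1, 1] == pytest.approx(100.0)

    def test_land_cover_3_exact_table_lookup(self):
        land = np.array([[LAND_COVER_CODES[k] for k in LAND_COVER_CODES]], dtype=float)
        s = build_surface(CostScheme("land_cover_3"), self.layers(land=land, shape=(1, 6)))
        np.testing.assert_allclose(s.grid.data[0], [10, 1, 10, 80, 90, 100])

    def test_urban_cost_varies_by_scenario(self):
        land = np.full((2, 2), float(LAND_COVER_CODES["urban"]))
        costs = [
            build_surface(CostScheme(h), self.layers(land=land, shape=(2, 2))).grid.data[0, 0]
            for h in ("land_cover_1", "land_cover_2", "land_cover_3")
        ]
        assert costs == [50.0, 30.0, 10.0]

    def test_unknown_category_code_named_in_error(self):
        land = np.full((2, 2), 77.0)
        with pytest.raises(ValueError, match="77"):
            build_surface(CostScheme("land_cover_1"), self.layers(land=land, shape=(2, 2)))

    def test_orchard_plus_light_is_mean_of_components(self):
        rng = np.random.default_rng(0)
        layers = self.layers(light=rng.uniform(0, 60, (5, 5)))
        s1 = build_surface(CostScheme("orchard_distance"), layers)
        s2 = build_surface(CostScheme("light"), layers)
        s3 = build_surface(CostScheme("orchard_plus_light"), layers)
        np.testing.assert_allclose(s3.grid.data, (s1.grid.data + s2.grid.data) / 2)

    def test_unregistered_layers_rejected(self):
        layers = self.layers()
        layers["light"] = AsciiGrid(np.zeros((6, 6)), 0, 0, 1.0)
        with pytest.raises(ValueError):
            build_surface(CostScheme("light"), layers)

    def test_costs_stay_in_range(self):
        rng = np.random.default_rng(1)
        layers = self.layers(light=rng.uniform(0, 63, (5, 5)), tree=rng.uniform(0, 100, (5, 5)))
        for h in ("light", "tree_cover", "orchard_distance", "orchard_plus_light"):
            s = build_surface(CostScheme(h), layers)
            assert np.nanmin(s.grid.data) >= 1.0 and np.nanmax(s.grid.data) <= 100.0


class TestEffectiveResistance:
    def test_series_resistors(self):
        s = ResistanceSurface(AsciiGrid(np.ones((1, 3)), 0, 0, 1.0))
        r = effective_resistance(s, focal_frame([(0.5, 0.5), (2.5, 0.5)]), 4)
        assert r.values[0, 1] == pytest.approx(2.0)

    def test_four_cycle_parallel_paths(self):
        s = ResistanceSurface(AsciiGrid(np.ones((2, 2)), 0, 0, 1.0))
        r = effective_resistance(s, focal_frame([(0.5, 1.5), (1.5, 0.5)]), 4)
        assert r.values[0, 1] == pytest.approx(1.0)

    def test_matches_pseudo_inverse_oracle(self):
        rng = np.random.default_rng(2)
        s = ResistanceSurface(AsciiGrid(rng.uniform(1, 100, (8, 8)), 0, 0, 1.0))
        pts = [(0.5, 0.5), (7.5, 7.5), (3.5, 4.5)]
        r = effective_resistance(s, focal_frame(pts), 8)
        oracle = laplacian_pinv_resistance(s, [(pts[0], pts[1]), (pts[0], pts[2]), (pts[1], pts[2])])
        assert abs(r.values[0, 1] - oracle[0]) < 1e-6
        assert abs(r.values[0, 2] - oracle[1]) < 1e-6
        assert abs(r.values[1, 2] - oracle[2]) < 1e-6

    def test_metric_properties_on_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            s = ResistanceSurface(AsciiGrid(rng.uniform(1, 50, (5, 5)), 0, 0, 1.0))
            pts = [(0.5, 0.5), (4.5, 4.5), (2.5, 2.5), (4.5, 0.5)]
            r = effective_resistance(s, focal_frame(pts), 8).values
            np.testing.assert_allclose(r, r.T)
            n = len(pts)
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert r[i, j] <= r[i, k] + r[k, j] + 1e-9

    def test_linearity_in_costs(self):
        rng = np.random.default_rng(4)
        cost = rng.uniform(1, 50, (6, 6))
        pts = [(0.5, 0.5), (5.5, 5.5)]
        r1 = effective_resistance(ResistanceSurface(AsciiGrid(cost, 0, 0, 1.0)), focal_frame(pts), 8)
        r2 = effective_resistance(ResistanceSurface(AsciiGrid(cost * 2, 0, 0, 1.0)), focal_frame(pts), 8)
        assert r2.values[0, 1] == pytest.approx(2 * r1.values[0, 1], rel=1e-9)

    def test_current_conservation_at_interior_nodes(self):
        rng = np.random.default_rng(5)
        s = ResistanceSurface(AsciiGrid(rng.uniform(1, 20, (6, 6)), 0, 0, 1.0))
        pts = [(0.5, 0.5), (5.5, 5.5)]
        lap, node = _build_laplacian(s, 8)
        a = node[s.grid.cell_of(*pts[0])]
        b = node[s.grid.cell_of(*pts[1])]
        # recover potentials by dense solve and check net current injection
        L = lap.toarray()
        e = np.zeros(L.shape[0])
        e[a], e[b] = 1.0, -1.0
        v = np.linalg.lstsq(L, e, rcond=None)[0]
        net = L @ v
        interior = np.ones(len(net), dtype=bool)
        interior[[a, b]] = False
        assert np.abs(net[interior]).max() < 1e-8

    def test_disconnected_pair_flagged_infinite(self):
        grid = np.ones((3, 5))
        grid[:, 2] = np.nan
        s = ResistanceSurface(AsciiGrid(grid, 0, 0, 1.0))
        r = effective_resistance(s, focal_frame([(0.5, 1.5), (4.5, 1.5)]), 4)
        assert np.isinf(r.values[0, 1])

    def test_focal_on_nodata_rejected(self):
        grid = np.ones((3, 3))
        grid[1, 1] = np.nan
        s = ResistanceSurface(AsciiGrid(grid, 0, 0, 1.0))
        with pytest.raises(ValueError, match="NODATA"):
            effective_resistance(s, focal_frame([(1.5, 1.5), (0.5, 0.5)]), 8)

    def test_costs_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ResistanceSurface(AsciiGrid(np.full((2, 2), 0.5), 0, 0, 1.0))
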