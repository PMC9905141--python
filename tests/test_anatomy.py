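"""Tests of surface fitting, depth normalization, layer assignment, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import subplate as sp
from subplate.anatomy import LAYER_ORDER, assign_layer
from subplate.synthetic import CellCloud


def grid_points(f, lx=600.0, ly=350.0, step=25.0):
    xs = np.arange(0.0, lx + step / 2, step)
    ys = np.arange(0.0, ly + step / 2, step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), f(gx, gy).ravel()])


class TestLayerScheme:
    def test_bundled_schemes_load_and_renormalize(self):
        for area in ("M1", "S1Bf", "S2"):
            scheme = sp.load_scheme(area)
            assert scheme.layers == LAYER_ORDER
            assert scheme.thickness_renormalized().sum() == pytest.approx(1.0)
            b = scheme.depth_boundaries()
            assert b[0] == 0.0 and b[-1] == 1.0
            assert np.all(np.diff(b) > 0)

    def test_s1bf_cumulative_boundaries(self):
        b = sp.load_scheme("S1Bf").depth_boundaries()
        np.testing.assert_allclose(
            b[1:-1], [0.0724, 0.3257, 0.6370, 0.9090], atol=5e-4
        )

    def test_verbatim_s2_variant_loadable(self):
        verbatim = sp.load_scheme("S2", thickness_variant="verbatim")
        assert verbatim.thickness["L6"] == 0.867
        corrected = sp.load_scheme("S2")
        assert corrected.thickness["L6"] == 0.267


class TestFitSurface:
    def test_plane_fit_is_exact(self):
        pts = grid_points(lambda x, y: np.full_like(x, 100.0))
        m = sp.fit_surface(pts)
        assert m.rms_residual < 1e-9
        np.testing.assert_allclose(m.coeffs, [100, 0, 0, 0, 0, 0], atol=1e-9)

    def test_quadratic_coefficients_recovered(self):
        pts = grid_points(lambda x, y: x * x / 1000.0)
        m = sp.fit_surface(pts)
        np.testing.assert_allclose(m.coeffs[3], 1e-3, rtol=1e-6)
        assert np.all(np.abs(m.coeffs[[0, 1, 2, 4, 5]]) < 1e-6)

    def test_underdetermined_and_degenerate_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            sp.fit_surface(np.zeros((5, 3)))
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="rank-deficient|degenerate"):
            sp.fit_surface(line)


class TestPointSurfaceDistance:
    def test_plane_distance(self):
        m = sp.fit_surface(grid_points(lambda x, y: np.zeros_like(x)))
        assert sp.point_surface_distance(m, (100.0, 100.0, 250.0)) == pytest.approx(250.0)
        # above the surface (smaller z) is negative
        assert sp.point_surface_distance(m, (100.0, 100.0, -50.0)) == pytest.approx(-50.0)

    def test_point_on_surface_zero(self):
        m = sp.fit_surface(grid_points(lambda x, y: 0.2 * x + 1e-4 * y * y))
        z = float(m(200.0, 100.0))
        assert abs(sp.point_surface_distance(m, (200.0, 100.0, z))) < 1e-6

    def test_matches_dense_grid_oracle(self, rng):
        m = sp.fit_surface(grid_points(lambda x, y: 0.1 * x - 0.05 * y + 2e-4 * x * y))
        for _ in range(100):
            p = (rng.uniform(100, 500), rng.uniform(50, 300), rng.uniform(50, 600))
            d = abs(sp.point_surface_distance(m, p))
            gx = np.arange(p[0] - 200, p[0] + 200, 1.0)
            gy = np.arange(p[1] - 200, p[1] + 200, 1.0)
            gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
            oracle = np.sqrt(
                (gxx - p[0]) ** 2 + (gyy - p[1]) ** 2 + (m(gxx, gyy) - p[2]) ** 2
            ).min()
            assert abs(d - oracle) < 0.5


class TestNormalizedDepth:
    def _cloud(self, coords, area="S1Bf"):
        frame = pd.DataFrame(coords, columns=["x_um", "y_um", "z_um"])
        frame.insert(0, "cell_id", np.arange(len(frame)))
        frame["true_layer"] = ""
        frame["backlabeled"] = 0
        return CellCloud(frame=frame, area=area)

    def test_flat_surfaces_closed_form(self):
        pial = sp.fit_surface(grid_points(lambda x, y: np.zeros_like(x)))
        lower = sp.fit_surface(grid_points(lambda x, y: np.full_like(x, 1000.0)))
        cells = sp.normalized_depths(self._cloud([(300.0, 175.0, 250.0)]), pial, lower)
        assert cells["normalized_depth"].iloc[0] == pytest.approx(0.25, abs=1e-9)
        assert cells["local_thickness_um"].iloc[0] == pytest.approx(1000.0)

    def test_cells_on_surfaces_hit_bounds(self):
        pial = sp.fit_surface(grid_points(lambda x, y: np.zeros_like(x)))
        lower = sp.fit_surface(grid_points(lambda x, y: np.full_like(x, 700.0)))
        cells = sp.normalized_depths(
            self._cloud([(300.0, 175.0, 0.0), (300.0, 175.0, 700.0)]), pial, lower
        )
        assert cells["normalized_depth"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert cells["normalized_depth"].iloc[1] == pytest.approx(1.0, abs=1e-9)

    def test_curved_surfaces_recover_generator_truth(self):
        scheme = sp.load_scheme("S1Bf")
        vol = sp.VolumeSpec(
            pial_coeffs=(10.0, 0.05, -0.03, 1e-4, -5e-5, 8e-5),
            mean_thickness=700.0,
            n_neurons=600,
        )
        cloud, pial_pts, sp_pts = sp.generate_cortical_volume(vol, scheme, seed=3)
        pial = sp.fit_surface(pial_pts)
        lower = sp.fit_surface(sp_pts)
        cells = sp.normalized_depths(cloud, pial, lower, scheme)
        err = np.abs(cells["normalized_depth"] - cells["true_depth"])
        assert err.max() < 0.01

    def test_invariance_under_translation_and_scaling(self):
        f = lambda x, y: 5.0 + 0.02 * x + 1e-4 * y * y
        g = lambda x, y: f(x, y) + 700.0
        cells0 = sp.normalized_depths(
            self._cloud([(300.0, 175.0, 400.0)]),
            sp.fit_surface(grid_points(f)),
            sp.fit_surface(grid_points(g)),
        )
        shift = np.array([50.0, -20.0, 30.0])
        fs = lambda x, y: f(x - shift[0], y - shift[1]) + shift[2]
        gs = lambda x, y: g(x - shift[0], y - shift[1]) + shift[2]
        cells1 = sp.normalized_depths(
            self._cloud([(350.0, 155.0, 430.0)]),
            sp.fit_surface(grid_points(fs)),
            sp.fit_surface(grid_points(gs)),
        )
        k = 2.0
        fk = lambda x, y: k * f(x / k, y / k)
        gk = lambda x, y: k * g(x / k, y / k)
        cells2 = sp.normalized_depths(
            self._cloud([(600.0, 350.0, 800.0)]),
            sp.fit_surface(grid_points(fk, lx=1200, ly=700)),
            sp.fit_surface(grid_points(gk, lx=1200, ly=700)),
        )
        d0 = cells0["normalized_depth"].iloc[0]
        assert cells1["normalized_depth"].iloc[0] == pytest.approx(d0, abs=1e-6)
        assert cells2["normalized_depth"].iloc[0] == pytest.approx(d0, abs=1e-6)


class TestAssignLayer:
    def test_reference_depths(self):
        scheme = sp.load_scheme("S1Bf")
        assert assign_layer(0.5, scheme) == "L5"
        assert assign_layer(0.0, scheme) == "MZ"
        assert assign_layer(1.0, scheme) == "SP"

    def test_boundary_goes_to_deeper_layer(self):
        scheme = sp.load_scheme("S1Bf")
        b = scheme.depth_boundaries()
        assert assign_layer(b[1], scheme) == "CP"
        assert assign_layer(b[2], scheme) == "L5"

    def test_partition_of_unit_interval(self):
        scheme = sp.load_scheme("M1")
        depths = np.linspace(0, 1, 501)
        labels = [assign_layer(d, scheme) for d in depths]
        assert set(labels) == set(LAYER_ORDER)
        # depth order must follow layer order
        first_seen = [labels.index(l) for l in LAYER_ORDER]
        assert first_seen == sorted(first_seen)


class TestLayerProportions:
    def test_printed_percentages_from_counts(self):
        out = sp.layer_proportions({"L6": 41, "L5": 37, "CP": 18, "SP": 15})
        by = out.set_index("layer")["percent"]
        assert (by["L6"], by["L5"], by["CP"], by["SP"]) == (36, 33, 16, 13)
        assert out.attrs["total"] == 111

    def test_single_layer_is_100(self):
        out = sp.layer_proportions({"SP": 7})
        assert out.set_index("layer")["percent"]["SP"] == 100

    def test_floored_percentages_sum_at_most_100(self, rng):
        for _ in range(20):
            counts = {l: int(rng.integers(0, 50)) for l in LAYER_ORDER}
            if sum(counts.values()) == 0:
                counts["CP"] = 1
            out = sp.layer_proportions(counts)
            assert out["percent"].sum() <= 100


class TestEnrichment:
    def test_exactly_proportional_counts_give_p_one(self):
        scheme = sp.load_scheme("S1Bf")
        p = scheme.proportions_renormalized(include=("CP", "L5", "L6", "SP"))
        counts = dict(zip(("CP", "L5", "L6", "SP"), np.round(p * 10000).astype(int)))
        res = sp.enrichment_test(counts, scheme)
        assert res.chi2 == pytest.approx(0.0, abs=0.05)
        assert res.p_value > 0.99

    def test_exact_binomial_reference_value(self):
        # direct check of the two-sided exact binomial convention: 8/10 vs 0.5
        assert stats.binomtest(8, 10, 0.5).pvalue == pytest.approx(112 / 1024)

    def test_enriched_layer_flagged_with_direction(self):
        scheme = sp.load_scheme("S1Bf")
        res = sp.enrichment_test({"CP": 100, "L5": 400, "L6": 300, "SP": 100}, scheme)
        assert res.significant
        assert res.direction["L5"] == "enriched"
        assert res.binomial_p["L5"] < 0.01
        assert res.direction["CP"] == "depleted"

    def test_small_sample_rejected_and_df(self):
        scheme = sp.load_scheme("M1")
        with pytest.raises(ValueError):
            sp.enrichment_test({"L5": 2}, scheme)
        res = sp.enrichment_test({"CP": 10, "L5": 10, "L6": 10, "SP": 10}, scheme)
        assert res.df == 3

    def test_pipeline_layer_recovery_away_from_boundaries(self):
        scheme = sp.load_scheme("S1Bf")
        vol = sp.VolumeSpec(
            pial_coeffs=(5.0, 0.03, -0.02, 5e-5, -3e-5, 4e-5),
            mean_thickness=700.0,
            n_neurons=2000,
        )
        cloud, pial_pts, sp_pts = sp.generate_cortical_volume(vol, scheme, seed=9)
        pial = sp.fit_surface(pial_pts)
        lower = sp.fit_surface(sp_pts)
        cells = sp.normalized_depths(cloud, pial, lower, scheme)
        margin = 2.0 / 700.0  # two microns in normalized units
        b = scheme.depth_boundaries()[1:-1]
        away = np.all(np.abs(cells["true_depth"].to_numpy()[:, None] - b[None, :]) > margin, axis=1)
        frac = (cells.loc[away, "assigned_layer"] == cells.loc[away, "true_layer"]).mean()
        assert frac >= 0.99
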