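"""Growth domain: outlines, triangulation quality, transfer-map conservation."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import limbgrn as lg
from limbgrn.geometry import (AER_FGF4_SOURCE, AER_SOURCE, FLANK_SOURCE,
                              GeometryParams, MeshError, compute_transfer_map,
                              growth_displacement, stage_of_hour, triangulate)


class TestOutline:
    def test_initial_pd_extent_matches_configuration(self):
        params = GeometryParams()
        poly = lg.build_limb_outline(0, params)
        xs = np.asarray(poly.exterior.coords)[:, 0]
        assert xs.max() == pytest.approx(params.initial_pd_extent, rel=1e-6)

    def test_growth_is_monotone_in_extent_and_area(self):
        params = GeometryParams()
        polys = [lg.build_limb_outline(h, params) for h in range(37)]
        extents = [np.asarray(p.exterior.coords)[:, 0].max() for p in polys]
        areas = [p.area for p in polys]
        assert all(b > a for a, b in zip(extents, extents[1:]))
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_degenerate_parameters_rejected(self):
        bad = GeometryParams(initial_pd_extent=-10.0)
        with pytest.raises(MeshError):
            lg.build_limb_outline(0, bad)


class TestTriangulate:
    def test_area_conservation_on_unit_square(self):
        square = Polygon([(0, -0.5), (1, -0.5), (1, 0.5), (0, 0.5)])
        params = GeometryParams(initial_pd_extent=1.0, final_pd_extent=2.0,
                                flank_half_width=0.5, flank_widening_rate=0.0)
        mesh = triangulate(square, 0.25, hour=0, params=params)
        assert mesh.element_area.sum() == pytest.approx(1.0, abs=1e-9)

    def test_quality_floor_and_orientation(self, tiny_series):
        for mesh in tiny_series.meshes:
            assert mesh.min_quality() >= 0.08
            assert np.all(mesh.element_area > 0)

    def test_source_labels_disjoint_and_placed(self, tiny_series):
        params = tiny_series.params
        for mesh in tiny_series.meshes:
            flank = set(mesh.elements_in_region(FLANK_SOURCE))
            aer = set(mesh.elements_in_region(AER_SOURCE))
            fgf4 = set(mesh.elements_in_region(AER_FGF4_SOURCE))
            assert not flank & (aer | fgf4)
            assert not aer & fgf4
            L = params.pd_extent(mesh.hour)
            # flank sources hug the body-side boundary, AER the distal arc
            assert mesh.centroids[list(flank), 0].max() < 0.35 * L
            assert mesh.centroids[list(aer | fgf4), 0].min() > 0.1 * L

    def test_fgf4_subregion_is_posterior_and_expands(self):
        params = GeometryParams()
        assert params.fgf4_fraction(0) == pytest.approx(0.3)
        assert params.fgf4_fraction(18) == pytest.approx(1.0)
        outline = lg.build_limb_outline(0, params)
        mesh = triangulate(outline, 45.0, hour=0, params=params)
        fgf4 = mesh.elements_in_region(AER_FGF4_SOURCE)
        aer8 = mesh.elements_in_region(AER_SOURCE)
        assert len(fgf4) and len(aer8)
        # posterior = negative y
        assert mesh.centroids[fgf4, 1].mean() < mesh.centroids[aer8, 1].mean()

    def test_too_large_edge_rejected(self):
        params = GeometryParams()
        outline = lg.build_limb_outline(0, params)
        with pytest.raises(MeshError):
            triangulate(outline, 500.0, hour=0, params=params)


class TestTransferMap:
    def test_identity_when_meshes_coincide(self, tiny_series):
        mesh = tiny_series.meshes[0]
        tmap = compute_transfer_map(mesh, mesh)
        rng = np.random.default_rng(0)
        c = rng.uniform(0.0, 1.0, mesh.n_elements)
        out = tmap.remap_concentration(c, mesh, mesh)
        assert np.allclose(out, c, atol=1e-12)

    def test_columns_sum_to_one(self, tiny_series):
        for tmap in tiny_series.transfer_maps:
            cols = np.asarray(tmap.matrix.sum(axis=0)).ravel()
            assert np.abs(cols - 1.0).max() < 1e-9
            assert tmap.matrix.min() >= 0.0

    def test_uniform_field_fixed_point_without_growth(self, tiny_series):
        # the same boundary triangulated with two interior lattices: a
        # constant field must survive the remesh exactly (the area-weighted
        # average of a constant is that constant)
        params = tiny_series.params
        outline = lg.build_limb_outline(1, params)
        a = triangulate(outline, 90.0, hour=1, params=params)
        b = triangulate(outline, 90.0, hour=1, params=params,
                        lattice_offset=0.41)
        assert not np.array_equal(a.centroids, b.centroids)
        tmap = compute_transfer_map(a, b)
        out = tmap.remap_concentration(np.full(a.n_elements, 0.7), a, b)
        assert np.allclose(out, 0.7, atol=1e-9)

    def test_total_amount_conserved_for_random_fields(self, tiny_series):
        rng = np.random.default_rng(42)
        for h, tmap in enumerate(tiny_series.transfer_maps):
            old, new = tiny_series.meshes[h], tiny_series.meshes[h + 1]
            c = rng.uniform(0.0, 2.0, (3, old.n_elements))
            out = tmap.remap_concentration(c, old, new)
            before = (c * old.element_area).sum(axis=1)
            after = (out * new.element_area).sum(axis=1)
            assert np.allclose(after, before, rtol=1e-6)

    def test_displacement_is_pd_biased(self):
        params = GeometryParams()
        disp = growth_displacement(params, 0, 1)
        tip = disp(np.array([350.0, 0.0]))
        flank_pt = disp(np.array([10.0, 100.0]))
        assert tip[0] - 350.0 > 10.0  # distal apex advances
        assert abs(flank_pt[0] - 10.0) < 1.0  # proximal tissue barely moves


class TestGrowthSeries:
    def test_counts_and_monotone_area(self, tiny_series):
        assert len(tiny_series.meshes) == 5
        assert len(tiny_series.transfer_maps) == 4
        areas = [m.total_area for m in tiny_series.meshes]
        assert all(b > a for a, b in zip(areas, areas[1:]))

    @pytest.mark.parametrize("hour,stage", [
        (0, "mE10:09"), (7, "mE10:16"), (15, "mE11:00"), (27, "mE11:12")])
    def test_stage_notation(self, hour, stage):
        assert stage_of_hour(hour) == stage

    def test_series_rejects_zero_hours(self):
        with pytest.raises(ValueError):
            lg.build_growth_series(n_hours=0)
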