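"""Image filtering, fishnet construction, spatial join, Jenks, export."""

import itertools
import json
import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from parkscape import FeatureVector, OUTCOMES
from parkscape.mapping import (
    GeoImagePoint,
    assign_points,
    build_fishnet,
    cell_features,
    classify_cells,
    export_maps,
    filter_images,
    jenks_classify,
    predict_cells,
    read_boundary,
    read_cells_geojson,
    write_boundary,
)
from parkscape.regression import reference_models


def make_point(image_id, x, y, resolution=1920, landscape=True, key=None,
               **fractions):
    return GeoImagePoint(
        image_id=image_id, x=x, y=y, resolution=resolution,
        is_landscape=landscape, duplicate_key=key or image_id,
        features=FeatureVector(fractions),
    )


class TestFilterImages:
    def test_low_resolution_rejected(self):
        retained, log = filter_images([make_point("a", 0, 0, resolution=720)])
        assert retained == [] and log["low_resolution"] == 1

    def test_duplicate_second_occurrence_rejected(self):
        pts = [make_point("a", 0, 0, key="h1"), make_point("b", 1, 1, key="h1")]
        retained, log = filter_images(pts)
        assert [p.image_id for p in retained] == ["a"]
        assert log["duplicate"] == 1

    def test_mixed_fixture_enumeration(self):
        pts = (
            [make_point(f"ok{i}", i, i) for i in range(6)]
            + [make_point("lr1", 0, 0, resolution=700),
               make_point("lr2", 0, 0, resolution=1079)]
            + [make_point("dup", 0, 0, key="ok3")]
            + [make_point("nl", 0, 0, landscape=False)]
        )
        retained, log = filter_images(pts)
        assert len(retained) == 6
        assert log == {"low_resolution": 2, "non_landscape": 1,
                       "duplicate": 1, "retained": 6}


class TestBuildFishnet:
    def test_rectangle_tiling(self):
        cells = build_fishnet(box(1000, 1000, 1090, 1060), cell_size=30)
        assert len(cells) == 6
        assert {(c.row, c.col) for c in cells} == \
            {(r, c) for r in range(2) for c in range(3)}

    def test_single_cell_boundary(self):
        cells = build_fishnet(box(500, 500, 530, 530), cell_size=30)
        assert len(cells) == 1
        assert cells[0].bounds == (500, 500, 530, 530)

    def test_l_shape_matches_brute_force(self):
        l_shape = Polygon([(1000, 1000), (1090, 1000), (1090, 1030),
                           (1030, 1030), (1030, 1090), (1000, 1090)])
        cells = build_fishnet(l_shape, cell_size=30)
        expected = {
            (r, c)
            for r in range(3) for c in range(3)
            if l_shape.intersects(box(1000 + c * 30, 1000 + r * 30,
                                      1030 + c * 30, 1030 + r * 30))
        }
        assert {(c.row, c.col) for c in cells} == expected

    def test_geographic_coordinates_rejected(self):
        with pytest.raises(ValueError, match="geographic"):
            build_fishnet(box(121.4, 31.2, 121.5, 31.3))

    def test_degenerate_boundary_rejected(self):
        with pytest.raises(ValueError):
            build_fishnet(Polygon())


class TestAssignPoints:
    def _grid(self):
        return build_fishnet(box(1000, 1000, 1090, 1060), cell_size=30)

    def test_lower_left_corner_belongs_to_cell(self):
        cells = self._grid()
        assigned, un = assign_points([make_point("a", 1030.0, 1030.0)], cells)
        assert un == []
        assert assigned["r1c1"][0].image_id == "a"

    def test_shared_edge_goes_to_higher_index(self):
        cells = self._grid()
        assigned, _ = assign_points([make_point("e", 1060.0, 1015.0)], cells)
        assert [p.image_id for p in assigned["r0c2"]] == ["e"]
        assert assigned["r0c1"] == []

    def test_outermost_edge_closed(self):
        cells = self._grid()
        assigned, un = assign_points([make_point("far", 1090.0, 1060.0)], cells)
        assert un == []
        assert [p.image_id for p in assigned["r1c2"]] == ["far"]

    def test_outside_points_logged(self):
        cells = self._grid()
        _, un = assign_points([make_point("out", 2000.0, 2000.0)], cells)
        assert un == ["out"]

    def test_random_points_match_brute_force(self, rng):
        cells = self._grid()
        pts = [make_point(f"p{i}", rng.uniform(1000, 1090), rng.uniform(1000, 1060))
               for i in range(100)]
        assigned, un = assign_points(pts, cells)
        assert un == []
        for cell in cells:
            xmin, ymin, xmax, ymax = cell.bounds
            last_col = cell.col == 2
            last_row = cell.row == 1
            expect = {
                p.image_id for p in pts
                if (xmin <= p.x < xmax or (last_col and p.x == xmax))
                and (ymin <= p.y < ymax or (last_row and p.y == ymax))
            }
            assert set(p.image_id for p in assigned[cell.cell_id]) == expect

    def test_every_point_in_exactly_one_cell(self, rng):
        cells = self._grid()
        pts = [make_point(f"p{i}", rng.uniform(1000, 1090), rng.uniform(1000, 1060))
               for i in range(200)]
        assigned, un = assign_points(pts, cells)
        total = sum(len(v) for v in assigned.values()) + len(un)
        assert total == 200 and un == []

    def test_translation_invariance(self, rng):
        boundary = box(1000, 1000, 1090, 1060)
        pts = [make_point(f"p{i}", rng.uniform(1000, 1090),
                          rng.uniform(1000, 1060), sky=0.1 * (i % 5) / 5)
               for i in range(50)]
        dx, dy = 5000.0, -3000.0
        shifted = [make_point(p.image_id, p.x + dx, p.y + dy,
                              sky=p.features["sky"]) for p in pts]

        def classify(b, ps):
            cells = build_fishnet(b, 30)
            assigned, _ = assign_points(ps, cells)
            cell_features(cells, assigned)
            predict_cells(cells, reference_models())
            classify_cells(cells, k=3)
            return {(c.row, c.col): (sorted(c.point_ids),
                                     c.scores.OBI if c.scores else None,
                                     c.jenks_class)
                    for c in cells}

        from shapely.affinity import translate

        assert classify(boundary, pts) == \
            classify(translate(boundary, dx, dy), shifted)


class TestCellFeatures:
    def test_single_point_cell_mean_is_point(self):
        cells = build_fishnet(box(1000, 1000, 1030, 1030), 30)
        p = make_point("a", 1010, 1010, sky=0.3)
        assigned, _ = assign_points([p], cells)
        cell_features(cells, assigned)
        assert cells[0].mean_features["sky"] == pytest.approx(0.3)

    def test_two_point_mean(self):
        cells = build_fishnet(box(1000, 1000, 1030, 1030), 30)
        pts = [make_point("a", 1010, 1010, sky=0.1),
               make_point("b", 1020, 1020, sky=0.3)]
        assigned, _ = assign_points(pts, cells)
        cell_features(cells, assigned)
        assert cells[0].mean_features["sky"] == pytest.approx(0.2)

    def test_empty_cell_is_no_data_and_excluded(self):
        cells = build_fishnet(box(1000, 1000, 1060, 1030), 30)
        pts = [make_point("a", 1010, 1010, sky=0.2)]
        assigned, _ = assign_points(pts, cells)
        cell_features(cells, assigned)
        predict_cells(cells, reference_models())
        classify_cells(cells, k=1)
        empty = [c for c in cells if not c.point_ids][0]
        assert empty.mean_features is None and empty.scores is None
        assert empty.jenks_class is None


class TestPredictCells:
    def _one_cell_with(self, **fractions):
        cells = build_fishnet(box(1000, 1000, 1030, 1030), 30)
        p = make_point("a", 1010, 1010, **fractions)
        assigned, _ = assign_points([p], cells)
        cell_features(cells, assigned)
        predict_cells(cells, reference_models())
        return cells[0]

    def test_zero_features_give_intercepts(self):
        cell = self._one_cell_with()
        assert cell.scores.OBI == pytest.approx(281.63)
        assert cell.scores.SBI == pytest.approx(-106.58)

    def test_sky_half_sbi_arithmetic(self):
        cell = self._one_cell_with(sky=0.5)
        assert cell.scores.SBI == pytest.approx(-106.58 + 630.875)


def exhaustive_jenks(values, k):
    """Oracle: try every contiguous partition of the sorted values."""
    sv = sorted(values)
    n = len(sv)
    best, best_cost = None, math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = 0.0
        for a, b in zip(bounds, bounds[1:]):
            seg = sv[a:b]
            mu = sum(seg) / len(seg)
            cost += sum((v - mu) ** 2 for v in seg)
        if cost < best_cost - 1e-12:
            best, best_cost = bounds, cost
    return best, best_cost


class TestJenks:
    def test_two_obvious_clusters(self):
        breaks, labels = jenks_classify([1, 2, 3, 10, 11, 12], 2)
        assert list(labels) == [0, 0, 0, 1, 1, 1]
        assert breaks.breaks == (3.0,)

    def test_n_equals_k_perfect_fit(self):
        breaks, labels = jenks_classify([5.0, 9.0, 14.0], 3)
        assert sorted(labels) == [0, 1, 2]
        assert breaks.gvf == pytest.approx(1.0)

    def test_single_class_gvf_zero(self):
        breaks, labels = jenks_classify([4.0, 8.0, 15.0], 1)
        assert set(labels) == {0} and breaks.gvf == 0.0

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            jenks_classify([1.0, 1.0, 2.0], 3)
        with pytest.raises(ValueError):
            jenks_classify([1.0, 2.0], 0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, min(5, n)))
            values = np.round(rng.uniform(0, 100, n), 3)
            if len(np.unique(values)) < k:
                continue
            _, oracle_cost = exhaustive_jenks(values.tolist(), k)
            breaks, labels = jenks_classify(values, k)
            sv = np.sort(values)
            ls = labels[np.argsort(values, kind="stable")]
            cost = sum(
                ((sv[ls == c] - sv[ls == c].mean()) ** 2).sum()
                for c in np.unique(ls)
            )
            assert cost == pytest.approx(oracle_cost, abs=1e-8)

    def test_ssd_decomposition(self, rng):
        values = rng.uniform(0, 50, 40)
        breaks, labels = jenks_classify(values, 4)
        total = ((values - values.mean()) ** 2).sum()
        within = sum(((values[labels == c] - values[labels == c].mean()) ** 2).sum()
                     for c in np.unique(labels))
        between = sum(len(values[labels == c])
                      * (values[labels == c].mean() - values.mean()) ** 2
                      for c in np.unique(labels))
        assert within + between == pytest.approx(total)
        assert breaks.gvf == pytest.approx(1 - within / total)

    def test_labels_monotone_in_value(self, rng):
        values = rng.uniform(0, 10, 30)
        _, labels = jenks_classify(values, 5)
        order = np.argsort(values, kind="stable")
        assert (np.diff(labels[order]) >= 0).all()


class TestExport:
    def _classified_grid(self, rng):
        cells = build_fishnet(box(1000, 1000, 1090, 1060), 30)
        pts = [make_point(f"p{i}", rng.uniform(1000, 1090),
                          rng.uniform(1000, 1030),  # bottom row only
                          sky=float(rng.uniform(0, 0.3)))
               for i in range(30)]
        assigned, _ = assign_points(pts, cells)
        cell_features(cells, assigned)
        predict_cells(cells, reference_models())
        classify_cells(cells, k=3)
        return cells

    def test_geojson_validity_and_counts(self, rng, tmp_path):
        cells = self._classified_grid(rng)
        paths = export_maps(cells, tmp_path)
        gj = json.load(open(paths["geojson"]))
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == 6
        for feat in gj["features"]:
            assert feat["geometry"]["type"] == "Polygon"
            ring = feat["geometry"]["coordinates"][0]
            assert ring[0] == ring[-1]  # closed ring per GeoJSON

    def test_round_trip_preserves_scores(self, rng, tmp_path):
        cells = self._classified_grid(rng)
        paths = export_maps(cells, tmp_path)
        back = {c.cell_id: c for c in read_cells_geojson(paths["geojson"])}
        for c in cells:
            rt = back[c.cell_id]
            if c.scores is None:
                assert rt.scores is None
            else:
                for o in OUTCOMES:
                    assert rt.scores.as_dict()[o] == \
                        pytest.approx(c.scores.as_dict()[o], abs=1e-9)
                assert rt.jenks_class == c.jenks_class

    def test_no_data_cells_exported_null(self, rng, tmp_path):
        cells = self._classified_grid(rng)
        paths = export_maps(cells, tmp_path)
        gj = json.load(open(paths["geojson"]))
        empties = [f for f in gj["features"] if f["properties"]["OBI"] is None]
        assert len(empties) == 3  # the untouched top row

    def test_boundary_round_trip(self, tmp_path):
        geom = box(1000, 1000, 1090, 1060)
        write_boundary(geom, tmp_path / "b.geojson")
        assert read_boundary(tmp_path / "b.geojson").equals(geom)
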