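"""Distance-binned proximity profiles and association fractions."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Point

from cycihc.phenotype import DetectedObject, PathologyObject
from cycihc.proximity import (
    association_summary,
    distance_to_object,
    nearest_pathology,
    proximity_profile,
)
from cycihc.scenes import Scene, SceneConfig
from oracles import boundary_sample_distance


def _cell(i, x, y, label="IBA1-only", r=4.0):
    return DetectedObject(
        id=i, centroid_um=(x, y), area_um2=np.pi * r * r,
        equivalent_diameter_um=2 * r, boundary=Point(x, y).buffer(r, quad_segs=32),
        label=label)


def _plaque(i, x, y, r):
    poly = Point(x, y).buffer(r, quad_segs=64)
    return PathologyObject(i, "abeta_plaque", poly, 2 * r, poly.area)


class TestDistance:
    def test_centroid_inside_is_zero(self):
        assert distance_to_object(_cell(1, 100, 100), _plaque(1, 95, 100, 30)) == 0.0

    def test_circular_plaque_geometry(self):
        # centroid 55 um from the center of a radius-30 plaque: 25 um to edge
        d = distance_to_object(_cell(1, 155.0, 100.0), _plaque(1, 100.0, 100.0, 30.0))
        assert d == pytest.approx(25.0, abs=0.05)

    def test_matches_boundary_sampling_oracle(self, rng):
        """Distances to irregular polygons agree with dense boundary
        sampling within 0.5 um."""
        from shapely.geometry import Polygon

        for k in range(6):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
            radii = rng.uniform(20, 60, 12)
            pts = [(200 + r * np.cos(a), 200 + r * np.sin(a))
                   for a, r in zip(angles, radii)]
            poly = Polygon(pts).buffer(0)
            if poly.geom_type != "Polygon":           # self-intersecting star
                poly = max(poly.geoms, key=lambda g: g.area)
            obj = PathologyObject(k + 1, "abeta_plaque", poly,
                                  2 * np.sqrt(poly.area / np.pi), poly.area)
            for _ in range(5):
                x, y = rng.uniform(120, 280, 2)
                got = distance_to_object(_cell(1, x, y), obj)
                want = boundary_sample_distance((x, y), poly)
                assert got == pytest.approx(want, abs=0.5)

    def test_degenerate_object_rejected(self):
        from shapely.geometry import Polygon

        with pytest.raises(ValueError):
            PathologyObject(1, "abeta_plaque", Polygon(), 0.0, 0.0)


class TestProfile:
    def test_cells_fall_in_expected_bins(self):
        plaque = _plaque(1, 300.0, 300.0, 30.0)
        cells = [_cell(1, 335.0, 300.0), _cell(2, 355.0, 300.0),
                 _cell(3, 375.0, 300.0)]          # 5, 25, 45 um from the edge
        profiles = proximity_profile(cells, [plaque], radius_um=100,
                                     bin_width_um=20)
        counts = profiles["abeta_plaque"].counts["IBA1-only"]
        assert counts.tolist() == [1, 1, 1, 0, 0]

    def test_cell_beyond_radius_excluded(self):
        plaque = _plaque(1, 300.0, 300.0, 30.0)
        cells = [_cell(1, 300.0 + 30.0 + 101.0, 300.0)]
        profiles = proximity_profile(cells, [plaque])
        p = profiles["abeta_plaque"]
        assert p.counts.to_numpy().sum() == 0
        assert p.n_excluded == 1

    def test_conservation_binned_plus_excluded(self, rng):
        plaque = _plaque(1, 300.0, 300.0, 40.0)
        cells = [_cell(i, *rng.uniform(0, 600, 2)) for i in range(200)]
        profiles = proximity_profile(cells, [plaque])
        p = profiles["abeta_plaque"]
        assert p.counts.to_numpy().sum() + p.n_excluded == len(cells)

    def test_bins_must_divide_radius(self):
        with pytest.raises(ValueError):
            proximity_profile([], [_plaque(1, 0, 0, 10)], radius_um=100,
                              bin_width_um=30)

    def test_no_pathology_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert proximity_profile([_cell(1, 0, 0)], []) == {}

    def test_row_percentages_sum_to_hundred(self, rng):
        plaque = _plaque(1, 300.0, 300.0, 40.0)
        labels = ["IBA1-only", "IBA1+P2Y12+", "IBA1+CD68+"]
        cells = [_cell(i, *rng.uniform(250, 450, 2), label=labels[i % 3])
                 for i in range(100)]
        p = proximity_profile(cells, [plaque])["abeta_plaque"]
        sums = p.row_percent.sum(axis=1).dropna()
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_uniform_cells_follow_annulus_areas(self):
        """Cells from a uniform spatial process bin in proportion to annulus
        area around a circular plaque (aggregated over 20 seeds)."""
        R, radius, width = 40.0, 100.0, 20.0
        plaque = _plaque(1, 300.0, 300.0, R)
        edges = np.arange(0, radius + 1, width)
        expect = np.diff([(R + e) ** 2 for e in edges])   # ∝ annulus areas
        expect = expect / expect.sum()
        totals = np.zeros(len(expect))
        n_binned = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            cells = []
            i = 0
            while len(cells) < 200:
                x, y = g.uniform(0, 600, 2)
                if np.hypot(x - 300, y - 300) >= R:       # outside the plaque
                    cells.append(_cell(i, x, y))
                    i += 1
            p = proximity_profile(cells, [plaque])["abeta_plaque"]
            totals += p.counts["IBA1-only"].to_numpy()
            n_binned += p.counts.to_numpy().sum()
        prop = totals / n_binned
        se = np.sqrt(expect * (1 - expect) / n_binned)
        assert np.all(np.abs(prop - expect) <= 3.5 * se)

    def test_profile_invariant_under_rigid_motion(self, rng):
        plaque_poly = Point(300, 300).buffer(35, quad_segs=32)
        cells = [_cell(i, *rng.uniform(150, 450, 2)) for i in range(80)]
        p0 = proximity_profile(
            cells, [PathologyObject(1, "abeta_plaque", plaque_poly, 70, plaque_poly.area)]
        )["abeta_plaque"]

        def move(geom):
            return affinity.translate(affinity.rotate(geom, 17, origin=(0, 0)),
                                      55.0, -40.0)

        moved_cells = []
        for c in cells:
            b = move(c.boundary)
            moved_cells.append(DetectedObject(
                id=c.id, centroid_um=(b.centroid.x, b.centroid.y),
                area_um2=c.area_um2, equivalent_diameter_um=c.equivalent_diameter_um,
                boundary=b, label=c.label))
        moved_plaque = move(plaque_poly)
        p1 = proximity_profile(
            moved_cells,
            [PathologyObject(1, "abeta_plaque", moved_plaque, 70, moved_plaque.area)]
        )["abeta_plaque"]
        np.testing.assert_array_equal(p0.counts.to_numpy(), p1.counts.to_numpy())


class TestAssociation:
    def test_overlapping_cell_is_touching(self):
        plaque = _plaque(1, 100.0, 100.0, 30.0)
        touching = _cell(1, 132.0, 100.0, label="IBA1+CD68+")   # overlaps edge
        far = _cell(2, 300.0, 300.0, label="IBA1+CD68+")
        summ = association_summary([touching, far], [plaque], [])
        row = {a.phenotype: a for a in summ}["IBA1+CD68+"]
        assert row.percent_touching_pathology == pytest.approx(50.0)
        assert row.percent_non_pathology == pytest.approx(50.0)

    def test_missing_vessels_reported_as_not_computed(self):
        plaque = _plaque(1, 100.0, 100.0, 30.0)
        summ = association_summary([_cell(1, 0, 0, label="IBA1-only")],
                                   [plaque], [], vessels=None)
        row = {a.phenotype: a for a in summ}["IBA1-only"]
        assert row.percent_vessel_associated is None

    def test_pathology_takes_priority_over_vessel(self):
        plaque = _plaque(1, 100.0, 100.0, 30.0)
        vessel_poly = Point(130, 100).buffer(10)
        vessel = PathologyObject(2, "vessel", vessel_poly, 20, vessel_poly.area)
        cell = _cell(1, 128.0, 100.0, label="IBA1+CD68+")   # touches both
        summ = association_summary([cell], [plaque], [], vessels=[vessel])
        row = {a.phenotype: a for a in summ}["IBA1+CD68+"]
        assert row.percent_touching_pathology == 100.0
        assert row.percent_vessel_associated == 0.0

    def test_touch_tolerance_expands_contact(self):
        plaque = _plaque(1, 100.0, 100.0, 30.0)
        near = _cell(1, 137.0, 100.0, r=4.0, label="IBA1-only")   # 3 um gap
        strict = association_summary([near], [plaque], [])[1]
        loose = association_summary([near], [plaque], [],
                                    touch_tolerance_um=5.0)[1]
        assert strict.percent_touching_pathology == 0.0
        assert loose.percent_touching_pathology == 100.0


def test_reactive_attraction_enriches_innermost_bin():
    """Raising the plaque-attraction of the triple-positive phenotype never
    lowers its share of the innermost distance bin."""
    shares = []
    for attraction in (0.0, 6.0):
        inner = np.zeros(2)
        for seed in (61, 62, 63):
            att = dict(SceneConfig().attraction)
            att["IBA1+Ferritin+CD68+"] = attraction
            cfg = SceneConfig(seed=seed, field_size_um=900.0, n_cells=220,
                              n_extra_nuclei=0, n_diffuse_speckles=0,
                              n_process_fragments=0, min_separation_um=10.0,
                              attraction=att)
            scene = Scene(cfg)
            gt = scene.ground_truth()
            plaques = [p for p in gt.pathology if p.kind == "abeta_plaque"]
            prof = proximity_profile(scene.truth_objects(), plaques)
            counts = prof["abeta_plaque"].counts
            inner += np.array([counts.iloc[0]["IBA1+Ferritin+CD68+"],
                               counts.iloc[0].sum()])
        shares.append(inner[0] / inner[1])
    assert shares[1] >= shares[0]


def test_nearest_pathology_picks_minimum():
    cells = _cell(1, 200.0, 100.0)
    near = _plaque(1, 250.0, 100.0, 20.0)
    far = _plaque(2, 400.0, 100.0, 20.0)
    obj, d = nearest_pathology(cells, [far, near])
    assert obj.id == 1
    assert d == pytest.approx(30.0, abs=0.05)
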