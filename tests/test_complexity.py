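"""Tooth complexity: closed forms, brute-force oracles, pooled tables."""

import numpy as np
import pytest

from heterodont import (
    Dentition,
    Outline,
    ToothParams,
    count_cusps,
    make_tooth,
    oar,
    ocr,
    oir,
    resolution_ladder,
    species_complexity,
    tooth_complexity,
)
from heterodont.complexity import (
    angle_measures,
    complexity_table,
    opc,
    streak_count,
)
from heterodont.outlines import Tooth
from heterodont.synthetic import DentitionParams, make_dentition
from heterodont.distances import dfs


def _circle_outline(n=1000, radius=1.0, span=1.9999 * np.pi):
    theta = np.linspace(0.0, span, n)
    return Outline(radius * np.column_stack([np.cos(theta), np.sin(theta)]))


def _semicircle(n=500, radius=1.0):
    theta = np.linspace(np.pi, 0.0, n)
    return Outline(radius * np.column_stack([np.cos(theta), np.sin(theta)]))


class TestResolutionLadder:
    def test_standard_values(self):
        assert resolution_ladder(1000) == [200, 100, 50, 25, 13, 6]

    def test_strictly_decreasing(self):
        ladder = resolution_ladder(480)
        assert all(a > b for a, b in zip(ladder, ladder[1:]))


class TestCountCusps:
    def test_single_smooth_bump(self):
        o = make_tooth(ToothParams(n_major_cusps=1, cusp_height=0.6), 500)
        assert count_cusps(o) == (1, 0)

    def test_generator_fixture_major_and_minor(self):
        o = make_tooth(
            ToothParams(
                n_major_cusps=2,
                n_minor_cusps=6,
                cusp_height=0.7,
                minor_cusp_height=0.01,
            ),
            1000,
        )
        assert count_cusps(o) == (2, 6)
        assert count_cusps(o, "major") == 2
        assert count_cusps(o, "minor") == 6

    def test_flat_baseline_no_cusps(self):
        flat = Outline(np.column_stack([np.linspace(0, 1, 50), np.zeros(50)]))
        assert count_cusps(flat) == (0, 0)

    def test_largest_extremum_always_major(self):
        # a single tiny bump: below the 2% col threshold, but still the
        # largest cusp, so it must be promoted to major
        x = np.linspace(0.0, 1.0, 400)
        y = 0.004 * np.sin(np.pi * x) ** 4
        o = Outline(np.column_stack([x, y]))
        assert count_cusps(o) == (1, 0)

    def test_matches_brute_force_peak_enumeration(self):
        o = make_tooth(
            ToothParams(n_major_cusps=4, n_minor_cusps=5, cusp_height=0.5,
                        minor_cusp_height=0.012),
            1000,
        )
        # independent oracle: scan the polyline for local maxima of y and
        # compute each peak's prominence directly (drop to the higher col)
        y = o.points[:, 1]
        peaks = [
            i
            for i in range(1, len(y) - 1)
            if y[i] > y[i - 1] and y[i] >= y[i + 1]
        ]
        # merge plateau duplicates
        def prominence(i):
            left = y[:i]
            right = y[i + 1 :]
            higher_left = np.where(left > y[i])[0]
            higher_right = np.where(right > y[i])[0]
            lo = left[higher_left[-1] :].min() if len(higher_left) else left.min()
            hi = right[: higher_right[0] + 1].min() if len(higher_right) else right.min()
            return y[i] - max(lo, hi)

        thr = 0.02 * o.length
        proms = [prominence(i) for i in peaks]
        major = sum(p >= thr for p in proms)
        minor = len(peaks) - major
        assert count_cusps(o) == (major, minor)


class TestExcentricityMeasures:
    def test_oar_semicircular_crown(self):
        # half disc of radius 1 on its diameter: length pi, area pi/2
        assert oar(_semicircle()) == pytest.approx(2.0, rel=1e-4)

    def test_oar_scales_inversely_with_size(self, cusped_crown):
        k = 3.0
        scaled = Outline(cusped_crown.points * k)
        assert oar(scaled) == pytest.approx(oar(cusped_crown) / k, rel=1e-12)

    def test_ocr_circle_closed_form(self):
        n = 1000
        o = _circle_outline(n)
        # all points at unit distance from the centroid: denominator
        # sqrt(n), length ~ 2 pi
        assert ocr(o) == pytest.approx(2 * np.pi / np.sqrt(n), rel=1e-2)

    def test_ocr_resolution_dependence(self):
        # doubling the point count scales the denominator by sqrt(2)
        r1 = ocr(_circle_outline(500))
        r2 = ocr(_circle_outline(1000))
        assert r1 / r2 == pytest.approx(np.sqrt(2), rel=1e-2)

    def test_oir_disc_is_one(self):
        assert oir(_circle_outline()) == pytest.approx(1.0, abs=1e-3)

    def test_oir_rectangle_closed_form(self):
        # 2x1 rectangle: inscribed r = 0.5, escribed R = sqrt(5)/2
        rect = Outline(
            np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 1.0], [2.0, 0.0]])
        )
        assert oir(rect) == pytest.approx(5.0, abs=1e-6)

    def test_oir_inscribed_radius_against_grid_search(self):
        """The library inscribed radius agrees with a brute-force
        max-min-distance grid search on an irregular crown."""
        from shapely import Polygon

        o = make_tooth(ToothParams(n_major_cusps=2, cusp_height=0.45), 200)
        poly = Polygon(o.points)
        from shapely import maximum_inscribed_circle

        r_lib = maximum_inscribed_circle(poly, tolerance=1e-9).length
        xs = np.linspace(0.0, 1.0, 220)
        ys = np.linspace(0.0, float(o.points[:, 1].max()), 130)
        gx, gy = np.meshgrid(xs, ys)
        from shapely import contains_xy, prepare
        prepare(poly)
        inside = contains_xy(poly, gx.ravel(), gy.ravel())
        pts = np.column_stack([gx.ravel(), gy.ravel()])[inside]
        closed = np.vstack([o.points, o.points[:1]])
        # distance from each interior grid point to the polygon boundary
        best = 0.0
        for p in pts:
            seg_d = _point_to_segments(p, closed)
            best = max(best, seg_d)
        assert r_lib == pytest.approx(best, abs=2e-2)

    def test_needle_sliver_hits_cap(self):
        sliver = Outline(
            np.array([[0.0, 0.0], [5.0, 0.02], [10.0, 0.0], [5.0, -0.021]])
        )
        assert oir(sliver) == 25.0


def _point_to_segments(p, closed):
    a = closed[:-1]
    b = closed[1:]
    ab = b - a
    t = np.clip(((p - a) * ab).sum(1) / (ab * ab).sum(1), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(proj - p, axis=1).min()


class TestDfs:
    def test_translation_invariance(self, cusped_crown):
        from heterodont import center_and_scale

        norm = center_and_scale(cusped_crown, "length")
        moved = Outline(norm.points + [2.0, -1.0])
        assert dfs(norm) == pytest.approx(dfs(Outline(moved.points - moved.points.mean(0))))

    def test_more_cusps_more_coefficient_mass(self):
        five = tooth_complexity(
            make_tooth(ToothParams(n_major_cusps=5, cusp_height=0.6), 500), 500
        )
        one = tooth_complexity(
            make_tooth(ToothParams(n_major_cusps=1, cusp_height=0.6), 500), 500
        )
        assert five.DFS > one.DFS


class TestAngleMeasures:
    def test_straight_polyline_all_zero(self):
        line = Outline(np.column_stack([np.linspace(0, 1, 500), np.zeros(500)]))
        ans, asc, and_ = angle_measures(line, ladder=[100, 50, 25])
        assert ans == pytest.approx(0.0, abs=1e-9)
        assert asc == pytest.approx(0.0, abs=1e-9)
        assert and_ == pytest.approx(0.0, abs=1e-9)

    def test_semicircle_closed_form_per_resolution(self):
        arc = _semicircle(2000)
        for n_r in (50, 25):
            ans, _, _ = angle_measures(arc, ladder=[n_r])
            expected = np.pi * (n_r - 2) / (n_r - 1)
            assert ans == pytest.approx(expected, rel=1e-3)

    def test_equiangular_shape_zero_disparity(self):
        arc = _semicircle(800)
        _, _, and_ = angle_measures(arc, ladder=[40])
        # tolerance covers piecewise-linear resampling jitter
        assert and_ == pytest.approx(0.0, abs=1e-3)

    def test_asc_signed_mean_of_cadence(self):
        o = make_tooth(ToothParams(n_major_cusps=3, cusp_height=0.5), 1000)
        ladder = [200, 100, 50]
        sums = []
        for n_r in ladder:
            ans_r, _, _ = angle_measures(o, ladder=[n_r])
            sums.append(ans_r)
        _, asc, _ = angle_measures(o, ladder=ladder)
        assert asc == pytest.approx(np.mean(np.diff(sums)), rel=1e-9)

    def test_short_ladder_resolutions_dropped_with_warning(self):
        o = make_tooth(ToothParams(), 100)
        with pytest.warns(UserWarning):
            angle_measures(o, ladder=[20, 2])


class TestOpc:
    def test_straight_line_single_streak(self):
        line = Outline(np.column_stack([np.linspace(0, 1, 300), np.zeros(300)]))
        assert opc(line) == pytest.approx(1.0)

    def test_zigzag_streaks_by_enumeration(self):
        # square-wave zigzag: vectors alternate between two directions
        n_teeth = 8
        pts = [(0.0, 0.0)]
        for i in range(n_teeth):
            pts.append((i + 0.5, 1.0))
            pts.append((i + 1.0, 0.0))
        vec = np.diff(np.array(pts), axis=0)
        count = streak_count(vec, partitions=4, offset=0.0)
        # brute-force enumeration over the vector sequence
        theta = np.arctan2(vec[:, 1], vec[:, 0])
        sectors = np.floor((theta % (2 * np.pi)) / (np.pi / 2)).astype(int)
        expected = 1 + int(np.count_nonzero(sectors[1:] != sectors[:-1]))
        assert count == expected == 2 * n_teeth

    def test_partition_refinement_monotone_at_zero_offset(self, crown_pool):
        for o in crown_pool[:4]:
            pts = o.points
            vec = np.diff(pts, axis=0)
            counts = [streak_count(vec, p, 0.0) for p in (2, 4, 8)]
            assert counts[0] <= counts[1] <= counts[2]


class TestSpeciesAggregation:
    def _uniform_dentition(self, outline, n=3):
        rows = {
            jaw: [Tooth("sp", jaw, i + 1, outline) for i in range(n)]
            for jaw in ("upper", "lower")
        }
        return Dentition("sp", rows)

    def test_identical_teeth_species_equals_single_tooth(self):
        o = make_tooth(ToothParams(n_major_cusps=2, cusp_height=0.5), 200)
        dent = self._uniform_dentition(o)
        single = tooth_complexity(o, n_points=200)
        agg = species_complexity(dent, n_points=200)
        for name in ("CUSP1", "OAR", "OCR", "OIR", "DFS", "ANS", "OPC"):
            assert getattr(agg, name) == pytest.approx(getattr(single, name))

    def test_cusp_ratio_zero_when_no_major(self):
        from heterodont.complexity import ComplexityRecord

        rec = ComplexityRecord(0, 3, 1, 1, 1, 1, 1, 0, 1, 1)
        assert rec.cusp_ratio == 0.0

    def test_combined_normalization_bounds(self):
        dents = []
        for i, (cusps, height) in enumerate([(1, 0.3), (3, 0.5), (5, 0.8)]):
            o = make_tooth(ToothParams(n_major_cusps=cusps, cusp_height=height), 200)
            rows = {
                jaw: [Tooth(f"s{i}", jaw, 1, o), Tooth(f"s{i}", jaw, 2, o)]
                for jaw in ("upper", "lower")
            }
            dents.append(Dentition(f"s{i}", rows))
        table = complexity_table(dents, n_points=200)
        norm_cols = [c for c in table.columns if c.endswith("_norm")]
        assert (table[norm_cols].min() >= 0.0).all()
        assert (table[norm_cols].max() <= 1.0).all()
        assert 0.0 <= table["Cx_combined"].min()
        assert table["Cx_combined"].max() <= 10.0

    def test_two_species_normalized_to_unit_interval(self):
        a = make_tooth(ToothParams(n_major_cusps=1, cusp_height=0.4), 200)
        b = make_tooth(ToothParams(n_major_cusps=4, cusp_height=0.7), 200)
        dents = []
        for name, o in (("a", a), ("b", b)):
            rows = {jaw: [Tooth(name, jaw, 1, o), Tooth(name, jaw, 2, o)] for jaw in ("upper", "lower")}
            dents.append(Dentition(name, rows))
        table = complexity_table(dents, n_points=200)
        for m in ("CUSP1", "DFS", "ANS"):
            assert set(np.round(table[f"{m}_norm"], 12)) == {0.0, 1.0}

    def test_empty_dentition_rejected(self):
        with pytest.raises(ValueError):
            species_complexity(Dentition("empty", {}))

    def test_monotone_cusp_response(self):
        """More generator cusps increase CUSP1, DFS, and ANS."""
        values = {"CUSP1": [], "DFS": [], "ANS": []}
        for cusps in (1, 3, 5):
            o = make_tooth(ToothParams(n_major_cusps=cusps, cusp_height=0.6), 500)
            rec = tooth_complexity(o, n_points=500)
            for key in values:
                values[key].append(getattr(rec, key))
        for key, seq in values.items():
            assert seq[0] < seq[1] < seq[2], key
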