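"""MCP home ranges, saturation, composition, overlap, and comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from owlrsf import homerange as hrm
from owlrsf.errors import GeometryError, RankError

from .conftest import uniform_landscape


def brute_force_mcp_area(points, isopleth):
    """Independent peel-and-hull oracle via scipy's ConvexHull."""
    import math

    pts = np.asarray(points, dtype=float)
    k = int(math.ceil(round((1 - isopleth) * len(pts), 9)))
    if k > 0:
        c = pts.mean(axis=0)
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        pts = pts[np.argsort(d, kind="stable")[: len(pts) - k]]
    try:
        return ConvexHull(pts).volume / 1e6  # 2-D "volume" is the area
    except Exception:
        return 0.0


class TestMCP:
    def test_matches_enumeration_oracle_on_random_sets(self):
        rng = np.random.default_rng(55)
        for trial in range(100):
            n = int(rng.integers(5, 31))
            pts = rng.uniform(0, 3000, size=(n, 2))
            iso = float(rng.choice([0.8, 0.9, 0.95, 1.0]))
            expected = brute_force_mcp_area(pts, iso)
            got = hrm.mcp(pts, isopleth=iso, allow_degenerate=True).area_km2
            assert got == pytest.approx(expected, abs=1e-12)

    def test_four_corners_full_isopleth(self):
        corners = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        pts = np.repeat(corners, 25, axis=0)
        hr = hrm.mcp(pts, isopleth=1.0)
        assert hr.area_km2 == pytest.approx(1.0)

    def test_outliers_peeled_at_95(self):
        rng = np.random.default_rng(8)
        core = rng.uniform(0, 1000, size=(95, 2))
        outliers = rng.uniform(10_000, 11_000, size=(5, 2))
        pts = np.vstack([core, outliers])
        hr = hrm.mcp(pts, isopleth=0.95)
        assert hr.area_km2 == pytest.approx(
            ConvexHull(core).volume / 1e6
        )
        assert hr.n_fixes_used == 95

    def test_area_monotone_in_isopleth(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1000, size=(200, 2))
        areas = [
            hrm.mcp(pts, isopleth=iso).area_km2 for iso in (0.5, 0.7, 0.9, 0.95, 1.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_fewer_than_3_distinct_raises(self):
        pts = np.array([[0, 0], [0, 0], [1, 1]])
        with pytest.raises(GeometryError):
            hrm.mcp(pts)
        assert hrm.mcp(pts, allow_degenerate=True).area_km2 == 0.0


class TestSaturation:
    def test_large_uniform_sample_saturates(self):
        rng = np.random.default_rng(10)
        theta = rng.uniform(0, 2 * np.pi, 2000)
        r = 1000 * np.sqrt(rng.uniform(0, 1, 2000))
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        res = hrm.saturation(pts, ladder=None, n_boot=50, seed=0)
        assert res.saturated

    def test_tiny_sample_does_not_saturate(self):
        pts = np.array([[0, 0], [100, 0], [0, 100], [100, 100], [50, 200]], dtype=float)
        res = hrm.saturation(pts, ladder=[3, 4, 5], n_boot=50, seed=0)
        assert not res.saturated

    def test_point_mass_locations_saturate(self):
        base = np.array([[0, 0], [1000, 0], [500, 900]], dtype=float)
        pts = np.repeat(base, 20, axis=0)
        res = hrm.saturation(pts, ladder=[30, 40, 50, 60], n_boot=30, seed=0, isopleth=1.0)
        assert res.saturated
        assert all(abs(i) < 1e-9 for i in res.last_increases)

    def test_ladder_exceeding_n_raises(self):
        with pytest.raises(GeometryError):
            hrm.saturation(np.zeros((5, 2)), ladder=[3, 10])


class TestCompositionOverlapDistance:
    def test_uniform_landscape_composition(self):
        ls = uniform_landscape("crop_rotation", n=40)
        hr = hrm.HomeRange(Polygon([(100, 100), (800, 100), (800, 800), (100, 800)]), 0.49, 4)
        comp = hrm.composition(hr, ls)
        assert comp["crop_rotation"] == pytest.approx(1.0)
        assert comp["unknown"] == 0.0

    def test_half_split_straddle(self):
        from owlrsf.landscape import CATEGORY_CODE, LandscapeRaster

        grid = np.full((40, 40), CATEGORY_CODE["forest"], dtype=np.int64)
        grid[:, 20:] = CATEGORY_CODE["urban"]
        empty = np.zeros((40, 40), dtype=bool)
        ls = LandscapeRaster(grid, empty, empty.copy(), cell_m=25.0)
        hr = hrm.HomeRange(Polygon([(250, 250), (750, 250), (750, 750), (250, 750)]), 0.25, 4)
        comp = hrm.composition(hr, ls)
        one_row = 1.0 / 20.0  # one cell row tolerance
        assert comp["forest"] == pytest.approx(0.5, abs=one_row)
        assert comp["urban"] == pytest.approx(0.5, abs=one_row)

    def test_composition_sums_to_at_most_one(self, landscape):
        hr = hrm.HomeRange(
            Polygon([(-500, -500), (2000, -500), (2000, 2000), (-500, 2000)]), 6.25, 4
        )
        comp = hrm.composition(hr, landscape)
        main = sum(comp[c] for c in ("crop_rotation", "intensive_grassland",
                                     "extensive_grassland", "forest", "urban"))
        assert main <= 1.0 + 1e-9
        assert comp["unknown"] > 0  # polygon extends off the landscape

    def test_overlap_properties(self):
        sq = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        shifted = Polygon([(500, 0), (1500, 0), (1500, 1000), (500, 1000)])
        far = Polygon([(9000, 9000), (9100, 9000), (9100, 9100), (9000, 9100)])
        a = hrm.HomeRange(sq, 1.0, 10)
        assert hrm.hr_overlap(a, a) == pytest.approx(1.0)
        assert hrm.hr_overlap(a, hrm.HomeRange(far, 0.01, 10)) == 0.0
        assert hrm.hr_overlap(a, hrm.HomeRange(shifted, 1.0, 10)) == pytest.approx(0.5)

    def test_centroid_distance(self):
        sq = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        hr = hrm.HomeRange(sq, 1.0, 10)
        assert hrm.centroid_distance(hr, (500, 500)) == pytest.approx(0.0)
        assert hrm.centroid_distance(hr, (500, 1700)) == pytest.approx(1200.0)


def _size_table(rng, n_ind=50, sex_effect=-0.5):
    rows = []
    for i in range(n_ind):
        sex = "m" if i < n_ind // 2 else "f"
        u = rng.normal(0, 0.3)
        for period in ("breeding", "non_breeding"):
            for year in (2018, 2019):
                mu = 1.5 + (sex_effect if sex == "m" else 0.0) + u
                rows.append(
                    dict(
                        individual_id=f"I{i}",
                        period=period,
                        sex=sex,
                        year=year,
                        area_km2=float(np.exp(mu + rng.normal(0, 0.3))),
                    )
                )
    return pd.DataFrame(rows)


class TestComparisons:
    def test_sex_effect_recovered(self):
        rng = np.random.default_rng(77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = hrm.compare_sizes(_size_table(rng), seed=1)
        row = summ.terms[summ.terms["term"].str.contains("sex")].iloc[0]
        assert row["lo"] <= -0.5 <= row["hi"]
        assert row["meaningful"]

    def test_null_effect_coverage(self):
        rng = np.random.default_rng(78)
        covered = 0
        n_rep = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                summ = hrm.compare_sizes(_size_table(rng, n_ind=20, sex_effect=0.0), seed=2)
                row = summ.terms[summ.terms["term"].str.contains("sex")].iloc[0]
                if row["lo"] <= 0.0 <= row["hi"]:
                    covered += 1
        assert covered >= 0.90 * n_rep

    def test_identical_sizes_give_zero_effects(self):
        rng = np.random.default_rng(79)
        df = _size_table(rng)
        df["area_km2"] = 5.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = hrm.compare_sizes(df, seed=3)
        effects = summ.terms[summ.terms["term"] != "Intercept"]
        assert np.allclose(effects["estimate"], 0.0, atol=1e-6)

    def test_singular_design_raises(self):
        rng = np.random.default_rng(80)
        df = _size_table(rng)
        # period perfectly confounded with year -> collinear dummies
        df["year"] = np.where(df["period"] == "breeding", 2018, 2019)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(RankError):
                hrm.compare_sizes(df, seed=4)

    def test_distance_type_effect_recovered(self):
        rng = np.random.default_rng(81)
        rows = []
        for i in range(40):
            u = rng.normal(0, 0.3)
            box = f"B{i % 15}"
            b = rng.normal(0, 0.2)
            for dt in (1, 2, 3):
                mu = 6.0 + (0.5 if dt == 2 else 0.0) + u + b
                rows.append(
                    dict(
                        individual_id=f"I{i}",
                        nestbox_id=box,
                        sex="m" if i % 2 else "f",
                        dist_type=dt,
                        distance_m=float(np.exp(mu + rng.normal(0, 0.4))),
                    )
                )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = hrm.compare_distances(pd.DataFrame(rows), seed=5)
        row = summ.terms[summ.terms["term"].str.contains(r"T\.2")].iloc[0]
        assert row["lo"] <= 0.5 <= row["hi"]
        assert row["meaningful"]
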