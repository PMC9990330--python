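"""Minimum-convex-polygon home ranges, saturation, composition, comparisons.

The 95% MCP follows the classical convention: discard the 5% of fixes
farthest from the (arithmetic-mean) centroid, then take the convex hull of
the remainder.  Saturation is judged on a bootstrap ladder of sample sizes:
a range is saturated when none of the last three relative area increases
exceeds 15%.  Log-scale size and centroid-distance comparisons are
random-intercept linear mixed models (REML) summarised by simulation from
the estimated sampling distribution of the fixed effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point

from .errors import GeometryError, RankError
from .landscape import CATEGORIES, LandscapeRaster


@dataclass
class HomeRange:
    polygon: object  # shapely geometry (convex)
    area_km2: float
    n_fixes_used: int
    deployment_id: str = ""
    period: str = ""
    saturated: bool | None = None


@dataclass
class SaturationResult:
    ladder: list
    mean_areas_km2: list
    last_increases: list
    saturated: bool


def _peel_count(n: int, isopleth: float) -> int:
    # guard float fuzz: (1 - 0.95) * 100 is slightly above 5
    return int(math.ceil(round((1.0 - isopleth) * n, 9)))


def mcp(
    points: np.ndarray,
    isopleth: float = 0.95,
    deployment_id: str = "",
    period: str = "",
    allow_degenerate: bool = False,
) -> HomeRange:
    """Minimum convex polygon containing ``isopleth`` of the points.

    Removes the ``ceil((1 - isopleth) * n)`` points farthest from the mean
    centroid (computed once), then hulls the remainder.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("points must be (n, 2)")
    distinct = np.unique(pts, axis=0)
    if len(distinct) < 3:
        if allow_degenerate:
            geom = MultiPoint(pts).convex_hull
            return HomeRange(geom, 0.0, len(pts), deployment_id, period)
        raise GeometryError("need >= 3 distinct points for an MCP")
    k = _peel_count(len(pts), isopleth)
    if k > 0:
        centroid = pts.mean(axis=0)
        d = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
        keep = np.argsort(d, kind="stable")[: len(pts) - k]
        pts = pts[keep]
    hull = MultiPoint(pts).convex_hull
    area = getattr(hull, "area", 0.0)
    if area == 0.0 and not allow_degenerate:
        # peel left collinear/coincident points
        raise GeometryError("retained points are collinear; degenerate MCP")
    return HomeRange(hull, area / 1e6, len(pts), deployment_id, period)


def saturation(
    points: np.ndarray,
    ladder: list | None = None,
    n_boot: int = 100,
    seed: int = 0,
    isopleth: float = 0.95,
    threshold: float = 0.15,
) -> SaturationResult:
    """Bootstrap area-accumulation test of home-range saturation.

    For each ladder rung, the mean MCP area over ``n_boot`` subsamples drawn
    without replacement; saturated iff each of the last three relative
    increases is at most ``threshold``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if ladder is None:
        lo = min(10, n)
        ladder = sorted(set(np.round(np.logspace(np.log10(lo), np.log10(n), 10)).astype(int)))
    ladder = sorted(int(r) for r in ladder)
    if ladder[-1] > n:
        raise GeometryError(f"ladder rung {ladder[-1]} exceeds n = {n}")
    if any(r < 1 for r in ladder):
        raise GeometryError("ladder rungs must be >= 1")
    rng = np.random.default_rng(seed)
    means = []
    for rung in ladder:
        areas = np.empty(n_boot)
        for b in range(n_boot):
            sub = pts[rng.choice(n, size=rung, replace=False)]
            try:
                areas[b] = mcp(sub, isopleth=isopleth, allow_degenerate=True).area_km2
            except GeometryError:
                areas[b] = 0.0
        means.append(float(areas.mean()))
    increases = []
    for prev, cur in zip(means[:-1], means[1:]):
        if prev == 0.0:
            increases.append(float("inf") if cur > 0 else 0.0)
        else:
            increases.append((cur - prev) / prev)
    last = increases[-3:] if increases else []
    saturated = all(inc <= threshold for inc in last)
    return SaturationResult(ladder, means, last, saturated)


def composition(hr: HomeRange, landscape: LandscapeRaster) -> dict[str, float]:
    """Habitat composition of a home range by cell counting.

    Counts landscape-lattice cell centres inside the polygon.  Main-category
    proportions sum to at most 1; cells inside the polygon but off the
    landscape are reported under ``unknown``.  Border/biodiversity fractions
    are overlay fractions over the same cells and may overlap categories.
    """
    poly = hr.polygon
    cell = landscape.cell_m
    minx, miny, maxx, maxy = poly.bounds
    i0 = math.floor(minx / cell)
    i1 = math.ceil(maxx / cell)
    j0 = math.floor(miny / cell)
    j1 = math.ceil(maxy / cell)
    xs = (np.arange(i0, i1) + 0.5) * cell
    ys = (np.arange(j0, j1) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    if not inside.any():
        raise GeometryError("polygon does not contain any landscape cell centre")
    gx = gx.ravel()[inside]
    gy = gy.ravel()[inside]
    total = gx.size
    on_grid = landscape.contains(gx, gy)
    out = {c: 0.0 for c in CATEGORIES}
    ix = (gx[on_grid] / cell).astype(int)
    iy = (gy[on_grid] / cell).astype(int)
    codes = landscape.grid[iy, ix]
    for code, count in zip(*np.unique(codes, return_counts=True)):
        out[CATEGORIES[code]] = count / total
    out["border_structures"] = float(landscape.border_mask[iy, ix].sum()) / total
    out["biodiversity_structures"] = float(landscape.biodiv_mask[iy, ix].sum()) / total
    out["unknown"] = float((~on_grid).sum()) / total
    return out


def hr_overlap(a: HomeRange, b: HomeRange) -> float:
    """Fraction of a's area shared with b."""
    if a.polygon.area == 0.0:
        return 0.0
    return a.polygon.intersection(b.polygon).area / a.polygon.area


def centroid_distance(hr: HomeRange, point) -> float:
    """Distance (m) from the home-range centroid to a point (nest box)."""
    return float(hr.polygon.centroid.distance(Point(point)))


# ---------------------------------------------------------------------------
# Log-linear comparisons (random-intercept mixed models)
# ---------------------------------------------------------------------------


@dataclass
class ModelSummary:
    """Fixed effects summarised from draws of the estimator's sampling
    distribution: mean, 2.5% and 97.5% quantiles; an effect is meaningful
    when its interval excludes 0."""

    terms: pd.DataFrame
    n_draws: int
    seed: int
    random_effects: dict = field(default_factory=dict)


def _simulate_summary(result, n_draws: int, seed: int) -> pd.DataFrame:
    params = np.asarray(result.fe_params)
    names = list(result.fe_params.index)
    cov = np.asarray(result.cov_params())[: len(params), : len(params)]
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(params, cov, size=n_draws, method="svd")
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    mean = draws.mean(axis=0)
    return pd.DataFrame(
        {
            "term": names,
            "estimate": mean,
            "lo": lo,
            "hi": hi,
            "meaningful": (lo > 0) | (hi < 0),
        }
    )


def _check_rank(exog, names):
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise RankError(f"singular design (rank {rank} < {exog.shape[1]})", names)


def compare_sizes(
    hr_table: pd.DataFrame, n_draws: int = 1000, seed: int = 0
) -> ModelSummary:
    """Log home-range size vs period, sex and year, individual as random
    intercept.  ``hr_table`` needs columns individual_id, period, sex, year,
    area_km2."""
    import statsmodels.formula.api as smf

    df = hr_table.copy()
    df["log_area"] = np.log(df["area_km2"].astype(float))
    model = smf.mixedlm(
        "log_area ~ C(period) + C(sex) + C(year)", df, groups=df["individual_id"]
    )
    _check_rank(model.exog, list(model.exog_names))
    result = model.fit(reml=True)
    terms = _simulate_summary(result, n_draws, seed)
    re_var = {"individual": float(result.cov_re.iloc[0, 0]), "residual": float(result.scale)}
    return ModelSummary(terms, n_draws, seed, re_var)


def compare_distances(
    dist_table: pd.DataFrame, n_draws: int = 1000, seed: int = 0
) -> ModelSummary:
    """Log centroid-nest-box distance vs distance type (1: breeding HR to
    breeding box, 2: non-breeding HR to previous box, 3: non-breeding HR to
    future box) and sex; individual and nest box as crossed random
    intercepts."""
    import statsmodels.formula.api as smf

    df = dist_table.copy()
    df["log_dist"] = np.log(df["distance_m"].astype(float))
    df["_one"] = 1
    vc = {"individual": "0 + C(individual_id)", "nestbox": "0 + C(nestbox_id)"}
    model = smf.mixedlm(
        "log_dist ~ C(dist_type) + C(sex)", df, groups=df["_one"], vc_formula=vc
    )
    _check_rank(model.exog, list(model.exog_names))
    try:
        result = model.fit(reml=True)
        re_var = dict(zip(model.exog_vc.names, (float(v) for v in result.vcomp)))
    except np.linalg.LinAlgError:
        # nest boxes aliased with individuals (each bird its own box): the
        # two variance components are not separable; keep the individual one
        warnings.warn(
            "crossed random effects unidentifiable; falling back to an "
            "individual-only random intercept"
        )
        model = smf.mixedlm(
            "log_dist ~ C(dist_type) + C(sex)", df, groups=df["individual_id"]
        )
        result = model.fit(reml=True)
        re_var = {"individual": float(result.cov_re.iloc[0, 0])}
    terms = _simulate_summary(result, n_draws, seed)
    re_var["residual"] = float(result.scale)
    return ModelSummary(terms, n_draws, seed, re_var)
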