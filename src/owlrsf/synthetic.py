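"""Synthetic landscapes, small-mammal surveys, and GPS deployments.

Everything downstream of raw field data is testable against this module:
landscapes are clustered categorical rasters with rare border/biodiversity
overlays, surveys are Poisson counts driven by known habitat x season
intensities (log-harmonic, so the activity model can recover them exactly up
to sampling noise), and GPS tracks are draws from an inhomogeneous point
process with known selection coefficients over focal-area covariates, on the
two-half-nights-a-week fix schedule.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .composition import FocalComposer
from .errors import ConfigurationError, GeometryError
from .landscape import CATEGORIES, CATEGORY_CODE, SURVEY_HABITATS, LandscapeRaster

#: Landscape composition typical of the intensively farmed study region:
#: home-range coverages (crop 43.5%, intensive grassland 16.1%, extensive
#: grassland 5.6%, forest 13.4%, urban 10.7%) rescaled to sum to one.
DEFAULT_HABITAT_MIX = {
    "crop_rotation": 0.487,
    "intensive_grassland": 0.180,
    "extensive_grassland": 0.063,
    "forest": 0.150,
    "urban": 0.120,
}

#: Session days of year: surveys run every second month, six sessions a year
#: (mid Feb, Apr, Jun, Aug, Oct, Dec).
SESSION_DAYS = (46, 105, 166, 227, 288, 349)

_OMEGA = 2.0 * math.pi / 365.0


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    road_density is km of road per km^2 (roads become one-cell border-
    structure strips); biodiv_density is biodiversity structures per km^2
    (single cells or 3-cell hedges).  patch_sigma controls habitat patch
    size in cells (smoothed-noise thresholding) and is unconstrained by any
    field measurement.
    """

    extent_m: float = 5000.0
    cell_m: float = 25.0
    habitat_mix: dict = field(default_factory=lambda: dict(DEFAULT_HABITAT_MIX))
    road_density: float = 0.6
    biodiv_density: float = 10.0
    patch_sigma: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.extent_m <= 0 or self.cell_m <= 0:
            raise ConfigurationError("extent_m and cell_m must be positive")
        n = self.extent_m / self.cell_m
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("cell_m must divide extent_m")
        total = sum(self.habitat_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"habitat_mix sums to {total}, expected 1")
        if any(v < 0 for v in self.habitat_mix.values()):
            raise ConfigurationError("habitat_mix proportions must be >= 0")
        unknown = set(self.habitat_mix) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")


def _largest_remainder_counts(shares: np.ndarray, total: int) -> np.ndarray:
    raw = shares * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_landscape(cfg: LandscapeConfig) -> LandscapeRaster:
    """Generate a clustered categorical landscape with structure overlays.

    Habitat patches come from per-category smoothed Gaussian noise fields;
    cells are assigned by descending field value until each category reaches
    its exact target cell count, so realised proportions match the mix up to
    rounding.  Roads are straight one-cell transects (alternating
    horizontal/vertical); biodiversity structures are single cells or 3-cell
    linear hedges.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.extent_m / cfg.cell_m))
    n_cells = n * n

    cats = [c for c in CATEGORIES if cfg.habitat_mix.get(c, 0.0) > 0]
    shares = np.array([cfg.habitat_mix[c] for c in cats])
    counts = _largest_remainder_counts(shares / shares.sum(), n_cells)

    fields = np.stack(
        [
            gaussian_filter(rng.standard_normal((n, n)), cfg.patch_sigma, mode="wrap")
            for _ in cats
        ]
    )
    grid = np.full(n_cells, -1, dtype=np.int64)
    # assign largest categories first; each takes its top unassigned cells
    order = np.argsort(-counts)
    for rank, k in enumerate(order):
        free = np.flatnonzero(grid < 0)
        if rank == len(order) - 1:
            take = free
        else:
            take = free[np.argsort(-fields[k].ravel()[free])[: counts[k]]]
        grid[take] = CATEGORY_CODE[cats[k]]
    grid = grid.reshape(n, n)

    border = np.zeros((n, n), dtype=bool)
    area_km2 = (cfg.extent_m / 1000.0) ** 2
    n_roads = int(round(cfg.road_density * area_km2 / (cfg.extent_m / 1000.0)))
    for i in range(n_roads):
        pos = int(rng.integers(0, n))
        if i % 2 == 0:
            border[pos, :] = True
        else:
            border[:, pos] = True

    biodiv = np.zeros((n, n), dtype=bool)
    n_struct = int(round(cfg.biodiv_density * area_km2))
    for _ in range(n_struct):
        iy = int(rng.integers(0, n))
        ix = int(rng.integers(0, n))
        if rng.random() < 0.5:
            biodiv[iy, ix] = True
        else:  # 3-cell linear hedge
            horiz = rng.random() < 0.5
            for step in range(3):
                jy = iy if horiz else min(iy + step, n - 1)
                jx = min(ix + step, n - 1) if horiz else ix
                biodiv[jy, jx] = True

    return LandscapeRaster(
        grid=grid, border_mask=border, biodiv_mask=biodiv, cell_m=cfg.cell_m
    )


# ---------------------------------------------------------------------------
# Small-mammal surveys
# ---------------------------------------------------------------------------


@dataclass
class SurveyDesign:
    """Survey layout: defaults give 4 regions x 4 plots x 5 habitats x 9
    transects = 720 transects (and as many track-plates) per session."""

    n_regions: int = 4
    n_plots_per_region: int = 4
    plot_area_km2: float = 9.0
    habitats_surveyed: tuple = SURVEY_HABITATS
    transects_per_habitat_per_plot: int = 9
    plate_nights: int = 3
    sessions_per_year: int = 6

    @property
    def transects_per_session(self) -> int:
        return (
            self.n_regions
            * self.n_plots_per_region
            * len(self.habitats_surveyed)
            * self.transects_per_habitat_per_plot
        )


@dataclass(frozen=True)
class HarmonicIntensity:
    """Log-linear seasonal intensity: ``log lam = a + amp1*cos(w(d - peak1))
    + amp2*cos(2w(d - peak2))`` with day-of-year ``d``."""

    a: float
    amp1: float = 0.0
    peak1: float = 0.0
    amp2: float = 0.0
    peak2: float = 0.0

    def log_lam(self, day: float) -> float:
        return (
            self.a
            + self.amp1 * math.cos(_OMEGA * (day - self.peak1))
            + self.amp2 * math.cos(2 * _OMEGA * (day - self.peak2))
        )


#: Vole-sign transect intensities: non-breeding peak in grassland and border
#: structures, post-harvest crash in crop rotation, low in forest.
VOLE_INTENSITY = {
    "grassland": HarmonicIntensity(a=0.7, amp1=0.8, peak1=335),
    "border_structures": HarmonicIntensity(a=0.9, amp1=0.9, peak1=335),
    "crop_rotation": HarmonicIntensity(a=0.3, amp1=1.2, peak1=170, amp2=0.4, peak2=80),
    "forest": HarmonicIntensity(a=-0.7, amp1=0.3, peak1=250),
    "biodiversity_structures": HarmonicIntensity(a=0.8, amp1=0.3, peak1=300),
}

#: Track-plate (all small mammals) intensities: broad summer maximum in the
#: farmed habitats, late peak reaching into the non-breeding period in forest
#: and biodiversity structures.
SMALLMAMMAL_INTENSITY = {
    "crop_rotation": HarmonicIntensity(a=1.2, amp1=0.9, peak1=170),
    "grassland": HarmonicIntensity(a=1.2, amp1=0.7, peak1=170),
    "forest": HarmonicIntensity(a=1.3, amp1=0.6, peak1=320),
    "biodiversity_structures": HarmonicIntensity(a=1.3, amp1=0.5, peak1=300),
    "border_structures": HarmonicIntensity(a=1.0, amp1=0.4, peak1=280),
}

#: Additive log-scale region effects (region 0 is the reference).
REGION_EFFECTS = (0.0, 0.1, -0.1, 0.05)

#: Reference temperature (deg C) at which intensities are quoted, and the
#: seasonal temperature curve used for the synthetic weather series.
TEMP_REF = 10.0


def seasonal_temperature(day) -> np.ndarray:
    """Smooth seasonal mean temperature (deg C), minimum mid January."""
    day = np.asarray(day, dtype=float)
    return 10.0 - 8.0 * np.cos(_OMEGA * (day - 196.0) + math.pi)


def default_survey_intensity(method: str):
    """Mean-count function ``f(habitat, region, day) -> lam`` for a method."""
    table = VOLE_INTENSITY if method == "transect" else SMALLMAMMAL_INTENSITY

    def f(habitat: str, region: int, day: float) -> float:
        base = table[habitat].log_lam(day)
        return math.exp(base + REGION_EFFECTS[region % len(REGION_EFFECTS)])

    return f


def simulate_surveys(
    intensity=None,
    design: SurveyDesign | None = None,
    seed: int = 0,
    temp_slope: float = 0.03,
    temp_noise_sd: float = 1.0,
    year: int = 2018,
) -> pd.DataFrame:
    """Simulate one year of transect and track-plate survey counts.

    Counts are Poisson with mean ``lam(habitat, region, day) *
    exp(temp_slope * (T_window - TEMP_REF))`` where the temperature window is
    the 10 days before the session for transects and the 3 plate nights for
    track-plates.  The returned frame carries a ``true_mean`` ground-truth
    column per record.
    """
    design = design or SurveyDesign()
    if intensity is None:
        intensity = {
            "transect": default_survey_intensity("transect"),
            "trackplate": default_survey_intensity("trackplate"),
        }
    rng = np.random.default_rng(seed)
    rows = []
    sessions = SESSION_DAYS[: design.sessions_per_year]
    for s_idx, day in enumerate(sessions, start=1):
        t_window = {
            "transect": float(np.mean(seasonal_temperature(np.arange(day - 10, day)))),
            "trackplate": float(
                np.mean(seasonal_temperature(np.arange(day, day + design.plate_nights)))
            ),
        }
        for region in range(design.n_regions):
            for plot in range(design.n_plots_per_region):
                temps = {
                    m: t_window[m] + rng.normal(0.0, temp_noise_sd) for m in t_window
                }
                for habitat in design.habitats_surveyed:
                    for _transect in range(design.transects_per_habitat_per_plot):
                        for method in ("transect", "trackplate"):
                            lam = intensity[method](habitat, region, day)
                            if lam < 0:
                                raise ConfigurationError("negative intensity")
                            mean = lam * math.exp(
                                temp_slope * (temps[method] - TEMP_REF)
                            )
                            rows.append(
                                {
                                    "method": method,
                                    "region": region,
                                    "plot": plot,
                                    "habitat": habitat,
                                    "session": s_idx,
                                    "year": year,
                                    "day_of_year": day,
                                    "temperature": temps[method],
                                    "count": int(rng.poisson(mean)),
                                    "true_mean": mean,
                                }
                            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GPS deployments
# ---------------------------------------------------------------------------


@dataclass
class TrueSelection:
    """Ground-truth selection: used-point density ``exp(beta . x(s))`` over
    weighted focal-area covariates within a disc-shaped home range.

    ``beta`` maps covariate names (main categories, optionally
    ``border_structures`` / ``biodiversity_structures``) to log relative-
    selection coefficients; the reference category (crop rotation) is 0 by
    construction.
    """

    beta: dict
    home_center: tuple
    home_radius: float

    def __post_init__(self):
        if self.beta.get("crop_rotation", 0.0) != 0.0:
            raise ConfigurationError("reference category coefficient must be 0")
        if self.home_radius <= 0:
            raise ConfigurationError("home_radius must be positive")


@dataclass
class ContaminationConfig:
    """Defaults exercise every cleaning rule with known expected removals:
    exact duplicates, aberrant fixes displaced >= 10 km (caught by the
    bounding-box sanity check), and stationary roost clusters of 3-6 hourly
    fixes within 10 m (collapsed by inactivity resampling)."""

    duplicate_frac: float = 0.02
    aberrant_frac: float = 0.005
    aberrant_min_km: float = 10.0
    roost_clusters_per_weeks: float = 0.5  # clusters per week
    roost_cluster_size: tuple = (3, 6)
    roost_radius_m: float = 10.0


def _halfnight_schedule(weeks: int, rng, start: pd.Timestamp) -> list[pd.Timestamp]:
    """Hourly fix slots on two half-nights a week (7-12 p.m. and 0-4 a.m.)."""
    slots = []
    for w in range(weeks):
        nights = rng.choice(7, size=2, replace=False)
        evening, morning = int(nights[0]), int(nights[1])
        base = start + pd.Timedelta(days=7 * w)
        for h in range(19, 24):
            slots.append(base + pd.Timedelta(days=evening, hours=h))
        for h in range(0, 5):
            slots.append(base + pd.Timedelta(days=morning, hours=h))
    return sorted(slots)


def sample_ipp_points(
    n: int,
    truth: TrueSelection,
    composer: FocalComposer,
    rng,
    batch: int = 4096,
) -> np.ndarray:
    """Rejection-sample ``n`` points with density ``exp(beta . x(s))`` over
    the home disc intersected with the landscape."""
    landscape = composer.landscape
    cx, cy = truth.home_center
    r = truth.home_radius
    beta_main = np.array([truth.beta.get(c, 0.0) for c in CATEGORIES])
    b_border = truth.beta.get("border_structures", 0.0)
    b_biodiv = truth.beta.get("biodiversity_structures", 0.0)
    log_bound = sum(max(v, 0.0) for v in truth.beta.values())

    out = np.empty((0, 2))
    guard = 0
    while out.shape[0] < n:
        guard += 1
        if guard > 10_000:
            raise GeometryError("IPP sampler failed to accept points")
        theta = rng.uniform(0, 2 * math.pi, size=batch)
        rad = r * np.sqrt(rng.uniform(0, 1, size=batch))
        x = cx + rad * np.cos(theta)
        y = cy + rad * np.sin(theta)
        inside = landscape.contains(x, y)
        if not inside.any():
            continue
        x, y = x[inside], y[inside]
        comp = composer.compose(x, y)
        score = (
            beta_main @ comp.main_w + b_border * comp.border_w + b_biodiv * comp.biodiv_w
        )
        accept = rng.uniform(0, 1, size=x.size) < np.exp(score - log_bound)
        pts = np.column_stack([x[accept], y[accept]])
        out = np.vstack([out, pts])
    return out[:n]


def simulate_deployment(
    truth: TrueSelection,
    landscape: LandscapeRaster,
    weeks: int,
    seed: int = 0,
    deployment_id: str = "D001",
    individual_id: str = "I001",
    sex: str = "f",
    start: str | pd.Timestamp = "2018-10-01",
    fix_success: float = 0.66,
    contamination: ContaminationConfig | None = None,
    composer: FocalComposer | None = None,
) -> pd.DataFrame:
    """Simulate a non-breeding GPS deployment.

    Fix slots follow the two-half-nights-a-week hourly schedule; each slot
    yields a fix with probability ``fix_success`` (default 0.66, matching an
    average of about 6.6 retained locations per week).  Used locations are an
    inhomogeneous point process with density proportional to
    ``exp(beta . x(s))`` within the home disc.  Optional contamination adds
    rows labelled in the ``truth_label`` column (clean rows are ``"used"``).
    """
    if weeks < 1:
        raise ConfigurationError("weeks must be >= 1")
    cx, cy = truth.home_center
    if not bool(landscape.contains(cx, cy)):
        raise GeometryError("home_center outside landscape")
    if (
        cx + truth.home_radius < 0
        or cy + truth.home_radius < 0
        or cx - truth.home_radius > landscape.extent_x
        or cy - truth.home_radius > landscape.extent_y
    ):
        raise GeometryError("home disc entirely outside landscape")

    rng = np.random.default_rng(seed)
    composer = composer or FocalComposer(landscape)
    slots = _halfnight_schedule(weeks, rng, pd.Timestamp(start))
    kept = [t for t in slots if rng.random() < fix_success]
    pts = sample_ipp_points(len(kept), truth, composer, rng)
    df = pd.DataFrame(
        {
            "deployment_id": deployment_id,
            "individual_id": individual_id,
            "sex": sex,
            "timestamp": kept,
            "x_m": pts[:, 0],
            "y_m": pts[:, 1],
            "truth_label": "used",
        }
    )

    if contamination is not None:
        df = _contaminate(df, landscape, contamination, rng)
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _contaminate(df, landscape, cfg: ContaminationConfig, rng) -> pd.DataFrame:
    n = len(df)
    extra = []
    # exact duplicates of existing rows
    n_dup = int(round(cfg.duplicate_frac * n))
    for i in rng.choice(n, size=n_dup, replace=False) if n_dup else []:
        row = df.iloc[int(i)].copy()
        row["truth_label"] = "duplicate"
        extra.append(row)
    # aberrant fixes far outside the landscape
    n_ab = int(round(cfg.aberrant_frac * n))
    for i in rng.choice(n, size=n_ab, replace=False) if n_ab else []:
        row = df.iloc[int(i)].copy()
        theta = rng.uniform(0, 2 * math.pi)
        dist = cfg.aberrant_min_km * 1000.0 * rng.uniform(1.0, 3.0)
        row["x_m"] = row["x_m"] + dist * math.cos(theta)
        row["y_m"] = row["y_m"] + dist * math.sin(theta)
        row["timestamp"] = row["timestamp"] + pd.Timedelta(minutes=1)
        row["truth_label"] = "aberrant"
        extra.append(row)
    # stationary roost clusters: rewrite runs of consecutive hourly fixes
    df = df.copy()
    weeks = max(1, int(round((df["timestamp"].max() - df["timestamp"].min()).days / 7)))
    n_clusters = int(round(cfg.roost_clusters_per_weeks * weeks))
    lo, hi = cfg.roost_cluster_size
    for _ in range(n_clusters):
        size = int(rng.integers(lo, hi + 1))
        if len(df) <= size:
            break
        start = int(rng.integers(0, len(df) - size))
        base_x = df["x_m"].iloc[start]
        base_y = df["y_m"].iloc[start]
        idx = df.index[start : start + size]
        ang = rng.uniform(0, 2 * math.pi, size=size)
        rad = rng.uniform(0, cfg.roost_radius_m, size=size)
        df.loc[idx, "x_m"] = base_x + rad * np.cos(ang)
        df.loc[idx, "y_m"] = base_y + rad * np.sin(ang)
        df.loc[idx, "truth_label"] = "roost"
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df
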