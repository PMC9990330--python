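"""Used/available design: focal areas, filters, and prey covariates.

Each used GPS fix and each availability point gets a 75 x 75 m focal area —
a 3 x 3 block of 25 m cells with the centre cell weighted 0.2 and each
neighbour 0.1 — summarised as weighted habitat proportions, overlay
fractions, a dominant category, structural richness, and prey activity
densities.  Three filters mirror the field protocol: coverage (described
fraction in [0.5, 1.2]), known dominant category, and suitable foraging
habitat (forest + urban not above 0.8).  All removals are counted per case
so the cascade accounting reconciles exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .activity import ActivityModel, index_by_habitat
from .composition import FocalComposer
from .errors import GeometryError
from .homerange import HomeRange
from .landscape import ACTIVITY_HABITATS, CATEGORIES, LandscapeRaster

#: survey stratum supplying the activity index of each focal habitat stratum
_ACT_TO_SURVEY = {
    "crop_rotation": "crop_rotation",
    "intensive_grassland": "grassland",
    "extensive_grassland": "grassland",
    "border_structures": "border_structures",
    "biodiversity_structures": "biodiversity_structures",
}

FOCAL_SIZE_M = 75.0
FOCAL_AREA_M2 = FOCAL_SIZE_M**2  # 5625


def sample_available(
    hr: HomeRange, n_used: int, ratio: int = 100, seed: int = 0
) -> np.ndarray:
    """Uniform availability sample inside the home-range polygon.

    Returns exactly ``n_used * ratio`` points, drawn by rejection from the
    polygon's bounding box; deterministic for a fixed seed.
    """
    poly = hr.polygon
    if poly.area == 0.0:
        raise GeometryError("zero-area polygon")
    n_target = int(n_used) * int(ratio)
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = poly.bounds
    out = []
    got = 0
    while got < n_target:
        m = max(4096, int(1.5 * (n_target - got) * (maxx - minx) * (maxy - miny) / poly.area))
        m = min(m, 4_000_000)
        x = rng.uniform(minx, maxx, size=m)
        y = rng.uniform(miny, maxy, size=m)
        inside = shapely.contains_xy(poly, x, y)
        pts = np.column_stack([x[inside], y[inside]])
        out.append(pts)
        got += len(pts)
    return np.vstack(out)[:n_target]


@dataclass
class FocalArea:
    """Weighted 75 x 75 m habitat summary around one point."""

    center: tuple
    case: str
    weighted_proportions: dict
    border_fraction: float
    biodiv_fraction: float
    described_fraction: float
    dominant: str  # category name or "unknown"
    structural_richness: int
    biodiv_present: bool
    vole_density: float = float("nan")
    smallmammal_density: float = float("nan")
    prey_by_habitat: dict = field(default_factory=dict)


def coverage_filter(described_fraction: float) -> bool:
    """Keep iff 0.50 <= described <= 1.20 (both boundaries inclusive)."""
    return 0.50 <= described_fraction <= 1.20


def foraging_filter(forest_w: float, urban_w: float) -> bool:
    """Keep unless forest + urban cover strictly more than 80%."""
    return (forest_w + urban_w) <= 0.80


def dominant_category(weighted_proportions: dict) -> str:
    """Argmax over the five main categories with the fixed priority
    tie-break; ``unknown`` iff all five are zero."""
    from .composition import DOMINANT_PRIORITY

    best, best_v = "unknown", 0.0
    for cat in DOMINANT_PRIORITY:
        v = weighted_proportions.get(cat, 0.0)
        if v > best_v:
            best, best_v = cat, v
    return best


def _activity_lookup(model: ActivityModel | None, region, date) -> np.ndarray:
    """Index per ACTIVITY_HABITAT (0 when no model is given)."""
    if model is None:
        return np.zeros(len(ACTIVITY_HABITATS))
    by_survey = index_by_habitat(model, region, date)
    return np.array([by_survey[_ACT_TO_SURVEY[h]] for h in ACTIVITY_HABITATS])


def build_focal_table(
    used: pd.DataFrame,
    available: pd.DataFrame,
    landscape: LandscapeRaster,
    vole_model: ActivityModel | None = None,
    smallmammal_model: ActivityModel | None = None,
    region=0,
    date=349,
    composer: FocalComposer | None = None,
) -> pd.DataFrame:
    """Compute every focal-area covariate and filter flag for a design table.

    ``used`` and ``available`` need columns x_m, y_m, deployment_id, sex.
    Prey densities are index x m^2 sums over the weighted habitat areas of
    the focal square; per-habitat components are kept for the total-prey
    model.  Filter flags (coverage_keep, dominant_known, foraging_keep) are
    attached; nothing is dropped here so the cascade can be audited.
    """
    composer = composer or FocalComposer(landscape, size_m=FOCAL_SIZE_M)
    frames = []
    for case, df in (("used", used), ("available", available)):
        if df is None or len(df) == 0:
            continue
        x = df["x_m"].to_numpy(dtype=float)
        y = df["y_m"].to_numpy(dtype=float)
        comp = composer.compose(x, y)
        out = pd.DataFrame(
            {
                "case": case,
                "y": 1 if case == "used" else 0,
                "deployment_id": df["deployment_id"].to_numpy(),
                "sex": df["sex"].to_numpy(),
                "x_m": x,
                "y_m": y,
            }
        )
        for i, cat in enumerate(CATEGORIES):
            out[f"w_{cat}"] = comp.main_w[i]
        out["border_w"] = comp.border_w
        out["biodiv_w"] = comp.biodiv_w
        out["described_fraction"] = comp.described_fraction
        dom = comp.dominant()
        out["dominant"] = np.where(
            dom < 0, "unknown", np.asarray(CATEGORIES + ("unknown",))[dom]
        )
        out["structural_richness"] = comp.structural_richness()
        out["biodiv_present"] = comp.biodiv_w > 0
        vole_idx = _activity_lookup(vole_model, region, date)
        sm_idx = _activity_lookup(smallmammal_model, region, date)
        areas = comp.activity_w * FOCAL_AREA_M2  # (5, n) weighted m^2
        for i, hab in enumerate(ACTIVITY_HABITATS):
            out[f"vole_{hab}"] = areas[i] * vole_idx[i]
            out[f"smallmammal_{hab}"] = areas[i] * sm_idx[i]
        out["vole_density"] = (areas * vole_idx[:, None]).sum(axis=0)
        out["smallmammal_density"] = (areas * sm_idx[:, None]).sum(axis=0)
        out["coverage_keep"] = (out["described_fraction"] >= 0.50) & (
            out["described_fraction"] <= 1.20
        )
        out["dominant_known"] = out["dominant"] != "unknown"
        out["foraging_keep"] = (out["w_forest"] + out["w_urban"]) <= 0.80
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def build_focal_area(
    point,
    landscape: LandscapeRaster,
    vole_model: ActivityModel | None = None,
    smallmammal_model: ActivityModel | None = None,
    region=0,
    date=349,
    case: str = "used",
) -> FocalArea:
    """Single-point convenience wrapper over :func:`build_focal_table`."""
    df = pd.DataFrame(
        {"x_m": [point[0]], "y_m": [point[1]], "deployment_id": ["_"], "sex": ["f"]}
    )
    row = build_focal_table(
        df, None, landscape, vole_model, smallmammal_model, region, date
    ).iloc[0]
    props = {cat: float(row[f"w_{cat}"]) for cat in CATEGORIES}
    prey = {
        hab: {"vole": float(row[f"vole_{hab}"]), "smallmammal": float(row[f"smallmammal_{hab}"])}
        for hab in ACTIVITY_HABITATS
    }
    return FocalArea(
        center=(float(point[0]), float(point[1])),
        case=case,
        weighted_proportions=props,
        border_fraction=float(row["border_w"]),
        biodiv_fraction=float(row["biodiv_w"]),
        described_fraction=float(row["described_fraction"]),
        dominant=str(row["dominant"]),
        structural_richness=int(row["structural_richness"]),
        biodiv_present=bool(row["biodiv_present"]),
        vole_density=float(row["vole_density"]),
        smallmammal_density=float(row["smallmammal_density"]),
        prey_by_habitat=prey,
    )


def zscore(values: np.ndarray, label: str = "") -> np.ndarray:
    """Centre and scale; a zero-variance column maps to all zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=0)
    if sd == 0.0:
        warnings.warn(f"zero-variance column {label!r}; z-scores set to 0")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def total_prey_by_habitat(
    table: pd.DataFrame, merge_grassland: bool = False
) -> pd.DataFrame:
    """Combined (vole + small mammal) prey activity per habitat and focal
    area: per habitat, the sum of the two methods' z-scored densities, the
    z-scores computed over the full table passed in.

    With ``merge_grassland`` the two grassland strata are pooled (area sums)
    before scaling, for the reduced-complexity total-prey model.
    """
    habitats = list(ACTIVITY_HABITATS)
    vole = {h: table[f"vole_{h}"].to_numpy(dtype=float) for h in habitats}
    sm = {h: table[f"smallmammal_{h}"].to_numpy(dtype=float) for h in habitats}
    if merge_grassland:
        for d in (vole, sm):
            d["grassland"] = d.pop("intensive_grassland") + d.pop("extensive_grassland")
        habitats = ["crop_rotation", "grassland", "border_structures", "biodiversity_structures"]
    out = pd.DataFrame(index=table.index)
    for h in habitats:
        out[f"total_prey_{h}"] = zscore(vole[h], f"vole_{h}") + zscore(sm[h], f"smallmammal_{h}")
    return out


@dataclass
class CascadeAccounting:
    """Sequential filter accounting for one case (used or available).

    ``sizes()`` returns the dataset size after each removal; the invariant
    ``n_out == n_in - sum(removals)`` holds by construction.
    """

    n_input: int
    removals: list

    def sizes(self) -> list:
        out = [self.n_input]
        for r in self.removals:
            out.append(out[-1] - r)
        return out

    @property
    def n_output(self) -> int:
        return self.sizes()[-1]

    def reconciles(self) -> bool:
        return self.n_output == self.n_input - sum(self.removals)


def cascade_from_flags(table: pd.DataFrame, case: str) -> CascadeAccounting:
    """Audit the filter cascade from the flags of a focal table."""
    df = table[table["case"] == case]
    n0 = len(df)
    r_cov = int((~df["coverage_keep"]).sum())
    after_cov = df[df["coverage_keep"]]
    r_dom = int((~after_cov["dominant_known"]).sum())
    return CascadeAccounting(n_input=n0, removals=[r_cov, r_dom])


def foraging_cascade_from_flags(table: pd.DataFrame, case: str) -> CascadeAccounting:
    """Cascade for the prey models: coverage filter then foraging filter."""
    df = table[table["case"] == case]
    n0 = len(df)
    r_cov = int((~df["coverage_keep"]).sum())
    after_cov = df[df["coverage_keep"]]
    r_forage = int((~after_cov["foraging_keep"]).sum())
    return CascadeAccounting(n_input=n0, removals=[r_cov, r_forage])
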