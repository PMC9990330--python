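"""Shared fixtures: all data are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from owlrsf import focal as fc
from owlrsf import homerange as hrm
from owlrsf.activity import fit_activity_model
from owlrsf.composition import FocalComposer
from owlrsf.landscape import LandscapeRaster
from owlrsf.synthetic import (
    LandscapeConfig,
    TrueSelection,
    generate_landscape,
    sample_ipp_points,
    simulate_surveys,
)


@pytest.fixture(scope="session")
def landscape():
    """Default 5 km synthetic landscape (200 x 200 cells of 25 m)."""
    return generate_landscape(LandscapeConfig(seed=1))


@pytest.fixture(scope="session")
def composer(landscape):
    return FocalComposer(landscape)


@pytest.fixture(scope="session")
def survey_records():
    return simulate_surveys(seed=5)


@pytest.fixture(scope="session")
def vole_model(survey_records):
    return fit_activity_model(survey_records, method="transect")


@pytest.fixture(scope="session")
def smallmammal_model(survey_records):
    return fit_activity_model(survey_records, method="trackplate")


def uniform_landscape(category: str, n: int = 40, cell_m: float = 25.0) -> LandscapeRaster:
    """Single-category landscape helper for degenerate-geometry tests."""
    from owlrsf.landscape import CATEGORY_CODE

    grid = np.full((n, n), CATEGORY_CODE[category], dtype=np.int64)
    empty = np.zeros((n, n), dtype=bool)
    return LandscapeRaster(grid=grid, border_mask=empty, biodiv_mask=empty.copy(), cell_m=cell_m)


def simulate_recovery_table(landscape, composer, seed: int, n_used: int = 2000, ratio: int = 100):
    """One IPP deployment with known truth plus its availability sample.

    Ground truth: selection +1 for intensive grassland and -1 for forest on
    the weighted focal-area proportions, inside a 900 m home disc;
    availability uniform over the same disc.
    """
    truth = TrueSelection(
        beta={"intensive_grassland": 1.0, "forest": -1.0},
        home_center=(2500.0, 2500.0),
        home_radius=900.0,
    )
    rng = np.random.default_rng(seed)
    used = sample_ipp_points(n_used, truth, composer, rng)
    disc = Point(truth.home_center).buffer(truth.home_radius, quad_segs=128)
    hr = hrm.HomeRange(polygon=disc, area_km2=disc.area / 1e6, n_fixes_used=n_used)
    avail = fc.sample_available(hr, n_used, ratio=ratio, seed=seed + 10_000)
    used_df = pd.DataFrame(
        {"x_m": used[:, 0], "y_m": used[:, 1], "deployment_id": "D1", "sex": "f"}
    )
    av_df = pd.DataFrame(
        {"x_m": avail[:, 0], "y_m": avail[:, 1], "deployment_id": "D1", "sex": "f"}
    )
    return truth, used_df, av_df


def recovery_design(table):
    """Design matching the generative covariates (continuous proportions)."""
    import owlrsf.rsf as rsf

    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "intensive_grassland": table["w_intensive_grassland"],
            "extensive_grassland": table["w_extensive_grassland"],
            "forest": table["w_forest"],
            "urban": table["w_urban"],
        }
    )
    w = np.where(table["y"] == 1, 1.0, 5000.0)
    return rsf.RSFDesign(
        X=X,
        y=table["y"].to_numpy(dtype=float),
        weights=w,
        groups=table["deployment_id"].to_numpy(),
        model="recovery",
    )


@pytest.fixture(scope="session")
def recovery_table(landscape, composer, vole_model, smallmammal_model):
    """Focal table of one simulated deployment (seed 7), used/available,
    with prey activity covariates attached (region 0, mid December)."""
    truth, used_df, av_df = simulate_recovery_table(landscape, composer, seed=7)
    table = fc.build_focal_table(
        used_df,
        av_df,
        landscape,
        vole_model=vole_model,
        smallmammal_model=smallmammal_model,
        region=0,
        date=349,
        composer=composer,
    )
    return truth, table
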