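"""Prey activity-density indices from small-mammal survey counts.

Vole-sign transect counts and track-plate trace counts are fitted
*separately* as Poisson log-link GLMs with one intercept per habitat x
region stratum, a cyclic harmonic seasonal basis (sin/cos pairs, default
order 2) interacted with habitat, and a linear temperature term.  The fitted
value for a habitat, region and date is the activity-density index used
throughout the pipeline; multiplied by the area a habitat covers, it yields
per-cell or per-focal-area prey activity surfaces.

Habitat-specific seasonal weights are needed because the seasonal signal of
interest *is* habitat specific (post-harvest crash in crop rotation,
non-breeding vole peak in grassland and border structures); an additive
seasonal term cannot represent those patterns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, MissingIndexError
from .landscape import LandscapeRaster, SURVEY_HABITATS

_OMEGA = 2.0 * math.pi / 365.0


def _day_of_year(date) -> float:
    if isinstance(date, (int, float, np.integer, np.floating)):
        return float(date)
    return float(pd.Timestamp(date).dayofyear)


@dataclass
class ActivityModel:
    """Fitted activity-density index for one survey method.

    ``coefficients`` maps term names (``stratum:<habitat>:<region>``,
    ``harm:<habitat>:sin<j>|cos<j>``, ``temperature``) to log-scale values.
    Degenerate strata (all counts zero) are excluded from the fit and predict
    an index of exactly 0.
    """

    method: str
    order: int
    coefficients: dict
    std_errors: dict
    temp_mean: float
    habitats: list
    regions: list
    degenerate_strata: list = field(default_factory=list)
    dispersion: float = float("nan")
    converged: bool = True

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "ActivityModel":
        d = json.loads(Path(path).read_text())
        d["degenerate_strata"] = [tuple(s) for s in d["degenerate_strata"]]
        return cls(**d)


def _term_names(habitats, regions, order, strata):
    names = [f"stratum:{h}:{r}" for (h, r) in strata]
    for h in habitats:
        for j in range(1, order + 1):
            names += [f"harm:{h}:sin{j}", f"harm:{h}:cos{j}"]
    names.append("temperature")
    return names


def _design_matrix(habitat, region, day, temp_c, habitats, regions, order, strata):
    habitat = np.asarray(habitat)
    region = np.asarray(region)
    day = np.asarray(day, dtype=float)
    n = habitat.size
    cols = []
    for h, r in strata:
        cols.append(((habitat == h) & (region == r)).astype(float))
    for h in habitats:
        mask = (habitat == h).astype(float)
        for j in range(1, order + 1):
            cols.append(np.sin(j * _OMEGA * day) * mask)
            cols.append(np.cos(j * _OMEGA * day) * mask)
    cols.append(np.asarray(temp_c, dtype=float) * np.ones(n))
    return np.column_stack(cols)


def fit_activity_model(
    records: pd.DataFrame, method: str | None = None, order: int = 2
) -> ActivityModel:
    """Fit the Poisson activity index to one method's survey records.

    ``records`` needs columns habitat, region, day_of_year (or session-date
    ``date``), temperature, count, and method when both methods are present.
    """
    df = records
    if method is not None:
        df = df[df["method"] == method]
    elif df["method"].nunique() > 1:
        raise ConfigurationError("records mix methods; pass method= explicitly")
    else:
        method = df["method"].iloc[0]
    if df["session"].nunique() < 2 or df["habitat"].nunique() < 2:
        raise ConfigurationError("need >= 2 sessions and >= 2 habitats")

    day = (
        df["day_of_year"].to_numpy(dtype=float)
        if "day_of_year" in df
        else np.array([_day_of_year(d) for d in df["date"]])
    )
    habitats = sorted(df["habitat"].unique())
    regions = sorted(df["region"].unique())

    # strata with no signal at all cannot support a log-scale intercept;
    # they are flagged and pinned to index 0
    totals = df.groupby(["habitat", "region"])["count"].sum()
    degenerate = [tuple(k) for k, v in totals.items() if v == 0]
    strata = [tuple(k) for k in totals.index if tuple(k) not in degenerate]

    keep = ~df.set_index(["habitat", "region"]).index.isin(degenerate)
    dfk = df.loc[keep]
    dayk = day[np.asarray(keep)]
    temp_mean = float(dfk["temperature"].mean())
    X = _design_matrix(
        dfk["habitat"],
        dfk["region"],
        dayk,
        dfk["temperature"].to_numpy(dtype=float) - temp_mean,
        habitats,
        regions,
        order,
        strata,
    )
    y = dfk["count"].to_numpy(dtype=float)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    names = _term_names(habitats, regions, order, strata)
    coefs = dict(zip(names, (float(b) for b in res.params)))
    ses = dict(zip(names, (float(s) for s in res.bse)))
    pearson = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    return ActivityModel(
        method=method,
        order=order,
        coefficients=coefs,
        std_errors=ses,
        temp_mean=temp_mean,
        habitats=habitats,
        regions=list(regions),
        degenerate_strata=degenerate,
        dispersion=pearson,
        converged=bool(res.converged),
    )


def predict_activity(
    model: ActivityModel, habitat: str, region, date, temperature: float | None = None
) -> float:
    """Activity-density index for a stratum at a date.

    Periodic in the date with period one year; evaluated at the training-mean
    temperature unless one is given.  Degenerate strata predict exactly 0;
    strata never seen in training raise MissingIndexError.
    """
    if (habitat, region) in [tuple(s) for s in model.degenerate_strata]:
        return 0.0
    key = f"stratum:{habitat}:{region}"
    if key not in model.coefficients:
        raise MissingIndexError(f"stratum ({habitat}, {region}) not in training data")
    day = _day_of_year(date) % 365.0
    eta = model.coefficients[key]
    for j in range(1, model.order + 1):
        eta += model.coefficients[f"harm:{habitat}:sin{j}"] * math.sin(j * _OMEGA * day)
        eta += model.coefficients[f"harm:{habitat}:cos{j}"] * math.cos(j * _OMEGA * day)
    if temperature is not None:
        eta += model.coefficients["temperature"] * (temperature - model.temp_mean)
    return math.exp(eta)


def fitted_values(model: ActivityModel, records: pd.DataFrame) -> np.ndarray:
    """Fitted mean count per survey record (vectorised).

    Rows in a degenerate stratum get 0; rows in a stratum never seen in
    training raise MissingIndexError.
    """
    habitat = records["habitat"].to_numpy()
    region = records["region"].to_numpy()
    day = (
        records["day_of_year"].to_numpy(dtype=float)
        if "day_of_year" in records
        else np.array([_day_of_year(d) for d in records["date"]])
    )
    temp = records["temperature"].to_numpy(dtype=float)
    degenerate = {tuple(s) for s in model.degenerate_strata}
    out = np.zeros(len(records))
    for i in range(len(records)):
        key = (habitat[i], region[i])
        if key in degenerate:
            continue
        stratum = f"stratum:{habitat[i]}:{region[i]}"
        if stratum not in model.coefficients:
            raise MissingIndexError(f"stratum {key} not in training data")
        eta = model.coefficients[stratum]
        for j in range(1, model.order + 1):
            eta += model.coefficients[f"harm:{habitat[i]}:sin{j}"] * math.sin(
                j * _OMEGA * day[i]
            )
            eta += model.coefficients[f"harm:{habitat[i]}:cos{j}"] * math.cos(
                j * _OMEGA * day[i]
            )
        eta += model.coefficients["temperature"] * (temp[i] - model.temp_mean)
        out[i] = math.exp(eta)
    return out


def index_by_habitat(
    model: ActivityModel, region, date, temperature: float | None = None
) -> dict[str, float]:
    """Index per survey habitat; habitats absent from training map to 0."""
    out = {}
    for h in SURVEY_HABITATS:
        if h not in model.habitats:
            out[h] = 0.0
        else:
            try:
                out[h] = predict_activity(model, h, region, date, temperature)
            except MissingIndexError:
                out[h] = 0.0
    return out


@dataclass
class ActivityRaster:
    """Per-cell prey activity (index units x m^2) on the landscape grid."""

    values: np.ndarray
    cell_m: float
    date: object
    method: str

    def total(self) -> float:
        return float(self.values.sum())


def rasterize_activity(
    model: ActivityModel,
    landscape: LandscapeRaster,
    region,
    date,
    temperature: float | None = None,
) -> ActivityRaster:
    """Spread the activity index over the landscape grid.

    Each cell gets ``index(effective habitat, region, date) * cell area``,
    the structure overlays taking precedence over the underlying category.
    Cells with no surveyed stratum (urban area) contribute 0, so the grid
    total equals ``sum_h index_h * area_h`` exactly.
    """
    idx = index_by_habitat(model, region, date, temperature)
    lut = np.array([idx[h] for h in SURVEY_HABITATS] + [0.0])
    eff = landscape.effective_survey_habitat()
    values = lut[np.where(eff < 0, len(SURVEY_HABITATS), eff)] * landscape.cell_m**2
    return ActivityRaster(
        values=values, cell_m=landscape.cell_m, date=date, method=model.method
    )
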