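"""Categorical habitat rasters on a planar metric grid.

The landscape is a square grid of 25 m cells (configurable), each carrying
exactly one of five main habitat categories.  Two sparse boolean overlays —
border structures (strips along roads) and biodiversity structures (hedges,
single trees, wildflower strips) — sit on top of the main categories without
replacing them.  Coordinates are planar metres, x east / y north, with cell
(0, 0) at the lower-left corner and half-open cell intervals, so the point
(x, y) falls in cell ``(iy, ix) = (floor(y / cell_m), floor(x / cell_m))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Main habitat categories, in raster code order (code = index).
CATEGORIES = (
    "crop_rotation",
    "intensive_grassland",
    "extensive_grassland",
    "forest",
    "urban",
)

CATEGORY_CODE = {name: i for i, name in enumerate(CATEGORIES)}

#: Habitat strata of the small-mammal survey.  Grasslands are surveyed as a
#: single stratum; border and biodiversity structures are surveyed in their
#: own right even though they overlay a main category on the map.
SURVEY_HABITATS = (
    "crop_rotation",
    "grassland",
    "border_structures",
    "forest",
    "biodiversity_structures",
)

#: Main category -> survey stratum providing its activity index.  Urban area
#: is not surveyed and carries no prey-activity index.
CATEGORY_TO_SURVEY = {
    "crop_rotation": "crop_rotation",
    "intensive_grassland": "grassland",
    "extensive_grassland": "grassland",
    "forest": "forest",
    "urban": None,
}

#: Habitat strata used when attaching prey activity to focal areas.  Forest
#: and urban never enter these sums (forest prey is inaccessible, urban is
#: unsurveyed), matching the five-stratum focal-area accounting.
ACTIVITY_HABITATS = (
    "crop_rotation",
    "intensive_grassland",
    "extensive_grassland",
    "border_structures",
    "biodiversity_structures",
)


@dataclass
class LandscapeRaster:
    """A categorical habitat grid plus structure overlays.

    Attributes
    ----------
    grid : (ny, nx) int array of main-category codes (see CATEGORIES).
    border_mask : (ny, nx) bool array, cells crossed by the road-border strip.
    biodiv_mask : (ny, nx) bool array, cells carrying biodiversity structures.
    cell_m : cell edge length in metres.
    """

    grid: np.ndarray
    border_mask: np.ndarray
    biodiv_mask: np.ndarray
    cell_m: float
    crs_note: str = "planar metres, x east / y north, origin lower-left"

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.border_mask.shape != self.grid.shape:
            raise ValueError("border_mask shape mismatch")
        if self.biodiv_mask.shape != self.grid.shape:
            raise ValueError("biodiv_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent_x(self) -> float:
        return self.grid.shape[1] * self.cell_m

    @property
    def extent_y(self) -> float:
        return self.grid.shape[0] * self.cell_m

    def category_areas(self) -> dict[str, float]:
        """Area (m^2) per main category; sums exactly to the grid area."""
        cell_area = self.cell_m**2
        counts = np.bincount(self.grid.ravel(), minlength=len(CATEGORIES))
        return {name: float(counts[i] * cell_area) for i, name in enumerate(CATEGORIES)}

    def effective_survey_habitat(self) -> np.ndarray:
        """Per-cell survey stratum code, structure overlays taking precedence.

        Returns an int array indexing SURVEY_HABITATS, with -1 for cells that
        have no survey stratum (urban area without overlays).
        """
        out = np.full(self.grid.shape, -1, dtype=np.int64)
        survey_code = {name: i for i, name in enumerate(SURVEY_HABITATS)}
        for cat, stratum in CATEGORY_TO_SURVEY.items():
            if stratum is not None:
                out[self.grid == CATEGORY_CODE[cat]] = survey_code[stratum]
        out[self.border_mask] = survey_code["border_structures"]
        out[self.biodiv_mask] = survey_code["biodiversity_structures"]
        return out

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x < self.extent_x) & (y >= 0) & (y < self.extent_y)

    # ---- text serialisation (ASCII grid + JSON sidecar) -------------------

    def save(self, path_stem: str | Path) -> None:
        """Write ``<stem>.asc`` (ESRI ASCII grid) and ``<stem>.json`` sidecar."""
        stem = Path(path_stem)
        ny, nx = self.grid.shape
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner 0.0\nyllcorner 0.0\n"
            f"cellsize {self.cell_m}\nNODATA_value -1\n"
        )
        # ASCII grids are written north-to-south
        body = "\n".join(" ".join(str(v) for v in row) for row in self.grid[::-1])
        stem.with_suffix(".asc").write_text(header + body + "\n")
        sidecar = {
            "categories": list(CATEGORIES),
            "cell_m": self.cell_m,
            "crs_note": self.crs_note,
            "border_cells": np.argwhere(self.border_mask).tolist(),
            "biodiv_cells": np.argwhere(self.biodiv_mask).tolist(),
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path_stem: str | Path) -> "LandscapeRaster":
        stem = Path(path_stem)
        lines = stem.with_suffix(".asc").read_text().splitlines()
        # fixed 6-line ESRI ASCII header, rows north-to-south
        grid = np.array(
            [[int(v) for v in line.split()] for line in lines[6:] if line.strip()]
        )[::-1]
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        border = np.zeros(grid.shape, dtype=bool)
        biodiv = np.zeros(grid.shape, dtype=bool)
        for iy, ix in sidecar["border_cells"]:
            border[iy, ix] = True
        for iy, ix in sidecar["biodiv_cells"]:
            biodiv[iy, ix] = True
        return cls(
            grid=grid,
            border_mask=border,
            biodiv_mask=biodiv,
            cell_m=float(sidecar["cell_m"]),
            crs_note=sidecar.get("crs_note", ""),
        )
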