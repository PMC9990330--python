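"""Clean the GPS fixes and estimate 95% MCP home ranges per deployment.

Runs the full preprocessing cascade (duplicates/aberrant first, then the
30 m / 120 min inactivity resampling), assigns annual-cycle periods,
estimates the 95% minimum convex polygon with a bootstrap saturation check
per deployment, extracts home-range habitat composition, and fits the
log-linear comparison models: home-range size vs period and sex, and
centroid-to-nest-box distance vs distance type and sex.
"""

import json
import warnings

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH

from owlrsf import homerange as hrm
from owlrsf.landscape import LandscapeRaster
from owlrsf.preprocess import preprocess


def main():
    warnings.filterwarnings("ignore")
    landscape = LandscapeRaster.load(SCRATCH / "landscape")
    truth = json.loads((RESULTS / "simulation_truth.json").read_text())
    fixes = pd.read_csv(SCRATCH / "fixes.csv", parse_dates=["timestamp"])

    cleaned, report = preprocess(
        fixes, bbox=(0, 0, landscape.extent_x, landscape.extent_y)
    )
    print(
        f"cleaning: {report.n_input} fixes -> removed "
        f"{report.n_removed_duplicate} duplicates + {report.n_removed_aberrant} "
        f"aberrant + {report.n_removed_inactive} inactive -> {report.n_output}"
    )
    assert report.balances()
    (RESULTS / "cleaning_report.json").write_text(
        json.dumps(
            {
                "n_input": report.n_input,
                "n_removed_duplicate": report.n_removed_duplicate,
                "n_removed_aberrant": report.n_removed_aberrant,
                "n_removed_inactive": report.n_removed_inactive,
                "n_output": report.n_output,
            },
            indent=2,
        )
    )
    cleaned.to_csv(SCRATCH / "fixes_clean.csv", index=False)

    hr_rows, dist_rows = [], []
    polygons = {}
    for dep, grp in cleaned.groupby("deployment_id"):
        pts = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        period = "breeding" if dep.endswith("BR") else "non_breeding"
        ind = grp["individual_id"].iloc[0]
        sex = grp["sex"].iloc[0]
        hr = hrm.mcp(pts, isopleth=0.95, deployment_id=dep, period=period)
        sat = hrm.saturation(pts, n_boot=50, seed=11)
        comp = hrm.composition(hr, landscape)
        polygons[dep] = hr
        hr_rows.append(
            {
                "deployment_id": dep,
                "individual_id": ind,
                "sex": sex,
                "period": period,
                "year": 2018,
                "n_fixes": len(pts),
                "area_km2": hr.area_km2,
                "saturated": sat.saturated,
                **{f"prop_{k}": v for k, v in comp.items()},
            }
        )
        nest = tuple(truth[ind]["nest_box"])
        dist_type = 1 if period == "breeding" else 2
        dist_rows.append(
            {
                "individual_id": ind,
                "nestbox_id": f"N-{ind}",
                "sex": sex,
                "dist_type": dist_type,
                "distance_m": hrm.centroid_distance(hr, nest),
            }
        )

    hr_table = pd.DataFrame(hr_rows)
    hr_table.to_csv(RESULTS / "homeranges.csv", index=False)
    med = hr_table.groupby(["period", "sex"])["area_km2"].median().round(1)
    print("\nmedian 95% MCP area (km^2) by period and sex:")
    print(med.to_string())
    print(f"saturated: {int(hr_table['saturated'].sum())}/{len(hr_table)} deployments")

    overlaps = []
    for ind in truth:
        br, nb = polygons.get(f"{ind}-BR"), polygons.get(f"{ind}-NB")
        if br and nb:
            overlaps.append(hrm.hr_overlap(nb, br))
    print(f"median non-breeding/breeding overlap: {np.median(overlaps):.0%}")

    size_model = hrm.compare_sizes(hr_table, seed=3)
    dist_model = hrm.compare_distances(pd.DataFrame(dist_rows), seed=4)
    summary = pd.concat(
        [size_model.terms.assign(model="size"), dist_model.terms.assign(model="distance")]
    )
    summary.to_csv(RESULTS / "homerange_models.csv", index=False)
    print("\nlog-linear comparisons (mean, 95% interval):")
    print(summary.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
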