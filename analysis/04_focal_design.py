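"""Build the used/available design over the non-breeding home ranges.

For each non-breeding deployment: keep the used fixes inside the 95% MCP,
sample available locations at 1 used : 100 available inside the same
polygon, and summarise every location as a weighted 75 x 75 m focal area
with prey activity covariates (December index, region 0).  The coverage,
dominant-category, and foraging filters are flagged and the removal
cascade reported per case.
"""

import json
import warnings

import numpy as np
import pandas as pd
import shapely

from common import RESULTS, SCRATCH, SEED

from owlrsf import focal as fc
from owlrsf import homerange as hrm
from owlrsf.activity import ActivityModel
from owlrsf.composition import FocalComposer
from owlrsf.landscape import LandscapeRaster

RATIO = 100
DATE = 349  # mid-December session, non-breeding
REGION = 0


def main():
    warnings.filterwarnings("ignore")
    landscape = LandscapeRaster.load(SCRATCH / "landscape")
    composer = FocalComposer(landscape)
    vole = ActivityModel.load(RESULTS / "activity_vole.json")
    smallmammal = ActivityModel.load(RESULTS / "activity_smallmammal.json")
    fixes = pd.read_csv(SCRATCH / "fixes_clean.csv", parse_dates=["timestamp"])
    nb = fixes[fixes["period"] == "non_breeding"]

    used_frames, avail_frames = [], []
    for i, (dep, grp) in enumerate(nb.groupby("deployment_id")):
        pts = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        hr = hrm.mcp(pts, isopleth=0.95, deployment_id=dep, period="non_breeding")
        inside = shapely.contains_xy(hr.polygon, pts[:, 0], pts[:, 1])
        used = grp.loc[inside]
        avail = fc.sample_available(hr, n_used=len(used), ratio=RATIO, seed=SEED * 77 + i)
        used_frames.append(
            used[["x_m", "y_m", "deployment_id", "individual_id", "sex"]]
        )
        avail_frames.append(
            pd.DataFrame(
                {
                    "x_m": avail[:, 0],
                    "y_m": avail[:, 1],
                    "deployment_id": dep,
                    "individual_id": grp["individual_id"].iloc[0],
                    "sex": grp["sex"].iloc[0],
                }
            )
        )
    used_df = pd.concat(used_frames, ignore_index=True)
    avail_df = pd.concat(avail_frames, ignore_index=True)

    table = fc.build_focal_table(
        used_df,
        avail_df,
        landscape,
        vole_model=vole,
        smallmammal_model=smallmammal,
        region=REGION,
        date=DATE,
        composer=composer,
    )
    table.to_csv(SCRATCH / "focal_table.csv", index=False)

    cascade = {}
    for case in ("used", "available"):
        acc = fc.cascade_from_flags(table, case)
        forage = fc.foraging_cascade_from_flags(table, case)
        cascade[case] = {
            "n_input": acc.n_input,
            "removed_coverage": acc.removals[0],
            "removed_unknown_dominant": acc.removals[1],
            "n_habitat_model": acc.n_output,
            "removed_foraging": forage.removals[1],
            "n_prey_models": forage.n_output,
        }
        assert acc.reconciles() and forage.reconciles()
    (RESULTS / "cascade.json").write_text(json.dumps(cascade, indent=2))
    print("filter cascade:")
    print(json.dumps(cascade, indent=2))
    ratio = cascade["available"]["n_habitat_model"] / cascade["used"]["n_habitat_model"]
    print(f"post-filter used:available ratio 1:{ratio:.0f}")


if __name__ == "__main__":
    main()
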