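"""Simulate the study system: landscape, prey surveys, GPS deployments.

Generates a 5 x 5 km agricultural landscape (five habitat categories, rare
border and biodiversity structures), one year of two-monthly small-mammal
surveys (720 transects and track-plates per session), and paired breeding /
non-breeding GPS deployments for 12 individuals whose selection
coefficients are known: population-level preference for intensive grassland
and avoidance of forest, with individual variation on both.  Contaminated
fixes (duplicates, aberrant jumps, roost clusters) are injected into the
non-breeding tracks to exercise the cleaning cascade.

Bulky tables go to scratch/; the ground truth needed by later stages goes
to results/simulation_truth.json.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH, SEED, N_INDIVIDUALS, WEEKS_BREEDING, WEEKS_NON_BREEDING

from owlrsf.composition import FocalComposer
from owlrsf.synthetic import (
    ContaminationConfig,
    LandscapeConfig,
    TrueSelection,
    generate_landscape,
    simulate_deployment,
    simulate_surveys,
)

POP_BETA = {"intensive_grassland": 0.5, "extensive_grassland": 0.1, "forest": -0.8, "urban": 0.3}
SLOPE_SD = 0.3  # individual deviation on the grassland and forest coefficients


def main():
    rng = np.random.default_rng(SEED)

    landscape = generate_landscape(LandscapeConfig(seed=SEED))
    landscape.save(SCRATCH / "landscape")
    composer = FocalComposer(landscape)
    areas = landscape.category_areas()
    total = sum(areas.values())
    print("landscape composition:", {k: round(v / total, 3) for k, v in areas.items()})

    surveys = simulate_surveys(seed=SEED + 1)
    surveys.to_csv(SCRATCH / "surveys.csv", index=False)
    print(f"surveys: {len(surveys)} records "
          f"({int((surveys['method'] == 'transect').sum())} transect counts)")

    truth_out = {}
    frames = []
    for i in range(N_INDIVIDUALS):
        ind = f"I{i:02d}"
        sex = "m" if i % 2 == 0 else "f"
        nest = rng.uniform(1900, 3100, size=2)
        radius = 1500.0 if sex == "f" else 1100.0
        beta = dict(POP_BETA)
        beta["intensive_grassland"] += float(rng.normal(0, SLOPE_SD))
        beta["forest"] += float(rng.normal(0, SLOPE_SD))
        offset_sd = 700.0 if sex == "f" else 300.0
        nb_center = nest + rng.normal(0, offset_sd, size=2)
        nb_center = np.clip(nb_center, 1700, 3300)

        br = simulate_deployment(
            TrueSelection(beta=beta, home_center=tuple(nest), home_radius=radius),
            landscape,
            weeks=WEEKS_BREEDING,
            seed=SEED * 1000 + i,
            deployment_id=f"{ind}-BR",
            individual_id=ind,
            sex=sex,
            start="2018-04-01",
            composer=composer,
        )
        nb = simulate_deployment(
            TrueSelection(beta=beta, home_center=tuple(nb_center), home_radius=radius),
            landscape,
            weeks=WEEKS_NON_BREEDING,
            seed=SEED * 1000 + 500 + i,
            deployment_id=f"{ind}-NB",
            individual_id=ind,
            sex=sex,
            start="2018-10-01",
            contamination=ContaminationConfig(),
            composer=composer,
        )
        frames.extend([br, nb])
        truth_out[ind] = {
            "sex": sex,
            "beta": beta,
            "nest_box": list(map(float, nest)),
            "non_breeding_center": list(map(float, nb_center)),
            "home_radius_m": radius,
        }

    fixes = pd.concat(frames, ignore_index=True)
    fixes = fixes.sort_values(["deployment_id", "timestamp"], kind="stable")
    fixes.to_csv(SCRATCH / "fixes.csv", index=False)
    print(f"fixes: {len(fixes)} from {fixes['deployment_id'].nunique()} deployments "
          f"({N_INDIVIDUALS} individuals)")

    (RESULTS / "simulation_truth.json").write_text(json.dumps(truth_out, indent=2))


if __name__ == "__main__":
    main()
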