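"""Fit the three resource-selection models and report selection strengths.

Model 1 (habitat): dominant focal-area category (crop rotation reference),
biodiversity-structure presence, structural richness, sex; also refitted
with habitat x biodiversity interactions.  Model 2 (density): vole and
small-mammal activity density per focal area with biodiversity
interactions.  Model 3 (total prey): combined z-scored prey activity per
habitat stratum.  Each model is fitted once over all deployments (weight
5000 on available locations) and again as a two-stage population fit
(per-deployment estimates pooled with a between-deployment variance).
"""

import warnings

import pandas as pd

from common import RESULTS, SCRATCH

from owlrsf import rsf


def main():
    warnings.filterwarnings("ignore")
    table = pd.read_csv(SCRATCH / "focal_table.csv")

    for model, interactions in (
        ("habitat", False),
        ("habitat", True),
        ("density", True),
        ("total_prey", None),
    ):
        design = rsf.build_design(table, model, interactions=interactions)
        fit = rsf.fit_weighted_logistic(design=design)
        report = rsf.rss(fit, n_draws=1000, seed=5).table

        per_dep = rsf.fit_per_deployment(design)
        pooled = rsf.fit_population(per_dep)
        pooled_rss = rsf.rss(pooled, n_draws=1000, seed=6).table
        report = report.merge(
            pooled_rss[["term", "beta", "rss"]].rename(
                columns={"beta": "beta_pooled", "rss": "rss_pooled"}
            ),
            on="term",
            how="left",
        )
        report["between_variance"] = report["term"].map(pooled.between_variance)

        tag = f"{model}{'_interactions' if interactions else ''}"
        report.to_csv(RESULTS / f"rsf_{tag}.csv", index=False)
        print(f"\n=== {tag} model ({fit.n_used} used / {fit.n_available} available, "
              f"{pooled.n_deployments} deployments pooled) ===")
        cols = ["term", "beta", "rss", "rss_lo", "rss_hi", "meaningful",
                "beta_pooled", "between_variance"]
        print(report[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
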