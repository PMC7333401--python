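"""Relate community distances to genetics, geography and climate.

Collapses the sample-level Bray-Curtis matrix to population means, then
runs the Spearman Mantel battery (community distance vs Fst, |dlat|,
|dlon|, |dBio1|, |dBio12|) for both Bray-Curtis and KL responses, and a
recursive path model (geography/climate -> Fst -> community distance)
with R-squared per endogenous variable.
"""

from pathlib import Path

import pandas as pd

import wolbiome as w
from wolbiome.beta import read_distance_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 20240905
COVARIATES = ["latitude", "longitude", "bio1", "bio12"]


def main() -> None:
    meta = w.read_metadata(SCRATCH / "survey_data" / "metadata.tsv")
    bc = read_distance_matrix(SCRATCH / "bray_curtis.tsv")
    kl = read_distance_matrix(BASE / "kl_divergence.tsv")
    groups = meta.loc[list(bc.ids), "population"]
    bc_pop = w.collapse_to_groups(bc, groups)
    pops = list(bc_pop.ids)
    fst = read_distance_matrix(SCRATCH / "survey_data" / "fst.tsv").filter(pops)
    pop_meta = meta.groupby("population")[COVARIATES].first().loc[pops]

    predictors = {"fst": fst, **{c: w.covariate_distance(pop_meta, c)
                                 for c in COVARIATES}}
    rows = []
    for resp_name, resp in (("bray_curtis", bc_pop), ("kl", kl.filter(pops))):
        for name, pred in predictors.items():
            res = w.mantel(resp, pred, n_perm=1000, seed=SEED)
            rows.append({"response": resp_name, "predictor": name,
                         "r": res.r, "p": res.p})
    mant = pd.DataFrame(rows)
    mant.to_csv(BASE / "mantel.tsv", sep="\t", index=False)
    print(mant.to_string(index=False))

    edges = [(c, "fst") for c in COVARIATES] + \
            [(c, "community") for c in COVARIATES] + [("fst", "community")]
    variables = {**{c: predictors[c] for c in COVARIATES},
                 "fst": fst, "community": bc_pop}
    pm = w.path_model(variables, edges, permutations=999, seed=SEED)
    pm.to_frame().to_csv(BASE / "path_model.tsv", sep="\t", index=False)
    print("\npath model (unstandardized slopes, permutation p):")
    print(pm.to_frame().to_string(index=False))
    for target, r2 in pm.r2.items():
        print(f"R2[{target}] = {r2:.3f}")


if __name__ == "__main__":
    main()
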