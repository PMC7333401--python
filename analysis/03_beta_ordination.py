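"""Bray-Curtis beta diversity, ordination and PERMANOVA across
populations with the symbiont fixed (the polymorphic population is held
out, as mixing infected and uninfected individuals would confound the
geography signal).

Writes the distance matrix, 2-axis principal coordinates and the
PERMANOVA summary.
"""

from pathlib import Path

import pandas as pd

import wolbiome as w
from wolbiome.beta import write_distance_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 20240903


def main() -> None:
    table = w.read_otu_table(SCRATCH / "survey_data" / "otu_table_rarefied.tsv",
                             SCRATCH / "survey_data" / "taxonomy.tsv")
    meta = w.read_metadata(SCRATCH / "survey_data" / "metadata.tsv")
    fixed = meta.groupby("population")["infected"].all()
    keep = meta["infected"] & meta["population"].map(fixed)
    sub = w.OtuTable(table.counts.loc[keep], table.taxonomy)
    groups = meta.loc[keep, "population"]
    print(f"{sub.n_samples} samples from {groups.nunique()} fixed-infection "
          f"populations")

    bc = w.bray_curtis(sub)
    write_distance_matrix(bc, SCRATCH / "bray_curtis.tsv")

    ordination = w.pcoa(bc, n_axes=2)
    ordination.coordinates.to_csv(BASE / "pcoa.tsv", sep="\t",
                                  index_label="sample_id")
    print("PCoA axes explain "
          + " + ".join(f"{p:.1%}" for p in ordination.proportion_explained)
          + f"; negative eigenvalue mass {ordination.negative_eigenvalue_mass:.3f}")

    res = w.permanova(bc, groups, n_perm=999, seed=SEED)
    pd.DataFrame([{"pseudo_f": res.pseudo_f, "r2": res.r2, "p": res.p,
                   "n_perm": res.n_perm}]).to_csv(
        BASE / "permanova.tsv", sep="\t", index=False)
    print(f"PERMANOVA by population: R2 = {res.r2:.3f}, p = {res.p:.3g} "
          f"({res.n_perm} permutations)")


if __name__ == "__main__":
    main()
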