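"""End-to-end orchestration: simulate or load tables, rarefy, run the
alpha/beta/power-law/KL/Mantel/path-model/group-comparison stages, and
write every stage's outputs plus a run manifest.

The manifest (JSON) records inputs, parameters, seeds and the SHA-256 of
every output file, so a run is auditable and a rerun with the same
config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, beta, compare, diversity, otu, powerlaw, simulate

log = logging.getLogger("wolbiome")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Either a simulation block or input paths, plus stage toggles.

    ``simulation`` holds keyword overrides for
    :class:`~wolbiome.simulate.CommunitySimSpec` /
    :class:`~wolbiome.simulate.MetadataSimSpec`; ``inputs`` holds paths
    (counts, taxonomy, metadata, fst).  Exactly one must be given.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None
    rarefaction: str | int = "min-depth"
    symbiont_taxon: str = simulate.SYMBIONT_GENUS
    others_threshold: float = 0.05
    kl_bins: int = 32
    n_perm: int = 999
    stages: list[str] = field(
        default_factory=lambda: [
            "alpha", "beta", "powerlaw", "kl", "mantel", "pathmodel", "groups"
        ]
    )

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation/inputs must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", **kw)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return the manifest dict (also written
    to ``<out_dir>/manifest.json``).  A stage failure aborts with the
    stage named; outputs of completed stages are preserved."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: list[Path] = []
    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "stages_completed": [],
        "outputs": {},
    }
    stage = "load"
    try:
        # ----- data ------------------------------------------------------
        if config.simulation is not None:
            sim_kw = dict(config.simulation)
            meta_kw = {
                k: sim_kw.pop(k)
                for k in list(sim_kw)
                if k in MetadataSimSpecFields
            }
            cspec = simulate.CommunitySimSpec(seed=config.seed, **sim_kw)
            table, sample_meta = simulate.simulate_otu_table(cspec)
            mspec = simulate.MetadataSimSpec(seed=config.seed + 1, **meta_kw)
            populations = list(pd.unique(sample_meta["population"]))
            pop_meta, fst = simulate.simulate_metadata(mspec, populations)
            sample_meta = sample_meta.join(pop_meta, on="population")
            outputs.append(_write(table.counts, out / "otu_table.tsv",
                                  index_label="sample_id"))
            outputs.append(_write(table.taxonomy.rename("lineage").to_frame(),
                                  out / "taxonomy.tsv", index_label="otu_id"))
            outputs.append(_write(sample_meta, out / "metadata.tsv"))
            beta.write_distance_matrix(fst, out / "fst.tsv")
            outputs.append(out / "fst.tsv")
        else:
            paths = config.inputs
            table = otu.read_otu_table(paths["counts"], paths.get("taxonomy"))
            sample_meta = otu.read_metadata(paths["metadata"])
            otu.validate_metadata(table, sample_meta)
            fst = (
                beta.read_distance_matrix(paths["fst"])
                if "fst" in paths else None
            )
        log.info("loaded %d samples x %d OTUs", table.n_samples, table.n_otus)

        # ----- rarefaction ------------------------------------------------
        stage = "rarefy"
        depth = (
            otu.min_depth(table)
            if config.rarefaction == "min-depth" else int(config.rarefaction)
        )
        table = otu.rarefy(table, depth, seed=config.seed + 10)
        manifest["rarefaction_depth"] = depth

        genus_table = otu.aggregate_to_genus(table)
        groups = sample_meta["population"] if "population" in sample_meta else None
        rel = otu.relative_abundance(
            genus_table, others_threshold=config.others_threshold, groups=groups
        )
        outputs.append(_write(rel, out / "genus_relative_abundance.tsv",
                              index_label="sample_id"))

        symbiont_prop = (
            genus_table.counts[config.symbiont_taxon] / depth
            if config.symbiont_taxon in genus_table.counts else None
        )

        # ----- stages -----------------------------------------------------
        if "alpha" in config.stages:
            stage = "alpha"
            alpha = diversity.alpha_diversity_table(table)
            outputs.append(_write(alpha, out / "alpha_diversity.tsv"))
            manifest["stages_completed"].append(stage)

        bc = None
        if "beta" in config.stages:
            stage = "beta"
            bc = beta.bray_curtis(table)
            beta.write_distance_matrix(bc, out / "bray_curtis.tsv")
            outputs.append(out / "bray_curtis.tsv")
            ordination = beta.pcoa(bc, n_axes=2)
            outputs.append(_write(ordination.coordinates, out / "pcoa.tsv",
                                  index_label="sample_id"))
            if groups is not None and groups.nunique() > 1:
                pr = beta.permanova(bc, groups, n_perm=config.n_perm,
                                    seed=config.seed + 20)
                manifest["permanova"] = {
                    "pseudo_f": pr.pseudo_f, "r2": pr.r2, "p": pr.p
                }
            manifest["stages_completed"].append(stage)

        if "powerlaw" in config.stages and groups is not None:
            stage = "powerlaw"
            rows = []
            for pop, sub in table.counts.groupby(groups):
                ab = sub.to_numpy().ravel()
                fit = powerlaw.fit_powerlaw(ab[ab > 0])
                rows.append({"population": pop, "x_prime": fit.x_prime,
                             "epsilon": fit.epsilon, "n_tail": fit.n_tail,
                             "ks_stat": fit.ks_stat,
                             "moment_class": fit.moment_class})
                curve = powerlaw.exceedance_curve(ab[ab > 0], fit)
                outputs.append(_write(curve.to_frame(),
                                      out / f"exceedance_{pop}.tsv", index=False))
            outputs.append(_write(pd.DataFrame(rows).set_index("population"),
                                  out / "powerlaw_fits.tsv"))
            manifest["stages_completed"].append(stage)

        kl = None
        if "kl" in config.stages and groups is not None and groups.nunique() > 1:
            stage = "kl"
            kl = powerlaw.kl_matrix(table, groups, bins=config.kl_bins)
            beta.write_distance_matrix(kl, out / "kl_divergence.tsv")
            outputs.append(out / "kl_divergence.tsv")
            manifest["stages_completed"].append(stage)

        pop_meta_cols = ["latitude", "longitude", "bio1", "bio12"]
        have_geo = all(c in sample_meta.columns for c in pop_meta_cols)
        if have_geo and groups is not None:
            pop_table = sample_meta.groupby(groups)[pop_meta_cols].first()
        if "mantel" in config.stages and bc is not None and have_geo and fst is not None:
            stage = "mantel"
            bc_pop = beta.collapse_to_groups(bc, groups)
            predictors = {
                "fst": fst,
                **{c: association.covariate_distance(pop_table, c)
                   for c in pop_meta_cols},
            }
            rows = []
            for resp_name, resp in (("bray_curtis", bc_pop), ("kl", kl)):
                if resp is None:
                    continue
                for name, pred in predictors.items():
                    res = association.mantel(resp, pred, n_perm=config.n_perm,
                                             seed=config.seed + 30)
                    rows.append({"response": resp_name, "predictor": name,
                                 "r": res.r, "p": res.p})
            outputs.append(_write(pd.DataFrame(rows), out / "mantel.tsv",
                                  index=False))
            manifest["stages_completed"].append(stage)

        if "pathmodel" in config.stages and bc is not None and have_geo and fst is not None:
            stage = "pathmodel"
            bc_pop = beta.collapse_to_groups(bc, groups)
            variables = {
                "latitude": association.covariate_distance(pop_table, "latitude"),
                "longitude": association.covariate_distance(pop_table, "longitude"),
                "bio1": association.covariate_distance(pop_table, "bio1"),
                "bio12": association.covariate_distance(pop_table, "bio12"),
                "fst": fst,
                "community": bc_pop,
            }
            edges = [
                ("latitude", "fst"), ("longitude", "fst"),
                ("bio1", "fst"), ("bio12", "fst"),
                ("latitude", "community"), ("longitude", "community"),
                ("bio1", "community"), ("bio12", "community"),
                ("fst", "community"),
            ]
            pm = association.path_model(variables, edges)
            outputs.append(_write(pm.to_frame(), out / "path_model.tsv",
                                  index=False))
            manifest["path_model_r2"] = pm.r2
            manifest["stages_completed"].append(stage)

        if "groups" in config.stages and "infected" in sample_meta.columns:
            stage = "groups"
            infected = sample_meta["infected"].astype(bool)
            if infected.nunique() == 2 and infected.value_counts().min() >= 2:
                alpha = diversity.alpha_diversity_table(table)
                rows = []
                for col in alpha.columns:
                    res = compare.welch_t(
                        alpha.loc[infected, col], alpha.loc[~infected, col],
                        unit=col,
                    )
                    rows.append({"index": col, "t": res.statistic, "p": res.p,
                                 "stars": res.stars})
                outputs.append(_write(pd.DataFrame(rows),
                                      out / "alpha_welch.tsv", index=False))
                genus_cmp = compare.per_genus_comparison(
                    genus_table, infected.map({True: "w+", False: "w-"})
                )
                outputs.append(_write(genus_cmp, out / "per_genus.tsv"))
            if symbiont_prop is not None and symbiont_prop.nunique() > 1:
                alpha = diversity.alpha_diversity_table(table)
                corr = compare.diversity_vs_proportion(
                    alpha[["shannon", "simpson"]], symbiont_prop
                )
                outputs.append(_write(corr, out / "diversity_vs_symbiont.tsv",
                                      index_label="index"))
            manifest["stages_completed"].append(stage)
    except Exception as exc:
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.removeHandler(handler)
    return manifest


MetadataSimSpecFields = {
    "latitude_range", "longitude_range", "bio1_range", "bio12_range",
    "fst_distance_decay", "fst_noise_sd",
}
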