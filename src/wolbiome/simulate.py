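"""Synthetic OTU tables, metadata and Fst matrices with the statistical
structure of a symbiont-swept planthopper microbiome survey.

The generator emulates the features the downstream analyses assume:

* one dominant maternally inherited symbiont genus ("Wolbachia") whose
  per-sample read proportion is beta-distributed around a per-population
  mean (zero in uninfected individuals);
* a heavy-tailed residual community: per population, residual relative
  abundances are Pareto draws (tail exponent epsilon), tilted along a
  latitude-like gradient axis so that nearby populations host similar
  communities;
* read counts drawn multinomially at a fixed sequencing depth;
* geographic/climatic covariates and a latitude-decay pairwise Fst
  matrix, mirroring mitochondrial differentiation accumulating along the
  sampling transect.

All randomness flows from a single explicitly seeded generator: the same
spec and seed reproduce the same tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .otu import OtuTable

__all__ = [
    "CommunitySimSpec",
    "MetadataSimSpec",
    "simulate_otu_table",
    "simulate_metadata",
    "simulate_dominance_gradient",
    "study_conditions",
    "SYMBIONT_GENUS",
]

SYMBIONT_GENUS = "Wolbachia"
SYMBIONT_LINEAGE = (
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;"
    "Anaplasmataceae;Wolbachia"
)


def _per_population(value, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if arr.shape != (n,):
        raise ValueError(f"{name} must be scalar or length {n}")
    return arr


@dataclass
class CommunitySimSpec:
    """Parameters of the community generator.

    Defaults are the survey conditions: 17 populations of 3 individuals
    sequenced to 34135 reads over 314 taxa; 13 low-latitude populations
    with a symbiont read share of 0.879 and 3 high-latitude ones at
    0.664, plus one polymorphic population (infection rate 0.5, mean
    0.664); residual tail exponent 2.5 (finite mean, infinite variance).
    """

    n_populations: int = 17
    samples_per_population: int = 3
    depth: int = 34135
    n_taxa: int = 314
    symbiont_mean_prop: float | np.ndarray = field(
        default_factory=lambda: np.r_[np.full(13, 0.879), np.full(4, 0.664)]
    )
    symbiont_prop_dispersion: float = 30.0
    tail_exponent: float = 2.5
    infection_rate: float | np.ndarray = field(
        default_factory=lambda: np.r_[np.full(16, 1.0), 0.5]
    )
    community_gradient_effect: float = 2.0
    community_noise_sd: float = 0.6
    otus_per_genus: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be at least 2")
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        if self.tail_exponent <= 1:
            raise ValueError("tail_exponent must exceed 1")
        if self.symbiont_prop_dispersion <= 0:
            raise ValueError("symbiont_prop_dispersion must be positive")
        self.symbiont_mean_prop = _per_population(
            self.symbiont_mean_prop, self.n_populations, "symbiont_mean_prop"
        )
        if ((self.symbiont_mean_prop < 0) | (self.symbiont_mean_prop > 1)).any():
            raise ValueError("symbiont_mean_prop must lie in [0, 1]")
        self.infection_rate = _per_population(
            self.infection_rate, self.n_populations, "infection_rate"
        )
        if ((self.infection_rate < 0) | (self.infection_rate > 1)).any():
            raise ValueError("infection_rate must lie in [0, 1]")


def _taxonomy(n_taxa: int, otus_per_genus: int) -> pd.Series:
    otu_ids = [f"OTU{i+1:04d}" for i in range(n_taxa)]
    lineages = [SYMBIONT_LINEAGE]
    for i in range(1, n_taxa):
        genus = f"Genus{(i - 1) // otus_per_genus + 1:04d}"
        lineages.append(f"Bacteria;Unresolved;{genus}")
    return pd.Series(lineages, index=otu_ids)


def _beta_draw(rng: np.random.Generator, mean: float, concentration: float) -> float:
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


def simulate_otu_table(spec: CommunitySimSpec) -> tuple[OtuTable, pd.DataFrame]:
    """Draw an OTU table and per-sample metadata from the spec.

    Per population, residual relative abundances are Pareto(epsilon - 1)
    draws tilted multiplicatively along a fixed random direction scaled
    by the population's position on a 0..1 gradient (a latitude
    stand-in) plus log-normal noise, then renormalized.  Per sample, the
    symbiont proportion is a beta draw around the population mean (zero
    for uninfected individuals) and counts are one multinomial draw of
    ``depth`` reads.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_taxa - 1
    taxonomy = _taxonomy(spec.n_taxa, spec.otus_per_genus)
    otu_ids = list(taxonomy.index)

    base_log = np.log(rng.pareto(spec.tail_exponent - 1.0, size=n_res) + 1.0)
    direction = rng.standard_normal(n_res)
    gradient = (
        np.linspace(0.0, 1.0, spec.n_populations)
        if spec.n_populations > 1 else np.zeros(1)
    )

    rows, meta = [], []
    for p in range(spec.n_populations):
        pop = f"P{p+1:02d}"
        tilt = spec.community_gradient_effect * gradient[p] * direction
        noise = spec.community_noise_sd * rng.standard_normal(n_res)
        res_rel = np.exp(base_log + tilt + noise)
        res_rel /= res_rel.sum()
        for s in range(spec.samples_per_population):
            sample_id = f"{pop}S{s+1}"
            infected = bool(rng.random() < spec.infection_rate[p])
            prop = (
                _beta_draw(rng, spec.symbiont_mean_prop[p],
                           spec.symbiont_prop_dispersion)
                if infected else 0.0
            )
            probs = np.concatenate([[prop], (1.0 - prop) * res_rel])
            rows.append(rng.multinomial(spec.depth, probs))
            meta.append(
                {"sample_id": sample_id, "population": pop,
                 "infected": infected, "symbiont_prop_true": prop,
                 "symbiont_taxon": SYMBIONT_GENUS}
            )
    counts = pd.DataFrame(
        np.array(rows), index=[m["sample_id"] for m in meta], columns=otu_ids
    )
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return OtuTable(counts, taxonomy), metadata


@dataclass
class MetadataSimSpec:
    """Geography, climate and a latitude-decay Fst matrix.

    Ranges cover the East-Asian sampling transect; climate follows
    latitude (temperature falls, precipitation falls) with noise, then
    is clipped into range.  Fst(i,j) = clip(decay * |lat_i - lat_j| +
    noise, [0, 1)), symmetrized with a zero diagonal.
    """

    latitude_range: tuple[float, float] = (19.0, 43.0)
    longitude_range: tuple[float, float] = (109.0, 141.0)
    bio1_range: tuple[float, float] = (4.0, 25.0)
    bio12_range: tuple[float, float] = (600.0, 2400.0)
    fst_distance_decay: float = 0.02
    fst_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fst_noise_sd < 0:
            raise ValueError("fst_noise_sd must be nonnegative")


def simulate_metadata(
    spec: MetadataSimSpec, populations: list[str]
) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Per-population coordinates, Bio1/Bio12 and the Fst matrix.

    Latitudes are sorted ascending over the population order, so the
    first population is southernmost — matching the community
    generator's gradient axis.
    """
    k = len(populations)
    if k < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(spec.seed)
    lat = np.sort(rng.uniform(*spec.latitude_range, size=k))
    lon = rng.uniform(*spec.longitude_range, size=k)

    def climate(rng, lat, lo, hi, decreasing):
        span = hi - lo
        frac = (lat - spec.latitude_range[0]) / (
            spec.latitude_range[1] - spec.latitude_range[0]
        )
        base = hi - span * frac if decreasing else lo + span * frac
        return np.clip(base + rng.normal(0.0, 0.08 * span, size=len(lat)), lo, hi)

    bio1 = climate(rng, lat, *spec.bio1_range, decreasing=True)
    bio12 = climate(rng, lat, *spec.bio12_range, decreasing=True)

    fst = spec.fst_distance_decay * np.abs(lat[:, None] - lat[None, :])
    noise = rng.normal(0.0, spec.fst_noise_sd, size=(k, k))
    fst = fst + (noise + noise.T) / 2.0
    fst = np.clip((fst + fst.T) / 2.0, 0.0, np.nextafter(1.0, 0.0))
    np.fill_diagonal(fst, 0.0)

    metadata = pd.DataFrame(
        {"latitude": lat, "longitude": lon, "bio1": bio1, "bio12": bio12},
        index=pd.Index(populations, name="population"),
    )
    return metadata, DistanceMatrix(fst, ids=list(populations))


def simulate_dominance_gradient(
    n_samples: int = 60,
    max_prop: float = 0.95,
    depth: int = 34135,
    n_taxa: int = 314,
    tail_exponent: float = 2.5,
    seed: int = 0,
) -> tuple[OtuTable, pd.DataFrame]:
    """Samples whose symbiont proportion sweeps 0..max_prop linearly over
    a shared residual community — the design for the diversity-collapse
    correlation (symbiont load vs Shannon/Simpson)."""
    rng = np.random.default_rng(seed)
    taxonomy = _taxonomy(n_taxa, 2)
    res_rel = rng.pareto(tail_exponent - 1.0, size=n_taxa - 1) + 1.0
    res_rel /= res_rel.sum()
    props = np.linspace(0.0, max_prop, n_samples)
    rows = []
    for prop in props:
        probs = np.concatenate([[prop], (1.0 - prop) * res_rel])
        rows.append(rng.multinomial(depth, probs))
    ids = [f"G{i+1:03d}" for i in range(n_samples)]
    counts = pd.DataFrame(np.array(rows), index=ids, columns=list(taxonomy.index))
    metadata = pd.DataFrame(
        {"symbiont_prop_true": props, "infected": props > 0},
        index=pd.Index(ids, name="sample_id"),
    )
    return OtuTable(counts, taxonomy), metadata


def study_conditions(seed: int = 0) -> tuple[CommunitySimSpec, MetadataSimSpec]:
    """The default survey scenario (spec/metadata pair sharing a seed)."""
    return CommunitySimSpec(seed=seed), MetadataSimSpec(seed=seed + 1)
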