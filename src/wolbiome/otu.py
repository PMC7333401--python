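"""OTU count tables: validation, I/O, rarefaction and taxon operations.

The central object is :class:`OtuTable`, an integer count matrix with
samples in rows and OTUs in columns plus a semicolon-delimited taxonomic
lineage per OTU (the last rank is read as the genus).  All depth
normalization is subsampling without replacement (multivariate
hypergeometric), drawn once from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNCLASSIFIED = "unclassified"

__all__ = [
    "OtuTable",
    "read_otu_table",
    "read_metadata",
    "validate_metadata",
    "min_depth",
    "rarefy",
    "aggregate_to_genus",
    "relative_abundance",
    "exclude_taxon_and_rarefy",
]


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with per-OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers; index = sample ids,
        columns = OTU ids.
    taxonomy
        Series mapping OTU id -> semicolon-delimited lineage whose last
        field is the genus.  OTUs missing from the map get
        ``"unclassified"``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.taxonomy is None:
            self.taxonomy = pd.Series(UNCLASSIFIED, index=self.counts.columns)
        else:
            self.taxonomy = pd.Series(self.taxonomy).reindex(
                self.counts.columns, fill_value=UNCLASSIFIED
            )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def genera(self) -> pd.Series:
        """Genus per OTU: last semicolon-delimited lineage field."""
        return self.taxonomy.str.split(";").str[-1].str.strip()

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, counts_path, taxonomy_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
        if taxonomy_path is not None:
            self.taxonomy.rename("lineage").to_csv(
                taxonomy_path, sep="\t", index_label="otu_id"
            )


def read_otu_table(counts_path, taxonomy_path=None, transposed: bool = False) -> OtuTable:
    """Read a TSV OTU table (samples in rows; ``transposed=True`` for the
    OTUs-in-rows dialect) and optional taxonomy TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if transposed:
        counts = counts.T
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy = tax.iloc[:, 0]
    return OtuTable(counts, taxonomy)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def validate_metadata(table: OtuTable, metadata: pd.DataFrame) -> None:
    """Every sample in the table must have a metadata row."""
    missing = table.sample_ids.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {list(missing)}")


def min_depth(table: OtuTable) -> int:
    """Lowest per-sample read total — the conventional rarefaction depth."""
    if table.n_samples == 0:
        raise ValueError("empty table")
    return int(table.sample_sums().min())


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample, fully
    determined by ``seed``.  Raises if any sample is shallower than
    ``depth``, naming the offending sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_sums()
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(
            f"sample(s) shallower than depth {depth}: "
            + ", ".join(f"{s} ({t})" for s, t in shallow.items())
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.sample_ids, columns=table.otu_ids)
    return OtuTable(counts, table.taxonomy)


def aggregate_to_genus(table: OtuTable) -> OtuTable:
    """Sum counts over OTUs sharing a genus; total reads are conserved."""
    genera = table.genera()
    agg = table.counts.T.groupby(genera, sort=False).sum().T
    taxonomy = pd.Series(agg.columns, index=agg.columns)
    return OtuTable(agg, taxonomy)


def relative_abundance(
    table: OtuTable,
    others_threshold: float = 0.0,
    groups: pd.Series | None = None,
    others_label: str = "others",
) -> pd.DataFrame:
    """Row-normalized proportions with optional pooling of minor taxa.

    A taxon is pooled into ``others_label`` when its maximum proportion
    across the displayed groups falls below ``others_threshold``.  By
    default each display group is the mean profile of a ``groups`` level;
    with ``groups=None`` the per-sample proportions are screened instead.
    """
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    props = table.counts.div(sums, axis=0)
    if others_threshold <= 0:
        return props
    if groups is not None:
        display = props.groupby(groups.reindex(props.index)).mean()
    else:
        display = props
    minor = display.max(axis=0) < others_threshold
    if not minor.any():
        return props
    pooled = props.loc[:, ~minor].copy()
    pooled[others_label] = props.loc[:, minor].sum(axis=1)
    return pooled


def exclude_taxon_and_rarefy(table: OtuTable, taxon: str, seed: int) -> OtuTable:
    """Drop every OTU of a genus, then re-rarefy to the new minimum depth.

    This is the focal-symbiont exclusion step: removing the dominant
    maternally inherited taxon and renormalizing the residual community
    to the shallowest residual sample.  A sample left with zero residual
    reads is an error.
    """
    genera = table.genera()
    keep = genera[genera != taxon].index
    residual = OtuTable(table.counts[keep], table.taxonomy.loc[keep])
    totals = residual.sample_sums()
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(
            f"sample(s) with zero residual reads after removing {taxon!r}: "
            f"{list(empty.index)}"
        )
    return rarefy(residual, min_depth(residual), seed)
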