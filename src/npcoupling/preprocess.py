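"""ASV-table preprocessing: abundance floor, averaged rarefaction, retention
filters, taxonomic aggregation, and major-taxon selection.

The pipeline order is fixed: global floor -> rarefy_average -> prevalence /
total-count retention -> aggregate -> select_major. All filters are
idempotent. Relative abundances are computed within each marker group
separately, since the three amplicon assays are separate sequencing universes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .exceptions import ConfigError, ValidationError
from .tableio import CountTable, TaxonomyMap

logger = logging.getLogger("npcoupling")


@dataclass
class PreprocessParams:
    """Filtering and rarefaction settings.

    global_floor
        Features whose share of the grand total is strictly below this are
        dropped (default 1e-5, i.e. 0.001% of all reads).
    rarefy_fraction, rarefy_reps
        Rarefaction depth is ``floor(fraction x min site depth)``; the table
        is averaged over ``reps`` independent subsamples.
    prevalence_min
        Minimum fraction of sites a 16S/phoD feature must occur in.
    min_total_count
        Minimum summed count for ITS features (fungal retention rule).
    major_abund
        A taxon is "major" when its mean relative abundance across sites is
        strictly above this (default 0.001, i.e. 0.1%).
    """

    global_floor: float = 1e-5
    rarefy_fraction: float = 0.9
    rarefy_reps: int = 100
    prevalence_min: float = 0.10
    min_total_count: int = 10
    major_abund: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        for name in ("global_floor", "rarefy_fraction", "prevalence_min", "major_abund"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.rarefy_reps < 1:
            raise ConfigError("rarefy_reps must be >= 1")


def filter_global_floor(table: CountTable, floor: float = 1e-5) -> CountTable:
    """Drop features comprising strictly less than ``floor`` of all reads.

    A feature sitting exactly at the floor is retained.
    """
    grand = int(table.data.to_numpy().sum())
    if grand == 0:
        raise ValidationError("cannot apply abundance floor: grand total is 0")
    share = table.data.sum(axis=0) / grand
    keep = share >= floor
    return CountTable(table.data.loc[:, keep], table.marker_group, raw=table.raw)


def rarefy_average(
    table: CountTable, fraction: float = 0.9, reps: int = 100, seed: int = 0
) -> CountTable:
    """Average ``reps`` even subsamples at ``floor(fraction x min depth)`` reads.

    Each repetition draws, for every site, a fixed number of reads without
    replacement (multivariate hypergeometric), so every site's row sum equals
    the target depth exactly in every repetition and hence in the average.
    The seed is split per repetition, making the result reproducible and
    independent of repetition order.
    """
    if not table.raw:
        raise ValidationError("rarefy_average expects a raw integer table")
    depths = table.depths().to_numpy()
    if (depths < 1).any():
        bad = table.sites[depths < 1][0]
        raise ValidationError(f"site {bad!r} has zero total count")
    target = int(math.floor(fraction * depths.min()))
    if target == 0:
        raise ValidationError("rarefaction depth is 0; increase fraction or depths")
    counts = table.data.to_numpy()
    acc = np.zeros_like(counts, dtype=float)
    for rep in range(reps):
        rng = default_rng(SeedSequence(seed, spawn_key=(rep,)))
        for i in range(counts.shape[0]):
            acc[i] += rng.multivariate_hypergeometric(counts[i], target)
    acc /= reps
    return CountTable(
        pd.DataFrame(acc, index=table.sites, columns=table.features),
        table.marker_group,
        raw=False,
    )


def filter_prevalence(
    table: CountTable, prevalence_min: float = 0.10, min_total_count: int = 10
) -> CountTable:
    """Apply the per-assay retention rule.

    16S and phoD features must occur (abundance > 0) in at least
    ``ceil(prevalence_min x n_sites)`` sites; ITS features must have a summed
    count of at least ``min_total_count``.
    """
    if table.marker_group in ("16S", "phoD"):
        need = math.ceil(prevalence_min * table.n_sites)
        keep = (table.data > 0).sum(axis=0) >= need
    elif table.marker_group == "ITS":
        keep = table.data.sum(axis=0) >= min_total_count
    else:  # pragma: no cover - CountTable already validates the group
        raise ConfigError(f"unknown marker group {table.marker_group!r}")
    return CountTable(table.data.loc[:, keep], table.marker_group, raw=table.raw)


@dataclass
class AggregatedTable:
    """Sites x taxa relative abundances at one rank for one or more groups."""

    data: pd.DataFrame
    rank: str
    group_of: pd.Series  # taxon -> marker group

    def __post_init__(self) -> None:
        missing = self.data.columns.difference(self.group_of.index)
        if len(missing):
            raise ValidationError(f"taxa without marker-group provenance: {list(missing)}")
        self.group_of = self.group_of.loc[self.data.columns]

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    @property
    def mean_abundance(self) -> pd.Series:
        return self.data.mean(axis=0)

    @property
    def occurrence(self) -> pd.Series:
        """Number of sites where a taxon is present (abundance > 0)."""
        return (self.data > 0).sum(axis=0)


def aggregate(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> AggregatedTable:
    """Sum features into taxa at ``rank`` and convert to relative abundance.

    Placeholder lineages (``unclassified_<parent>``) aggregate under their
    placeholder name. Relative abundance is computed within the marker group,
    so each site's row sums to 1.
    """
    labels = taxonomy.labels_at(table.features, rank)
    summed = table.data.T.groupby(labels).sum().T
    totals = summed.sum(axis=1)
    if (totals <= 0).any():
        bad = summed.index[totals <= 0][0]
        raise ValidationError(f"site {bad!r} has zero total abundance at rank {rank!r}")
    rel = summed.div(totals, axis=0)
    group_of = pd.Series(table.marker_group, index=rel.columns)
    return AggregatedTable(rel, rank=rank, group_of=group_of)


def select_major(agg: AggregatedTable, major_abund: float = 0.001) -> AggregatedTable:
    """Keep taxa whose mean relative abundance is strictly above the cutoff."""
    keep = agg.mean_abundance > major_abund
    return AggregatedTable(agg.data.loc[:, keep], agg.rank, agg.group_of.loc[keep[keep].index])


def merge_groups(tables: list[AggregatedTable]) -> AggregatedTable:
    """Join per-group aggregated tables over shared sites for pooled analyses.

    Taxon names are prefixed ``<group>|`` so identical genus names from
    different assays never collide.
    """
    if not tables:
        raise ValidationError("no tables to merge")
    ranks = {t.rank for t in tables}
    if len(ranks) != 1:
        raise ValidationError(f"cannot merge tables at mixed ranks: {sorted(ranks)}")
    frames, groups = [], []
    for t in tables:
        renamed = t.data.rename(
            columns={c: f"{t.group_of[c]}|{c}" for c in t.data.columns}
        )
        frames.append(renamed)
        groups.append(
            pd.Series(t.group_of.to_numpy(), index=renamed.columns)
        )
    merged = pd.concat(frames, axis=1)
    if merged.isna().to_numpy().any():
        raise ValidationError("site sets differ between marker groups")
    return AggregatedTable(merged, rank=ranks.pop(), group_of=pd.concat(groups))


def preprocess_table(
    table: CountTable, taxonomy: TaxonomyMap, rank: str, params: PreprocessParams
) -> AggregatedTable:
    """Run the fixed preprocessing chain for one marker group at one rank."""
    params.validate()
    group = table.marker_group
    t = filter_global_floor(table, params.global_floor)
    logger.info("%s: %d/%d features survive the global floor", group, t.n_features, table.n_features)
    t = rarefy_average(t, params.rarefy_fraction, params.rarefy_reps, params.seed)
    kept = filter_prevalence(t, params.prevalence_min, params.min_total_count)
    logger.info("%s: %d/%d features survive retention", group, kept.n_features, t.n_features)
    agg = aggregate(kept, taxonomy, rank)
    major = select_major(agg, params.major_abund)
    logger.info("%s %s: %d/%d taxa are major", group, rank, len(major.taxa), len(agg.taxa))
    return major
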