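"""Tabular containers and strict readers/writers.

On-disk orientation for count tables follows the common amplicon convention:
features (ASVs/OTUs or aggregated taxa) in rows, sites in columns, tab-delimited
UTF-8 with one header row. In memory everything is sites x features, which is
the natural orientation for per-site statistics.

Readers reject malformed input instead of coercing it; every writer/reader
pair is an inverse on valid data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .constants import (
    MARKER_GROUPS,
    NUTRIENT_VARIABLES,
    N_VARIABLES,
    P_VARIABLES,
    TAXONOMY_RANKS,
)
from .exceptions import ValidationError


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CountTable:
    """Sites x features abundance matrix for one marker group.

    Raw tables hold nonnegative integers (read counts); after rarefaction
    averaging cells are nonnegative reals and ``raw`` is False.
    """

    data: pd.DataFrame
    marker_group: str
    raw: bool = True

    def __post_init__(self) -> None:
        if self.marker_group not in MARKER_GROUPS:
            raise ValidationError(
                f"unknown marker group {self.marker_group!r}; expected one of {MARKER_GROUPS}"
            )
        _check_unique(self.data.index, "site")
        _check_unique(self.data.columns, "feature")
        values = self.data.to_numpy()
        if values.size:
            if (values < 0).any():
                site, feat = self._first_offender(values < 0)
                raise ValidationError(
                    f"negative abundance for feature {feat!r} at site {site!r}"
                )
            if self.raw and not np.allclose(values, np.round(values)):
                site, feat = self._first_offender(values != np.round(values))
                raise ValidationError(
                    f"non-integer count for feature {feat!r} at site {site!r} in raw table"
                )
        if self.raw:
            self.data = self.data.astype(np.int64)

    def _first_offender(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.data.index[i]), str(self.data.columns[j])

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def sites(self) -> pd.Index:
        return self.data.index

    @property
    def features(self) -> pd.Index:
        return self.data.columns

    def depths(self) -> pd.Series:
        """Per-site total abundance (sequencing depth for raw tables)."""
        return self.data.sum(axis=1)


@dataclass
class TaxonomyMap:
    """feature_id -> seven-rank lineage (kingdom..species).

    Unassigned ranks use the ``unclassified_<nearest named rank>`` placeholder
    convention, so every feature resolves to *some* phylum and genus label.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in TAXONOMY_RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing ranks: {missing}")
        _check_unique(self.data.index, "feature")
        self.data = self.data[list(TAXONOMY_RANKS)].astype(str)

    def labels_at(self, features: pd.Index, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValidationError(f"unknown taxonomic rank {rank!r}")
        absent = features.difference(self.data.index)
        if len(absent):
            raise ValidationError(
                f"features absent from taxonomy: {sorted(absent.tolist())}"
            )
        return self.data.loc[features, rank]


@dataclass
class NutrientTable:
    """Per-site values of the seven N- and P-cycling variables.

    The variable families partition as 4 N-cycling (TN, NAG, net_Nmin, N_inorg)
    + 3 P-cycling (TP, AP, AKP). net_Nmin is a 28-day net change and may be
    nonpositive; TP and AP must be positive wherever a stoichiometric ratio is
    formed (checked at the point of use).
    """

    data: pd.DataFrame
    families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"N": N_VARIABLES, "P": P_VARIABLES}
    )

    def __post_init__(self) -> None:
        for var in NUTRIENT_VARIABLES:
            if var not in self.data.columns:
                raise ValidationError(f"missing variable: {var}")
        _check_unique(self.data.index, "site")
        self.data = self.data[list(NUTRIENT_VARIABLES)].astype(float)

    @property
    def sites(self) -> pd.Index:
        return self.data.index


def _read_matrix(path, what: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric {what} cell {frame.iat[i, j]!r} for row "
            f"{frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"empty {what} cell for row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    return numeric


def read_count_table(path, marker_group: str, raw: bool = True) -> CountTable:
    """Read a feature x site tab-delimited count table.

    First column holds feature identifiers, remaining columns are sites.
    Column (site) order is preserved. Negative or non-numeric cells raise
    :class:`ValidationError` naming the offending feature and site.
    """
    matrix = _read_matrix(path, "count")
    return CountTable(matrix.T, marker_group=marker_group, raw=raw)


def write_count_table(table: CountTable, path) -> None:
    out = table.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyMap(frame)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    out = tax.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_nutrients(path) -> NutrientTable:
    matrix = _read_matrix(path, "nutrient")
    return NutrientTable(matrix)


def write_nutrients(nutrients: NutrientTable, path) -> None:
    out = nutrients.data.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# network + report export

EDGE_COLUMNS = ("taxon_a", "taxon_b", "r", "sign", "p_adj")


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Export a signed network, preserving node count and per-edge sign/weight.

    ``graphml`` keeps node/edge attributes and is readable by generic graph
    tools; ``edge_tsv`` writes one row per edge (isolated nodes are implied by
    the companion node table written by the pipeline).
    """
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        rows = [
            {"taxon_a": a, "taxon_b": b, "r": d["r"], "sign": d["sign"], "p_adj": d["p_adj"]}
            for a, b, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValidationError(f"unknown network format {format!r}")


def jsonable(obj):
    """Convert report values to plain JSON types.

    Infinite positive:negative edge ratios serialize as the string "Inf";
    NaN (undefined fractions on empty edge sets) as "NA".
    """
    if isinstance(obj, dict):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isinf(x):
            return "Inf"
        if math.isnan(x):
            return "NA"
        return x
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return jsonable(obj.to_dict())
    return obj


def write_report(report: dict, path) -> None:
    """Serialize a pipeline report as deterministic, sorted-key JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
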