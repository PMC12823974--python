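"""Signed co-occurrence networks, topology metrics, and keystone taxa.

Candidate taxa (coupled or decoupled, major, occurring in more than half the
sites) are correlated pairwise across sites; after Benjamini-Hochberg
adjustment over all computable pairs, only robust (|r| > 0.6) and significant
(adjusted p < 0.05) correlations become edges, signed by the correlation
sign. All eligible candidates stay in the node set — the printed densities of
sparse soil networks only reconcile with their node counts when isolated
nodes are kept.

Keystones are scored on the unsigned, unweighted skeleton: degree, harmonic
closeness (normalized by n-1; classic closeness is undefined across the
disconnected components these sparse networks typically have) and normalized
betweenness are standardized across the network's nodes (sample SD) and
combined as z_degree + z_closeness - z_betweenness; nodes at or above the
threshold (default 1) are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import DOMAIN_LETTER, GROUP_DOMAIN
from .exceptions import ValidationError
from .preprocess import AggregatedTable


@dataclass
class NetworkParams:
    r_min: float = 0.6
    alpha: float = 0.05
    occupancy_min: float = 0.5
    keystone_threshold: float = 1.0
    adjust_method: str = "fdr_bh"  # fixed; recorded for provenance

    def validate(self) -> None:
        if not 0 < self.r_min < 1:
            raise ValidationError("r_min must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.occupancy_min < 1:
            raise ValidationError("occupancy_min must lie in (0, 1)")


COUPLED_LABELS = ("coupled_positive", "coupled_negative")
DECOUPLED_LABELS = ("decoupled_N", "decoupled_P")


def select_candidates(
    agg: AggregatedTable,
    labels: pd.DataFrame,
    which: str,
    params: NetworkParams | None = None,
    major_abund: float = 0.001,
) -> list[str]:
    """Candidate taxa for the requested network.

    ``which='coupled'`` selects coupled_positive/negative taxa,
    ``'decoupled'`` selects decoupled_N/_P; "inconsistent" and "none" taxa
    enter neither network. Candidates must additionally be major (mean
    relative abundance strictly above ``major_abund``) and occur in strictly
    more than ``occupancy_min`` of the sites.
    """
    params = params or NetworkParams()
    params.validate()
    if which == "coupled":
        wanted = COUPLED_LABELS
    elif which == "decoupled":
        wanted = DECOUPLED_LABELS
    else:
        raise ValidationError(f"which must be 'coupled' or 'decoupled', got {which!r}")
    by_taxon = labels.set_index("taxon")["label"]
    mean_ok = agg.mean_abundance > major_abund
    occ_ok = agg.occurrence > params.occupancy_min * agg.n_sites
    out = [
        t
        for t in agg.taxa
        if t in by_taxon.index
        and by_taxon[t] in wanted
        and bool(mean_ok[t])
        and bool(occ_ok[t])
    ]
    return out


def build_network(
    agg: AggregatedTable, candidates: list[str], params: NetworkParams | None = None
) -> nx.Graph:
    """All-pairs Pearson screening among candidates -> signed undirected graph.

    BH adjustment runs over the full set of computable pairs; an edge needs
    |r| strictly above ``r_min`` AND adjusted p strictly below ``alpha``.
    Constant-abundance taxa stay in the node set but their pair tests are
    non-computable and excluded from the BH family.
    """
    params = params or NetworkParams()
    params.validate()
    if len(candidates) < 2:
        raise ValidationError("need at least 2 candidate taxa")
    if agg.n_sites < 4:
        raise ValidationError("need at least 4 sites to screen pair correlations")
    missing = [t for t in candidates if t not in agg.taxa]
    if missing:
        raise ValidationError(f"candidates absent from table: {missing}")

    X = agg.data[candidates].to_numpy(dtype=float)
    n, k = X.shape
    sd = X.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - X.mean(axis=0)) / sd
        R = Z.T @ Z / n
    R = np.clip(R, -1.0, 1.0)
    ok = (sd > 0)[:, None] & (sd > 0)[None, :]

    iu, ju = np.triu_indices(k, 1)
    pair_ok = ok[iu, ju]
    r_pairs = R[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_pairs * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r_pairs**2))
    p_raw = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p_raw = np.where(np.isclose(np.abs(r_pairs), 1.0), 0.0, p_raw)

    p_adj = np.full(len(r_pairs), np.nan)
    if pair_ok.any():
        p_adj[pair_ok] = multipletests(p_raw[pair_ok], method="fdr_bh")[1]

    graph = nx.Graph(
        r_min=params.r_min,
        alpha=params.alpha,
        occupancy_min=params.occupancy_min,
        adjust_method=params.adjust_method,
    )
    for taxon in candidates:
        graph.add_node(taxon, group=str(agg.group_of[taxon]))
    for idx in range(len(r_pairs)):
        if not pair_ok[idx]:
            continue
        r = float(r_pairs[idx])
        if abs(r) > params.r_min and p_adj[idx] < params.alpha:
            graph.add_edge(
                candidates[iu[idx]],
                candidates[ju[idx]],
                r=r,
                sign="+" if r > 0 else "-",
                p_adj=float(p_adj[idx]),
            )
    return graph


def _edge_type(graph: nx.Graph, a: str, b: str) -> str:
    letters = sorted(
        DOMAIN_LETTER[GROUP_DOMAIN.get(graph.nodes[n]["group"], graph.nodes[n]["group"])]
        for n in (a, b)
    )
    return "-".join(letters)


EDGE_TYPES = ("B-B", "B-F", "B-P", "F-F", "F-P", "P-P")


def network_metrics(graph: nx.Graph) -> dict:
    """Topology summary: connectance, signed-edge counts and composition.

    ``pos_neg_ratio`` is ``inf`` (serialized "Inf") when there is no negative
    edge; ``frac_edges_bacterial`` is NaN for an empty edge set. Connectance
    is reported at full precision plus a 2-decimal display rounding.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValidationError("network metrics need at least 2 nodes")
    n_edges = graph.number_of_edges()
    possible = n * (n - 1) // 2
    signs = [d["sign"] for _, _, d in graph.edges(data=True)]
    pos = sum(s == "+" for s in signs)
    neg = n_edges - pos
    comp = {et: 0 for et in EDGE_TYPES}
    bact = 0
    for a, b in graph.edges():
        comp[_edge_type(graph, a, b)] += 1
    bact = sum(v for et, v in comp.items() if "B" in et)
    connectance = n_edges / possible
    return {
        "n_nodes": n,
        "n_edges": n_edges,
        "connectance": connectance,
        "connectance_display": round(connectance, 2),
        "pos_edges": pos,
        "neg_edges": neg,
        "pos_neg_ratio": (pos / neg) if neg else math.inf,
        "edge_types": comp,
        "frac_edges_bacterial": (bact / n_edges) if n_edges else math.nan,
    }


def centrality_and_keystones(
    graph: nx.Graph, params: NetworkParams | None = None
) -> pd.DataFrame:
    """Per-node centralities, z-scores, combined keystone score and flag.

    Centralities are computed on the unsigned topology. A metric with zero
    variance across nodes standardizes to all-zero. The combined score is
    z_degree + z_closeness - z_betweenness; keystone iff the score is at or
    above the threshold.
    """
    params = params or NetworkParams()
    n = graph.number_of_nodes()
    if n < 3:
        raise ValidationError("keystone scoring needs at least 3 nodes")
    nodes = list(graph.nodes())
    degree = np.array([graph.degree(v) for v in nodes], dtype=float)
    harmonic = nx.harmonic_centrality(graph)
    closeness = np.array([harmonic[v] / (n - 1) for v in nodes])
    btw = nx.betweenness_centrality(graph, normalized=True)
    betweenness = np.array([btw[v] for v in nodes])

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1)
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    z_deg, z_clo, z_btw = zscore(degree), zscore(closeness), zscore(betweenness)
    combined = z_deg + z_clo - z_btw
    pos = {v: 0 for v in nodes}
    neg = {v: 0 for v in nodes}
    for a, b, d in graph.edges(data=True):
        tally = pos if d["sign"] == "+" else neg
        tally[a] += 1
        tally[b] += 1
    out = pd.DataFrame(
        {
            "taxon": nodes,
            "group": [graph.nodes[v]["group"] for v in nodes],
            "degree": degree.astype(int),
            "closeness": closeness,
            "betweenness": betweenness,
            "z_degree": z_deg,
            "z_closeness": z_clo,
            "z_betweenness": z_btw,
            "combined_score": combined,
            "keystone": combined >= params.keystone_threshold,
            "pos_edge_count": [pos[v] for v in nodes],
            "neg_edge_count": [neg[v] for v in nodes],
        }
    )
    return out.sort_values(
        ["combined_score", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)
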