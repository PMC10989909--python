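"""Prevalence- and correlation-thresholded co-occurrence networks.

ASVs present in more than half of a group's samples are correlated
pairwise (Spearman on relative abundances); edges with |rho| above the
correlation threshold and p below the significance threshold form an
undirected signed graph. Core nodes are ranked by shortest-path betweenness
centrality on the unweighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CommunityTable, ValidationError

__all__ = [
    "filter_prevalence", "spearman_matrix", "build_network",
    "network_stats", "merge_domains", "write_graphml", "NetworkStats",
]


def filter_prevalence(table: CommunityTable, min_fraction: float = 0.5,
                      min_present: int | None = None) -> CommunityTable:
    """Keep ASVs present in strictly more than ``min_fraction`` of samples.

    ``min_present`` overrides the fraction with a literal strict count
    threshold (keep ASVs present in more than ``min_present`` samples).
    """
    if min_present is None and not (0 < min_fraction < 1):
        raise ValueError("min_fraction must lie in (0, 1)")
    present = (table.counts > 0).sum(axis=0)
    if min_present is not None:
        keep = present > min_present
    else:
        keep = present > min_fraction * table.n_samples
    if not keep.any():
        raise ValidationError("prevalence filter removed every ASV")
    return CommunityTable(table.counts.loc[:, keep].copy(), table.group)


def spearman_matrix(table: CommunityTable
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho (mid-rank ties) and t-approximation p-values.

    Constant ASV vectors yield NaN rho/p for their pairs.
    """
    if table.n_samples < 5:
        raise ValidationError("need >= 5 samples for correlations")
    rel = table.relative_abundance().to_numpy()
    n = rel.shape[0]
    constant = np.ptp(rel, axis=0) == 0
    ranks = np.apply_along_axis(stats.rankdata, 0, rel)  # mid-rank ties
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    ids = table.asv_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def build_network(rho: pd.DataFrame, p: pd.DataFrame,
                  rho_min: float = 0.6, p_max: float = 0.01) -> pd.DataFrame:
    """Edge list where |rho| > rho_min and p < p_max (both strict).

    Negative correlations are retained as ``negative``-sign edges: the
    correlation threshold applies to |rho|.
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValidationError("rho and p matrices are not aligned")
    ids = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    keep = (np.abs(r[iu]) > rho_min) & (pv[iu] < p_max)
    keep &= np.isfinite(r[iu]) & np.isfinite(pv[iu])
    rows = [
        (ids[i], ids[j], r[i, j], pv[i, j],
         "positive" if r[i, j] > 0 else "negative")
        for i, j in zip(iu[0][keep], iu[1][keep])
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p",
                                       "sign"])


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    pos_neg_ratio: float          # inf when no negative edge
    mean_degree: float
    betweenness: pd.Series
    core_nodes: list[str]


def network_stats(edges: pd.DataFrame, k: int = 5) -> NetworkStats:
    """Topology summary with betweenness-ranked core nodes.

    Betweenness is shortest-path centrality on the unweighted graph; the
    top-k ranking breaks ties lexicographically by node id.
    """
    if edges.empty:
        raise ValidationError("network has no edges")
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["node_a"], row["node_b"], sign=row["sign"])
    pos = int((edges["sign"] == "positive").sum())
    neg = int((edges["sign"] == "negative").sum())
    bc = pd.Series(nx.betweenness_centrality(g, normalized=True))
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_positive=pos,
        n_negative=neg,
        pos_neg_ratio=(pos / neg) if neg else float("inf"),
        mean_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        betweenness=bc.sort_index(),
        core_nodes=[n for n, _ in ranked[:k]],
    )


def write_graphml(edges: pd.DataFrame, path) -> None:
    """Export the edge list as GraphML for external visualization tools."""
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["node_a"], row["node_b"], rho=float(row["rho"]),
                   p=float(row["p"]), sign=str(row["sign"]))
    nx.write_graphml(g, path)


def merge_domains(tables: list[CommunityTable],
                  domains: list[str] | None = None) -> CommunityTable:
    """Column-concatenate same-sample tables with domain-tagged ASV ids.

    With ``domains`` given, ids become ``{domain}|{asv}``; without tags,
    colliding ids across tables are an error.
    """
    if not tables:
        raise ValueError("no tables to merge")
    samples = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != samples:
            raise ValidationError("tables do not share identical samples")
    frames = []
    for idx, t in enumerate(tables):
        df = t.counts.copy()
        if domains is not None:
            df.columns = [f"{domains[idx]}|{a}" for a in df.columns]
        frames.append(df)
    merged = pd.concat(frames, axis=1)
    if merged.columns.duplicated().any():
        dup = merged.columns[merged.columns.duplicated()][0]
        raise ValidationError(
            f"colliding ASV id {dup!r}; pass domain tags to disambiguate"
        )
    return CommunityTable(merged, tables[0].group)
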