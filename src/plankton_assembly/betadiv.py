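"""Alpha diversity, pairwise dissimilarities, beta-diversity decomposition,
distance decay, Mantel tests and Mantel correlograms.

Total Bray-Curtis dissimilarity D between two samples is split, in the
Podani-family quantitative (percentage-difference) decomposition, into a
species-replacement component Repl and a richness/abundance-difference
component RichDiff, with S = 1 - D completing the ternary triplet:
for A = sum_j min(x_j, y_j), B = sum_j (x_j - min), C = sum_j (y_j - min),

    D        = (B + C) / (2A + B + C)
    Repl     = 2 min(B, C) / (2A + B + C)
    RichDiff = |B - C| / (2A + B + C)

so D = Repl + RichDiff exactly and S + Repl + RichDiff = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    CommunityTable, DistanceMatrix, EnvTable, PhyloTree, ValidationError,
)

__all__ = [
    "shannon", "bray_curtis_matrix", "beta_mntd_matrix", "decompose_beta",
    "distance_decay", "mantel_test", "niche_values", "niche_distance",
    "mantel_correlogram", "BetaDecomposition", "DistanceDecayFit",
    "CorrelogramResult",
]


# ---------------------------------------------------------------------------
# alpha / taxonomic beta
# ---------------------------------------------------------------------------

def shannon(table: CommunityTable) -> pd.Series:
    """Shannon-Wiener index H (nats) per sample."""
    q = table.relative_abundance().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids,
                     name="shannon")


def bray_curtis_matrix(table: CommunityTable,
                       use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``use_relative`` (default) computes on within-sample relative
    abundances; otherwise on raw counts.
    """
    x = (table.relative_abundance() if use_relative else table.counts)
    vals = squareform(pdist(x.to_numpy(float), metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, vals, kind="bray_curtis")


# ---------------------------------------------------------------------------
# phylogenetic beta
# ---------------------------------------------------------------------------

def beta_mntd_matrix(table: CommunityTable, tree: PhyloTree,
                     weighted: bool = True) -> DistanceMatrix:
    """Beta mean nearest taxon distance between all sample pairs.

    For samples k, m:
    ``0.5 * (sum_i f_ik min_{j in m} d_ij + sum_j f_jm min_{i in k} d_ij)``
    with f the within-sample relative abundance (weighted) or 1/richness
    (unweighted) and d the patristic distance.
    """
    missing = set(table.asv_ids) - set(tree.tip_labels)
    if missing:
        raise ValidationError(
            f"ASV absent from tree: {sorted(missing)[0]!r}"
        )
    D = tree.patristic_matrix(order=table.asv_ids).values
    F = _mntd_weights(table, weighted)
    vals = _beta_mntd_from_weights(F, D)
    return DistanceMatrix(table.sample_ids, vals, kind="bmntd")


def _mntd_weights(table: CommunityTable, weighted: bool) -> np.ndarray:
    counts = table.counts.to_numpy(float)
    present = counts > 0
    if weighted:
        F = counts / counts.sum(axis=1, keepdims=True)
    else:
        F = present / present.sum(axis=1, keepdims=True)
    return F


def _beta_mntd_from_weights(F: np.ndarray, D: np.ndarray) -> np.ndarray:
    """All-pairs weighted betaMNTD given weights F (S x T) and distances D."""
    S, T = F.shape
    present_idx = [np.flatnonzero(F[i] > 0) for i in range(S)]
    # M[t, m] = distance from taxon t to its nearest taxon in sample m
    M = np.empty((T, S))
    for m in range(S):
        M[:, m] = D[:, present_idx[m]].min(axis=1)
    G = F @ M  # G[k, m] = mean nearest-taxon distance from k into m
    return 0.5 * (G + G.T)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class BetaDecomposition:
    """Long-format per-pair decomposition plus within-group Repl/D means."""

    pairs: pd.DataFrame  # sample_a, sample_b, D, Repl, RichDiff, S
    group_summary: pd.DataFrame | None = None


def decompose_beta(table: CommunityTable,
                   family: str = "podani_quantitative",
                   use_relative: bool = True) -> BetaDecomposition:
    """Replacement / richness-difference decomposition for all sample pairs.

    ``family='podani_quantitative'`` (default) keeps D identical to
    Bray-Curtis; ``family='baselga_quantitative'`` splits D into balanced
    variation (Repl) and abundance-gradient (RichDiff) components instead.
    """
    if family not in ("podani_quantitative", "baselga_quantitative"):
        raise ValueError(f"unknown decomposition family {family!r}")
    x = (table.relative_abundance() if use_relative else table.counts)
    X = x.to_numpy(float)
    ids = table.sample_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            mins = np.minimum(X[i], X[j])
            A = mins.sum()
            B = X[i].sum() - A
            C = X[j].sum() - A
            denom = 2 * A + B + C
            if denom == 0:
                rows.append((ids[i], ids[j], np.nan, np.nan, np.nan, np.nan))
                continue
            if family == "podani_quantitative":
                repl = 2 * min(B, C) / denom
                rich = abs(B - C) / denom
            else:
                repl = min(B, C) / (A + min(B, C))
                rich = (abs(B - C) / denom) * (A / (A + min(B, C)))
            d = (B + C) / denom
            rows.append((ids[i], ids[j], d, repl, rich, 1.0 - d))
    pairs = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "D", "Repl", "RichDiff", "S"]
    )
    summary = None
    if table.group is not None:
        g = table.group
        mask = (g.loc[pairs["sample_a"]].to_numpy()
                == g.loc[pairs["sample_b"]].to_numpy())
        within = pairs[mask].copy()
        within["group"] = g.loc[within["sample_a"]].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            within["repl_over_d"] = within["Repl"] / within["D"]
        summary = (
            within.groupby("group")[["D", "Repl", "RichDiff", "repl_over_d"]]
            .mean()
            .reset_index()
        )
    return BetaDecomposition(pairs=pairs, group_summary=summary)


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

def _check_aligned(dm1: DistanceMatrix, dm2: DistanceMatrix) -> None:
    if dm1.ids != dm2.ids:
        raise ValidationError("distance matrices have mismatched ids/order")


def mantel_test(dm1: DistanceMatrix, dm2: DistanceMatrix,
                method: str = "pearson", n_perm: int = 999,
                seed: int | None = None, tail: str = "greater"
                ) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Correlation over strictly-lower-triangle entries; the permutation p-value
    is ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)`` (one-tailed, default) or
    the analogous two-tailed count on |r|.
    """
    _check_aligned(dm1, dm2)
    x = dm1.condensed()
    y = dm2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant distance matrix in Mantel test")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    n = dm1.n
    Y = squareform(y)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_p = Y[np.ix_(perm, perm)][iu]
        r_p = _pearson(x, y_p)
        if tail == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DistanceDecayFit:
    slope: float           # similarity change per km
    intercept: float
    r_squared: float
    mantel_r: float
    mantel_p: float
    kind: str = "taxonomic"


def distance_decay(similarity: DistanceMatrix, geo: DistanceMatrix,
                   n_perm: int = 999, seed: int | None = None,
                   kind: str = "taxonomic") -> DistanceDecayFit:
    """OLS of pairwise community similarity on geographic distance (km),
    plus a Mantel test of the same association."""
    _check_aligned(similarity, geo)
    x = geo.condensed()
    y = similarity.condensed()
    if np.ptp(x) == 0:
        raise ValidationError("all geographic distances identical")
    if np.ptp(y) == 0:
        return DistanceDecayFit(slope=0.0, intercept=float(y.mean()),
                                r_squared=0.0, mantel_r=0.0, mantel_p=1.0,
                                kind=kind)
    fit = stats.linregress(x, y)
    mr, mp = mantel_test(similarity, geo, n_perm=n_perm, seed=seed,
                         tail="two")
    return DistanceDecayFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), mantel_r=mr, mantel_p=mp,
        kind=kind,
    )


def similarity_from(dm: DistanceMatrix) -> DistanceMatrix:
    """1 - distance, for similarity-based decay fits.

    Values may be negative (e.g. 1 - betaMNTD when betaMNTD > 1), so the
    result carries the unconstrained ``similarity`` kind tag.
    """
    vals = 1.0 - dm.values
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(dm.ids, vals, kind="similarity")


# ---------------------------------------------------------------------------
# niche values & Mantel correlogram
# ---------------------------------------------------------------------------

def niche_values(table: CommunityTable, env: EnvTable,
                 variables=None) -> pd.DataFrame:
    """Abundance-weighted mean environment per ASV (z-scored variables).

    ``niche_jv = sum_i x_ij e_iv / sum_i x_ij``; ASVs absent everywhere are
    dropped.
    """
    variables = list(variables) if variables is not None else env.variables
    e = env.data.loc[table.sample_ids, variables].astype(float)
    sd = e.std(ddof=0)
    keep = sd > 0
    e = (e.loc[:, keep] - e.loc[:, keep].mean()) / sd[keep]
    x = table.counts.to_numpy(float)
    totals = x.sum(axis=0)
    present = totals > 0
    niche = (x[:, present].T @ e.to_numpy()) / totals[present][:, None]
    return pd.DataFrame(niche,
                        index=np.asarray(table.asv_ids)[present],
                        columns=e.columns)


def niche_distance(niche: pd.DataFrame) -> DistanceMatrix:
    vals = squareform(pdist(niche.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(niche.index), vals, kind="euclidean_env")


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics.

    ``classes`` columns: class_index, midpoint, n_pairs, mantel_r, p_raw,
    p_corrected (progressive Holm in class order; NaN rows are empty
    classes). The sign convention follows the classic Mantel correlogram:
    positive r in a class means pairs in that class are more similar (lower
    niche distance) than average.
    """

    classes: pd.DataFrame
    break_points: np.ndarray


def mantel_correlogram(niche_dist: DistanceMatrix,
                       phylo_dist: DistanceMatrix,
                       n_classes: int | None = None, n_perm: int = 999,
                       seed: int | None = None) -> CorrelogramResult:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Phylogenetic distances are cut into equal-width classes (Sturges count
    by default); within each class the Mantel statistic is the negated
    Pearson correlation between the niche-distance vector and the class
    membership indicator, tested by permuting taxa labels of the niche
    matrix. P-values receive a progressive Holm correction in class order.
    """
    _check_aligned(niche_dist, phylo_dist)
    d = phylo_dist.condensed()
    x = niche_dist.condensed()
    n_pairs = d.size
    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(n_pairs)))
    breaks = np.linspace(0.0, d.max(), n_classes + 1)
    # assign each pair to a class; right-inclusive top edge
    cls = np.clip(np.digitize(d, breaks[1:-1], right=True), 0, n_classes - 1)
    masks = [cls == c for c in range(n_classes)]
    counts = np.array([m.sum() for m in masks])

    def class_stats(vec: np.ndarray) -> np.ndarray:
        out = np.full(n_classes, np.nan)
        for c, mask in enumerate(masks):
            if 0 < counts[c] < n_pairs:
                out[c] = -_pearson(vec, mask.astype(float))
        return out

    r_obs = class_stats(x)
    rng = np.random.default_rng(seed)
    n = niche_dist.n
    X = squareform(x)
    iu = np.triu_indices(n, k=1)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = class_stats(X[np.ix_(perm, perm)][iu])
        exceed += np.abs(r_p) >= np.abs(r_obs)
    p_raw = np.where(np.isnan(r_obs), np.nan, (1 + exceed) / (1 + n_perm))
    # progressive Holm: class k corrected within the first k tested classes
    p_corr = np.full(n_classes, np.nan)
    tested = []
    for c in range(n_classes):
        if np.isnan(p_raw[c]):
            continue
        tested.append(c)
        sub = p_raw[tested]
        order = np.argsort(sub)
        k = len(sub)
        adj = np.empty(k)
        running = 0.0
        for rank, pos in enumerate(order):
            running = max(running, (k - rank) * sub[pos])
            adj[pos] = min(1.0, running)
        p_corr[c] = adj[-1]
    mid = (breaks[:-1] + breaks[1:]) / 2
    classes = pd.DataFrame({
        "class_index": np.arange(n_classes),
        "midpoint": mid,
        "n_pairs": counts,
        "mantel_r": r_obs,
        "p_raw": p_raw,
        "p_corrected": p_corr,
    })
    return CorrelogramResult(classes=classes, break_points=breaks)
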