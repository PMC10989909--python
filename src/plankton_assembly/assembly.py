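"""Null-model partitioning of community assembly processes.

Two complementary null models per sample pair:

* betaNTI — z-score of the observed (abundance-weighted) betaMNTD against a
  taxa-label-shuffle null: tip labels are permuted across the phylogeny,
  preserving each sample's richness and abundances while randomizing
  phylogenetic relationships. |betaNTI| > 2 indicates selection.
* RC_bray — position of the observed Bray-Curtis dissimilarity within a
  community-randomization null that preserves each sample's richness and
  total reads: taxa are drawn with probability proportional to regional
  occupancy, each drawn taxon is seeded with one read, and the remaining
  reads are allocated multinomially by regional relative abundance.
  RC = 2 * [(#{null < obs} + 0.5 #{null = obs}) / n_null] - 1 in [-1, 1].

Pairs are then classified into five assembly processes:
homogeneous selection (betaNTI < -2), variable selection (betaNTI > 2),
dispersal limitation (|betaNTI| < 2 and RC > 0.95), homogenizing dispersal
(|betaNTI| < 2 and RC < -0.95), and undominated otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .betadiv import _beta_mntd_from_weights, _mntd_weights
from .core_io import CommunityTable, PhyloTree, ValidationError

__all__ = [
    "beta_nti", "raup_crick_bray", "classify_pair", "process_fractions",
    "sorting_dispersal_ratio", "assembly_table", "ProcessFractions",
    "PROCESS_CLASSES",
]

PROCESS_CLASSES = (
    "homogeneous_selection", "variable_selection", "dispersal_limitation",
    "homogenizing_dispersal", "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def _pair_list(sample_ids, group: pd.Series | None,
               within_groups: bool) -> list[tuple[int, int]]:
    pairs = []
    for i, j in itertools.combinations(range(len(sample_ids)), 2):
        if within_groups and group is not None:
            if group.iloc[i] != group.iloc[j]:
                continue
        pairs.append((i, j))
    return pairs


def _pair_seed(master: int | None, i: int, j: int) -> np.random.SeedSequence:
    base = 0 if master is None else int(master)
    return np.random.SeedSequence(entropy=base, spawn_key=(i, j))


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

def beta_nti(table: CommunityTable, tree: PhyloTree, n_null: int = 999,
             weighted: bool = True, seed: int | None = None,
             within_groups: bool = False, pairs=None,
             null_mode: str = "shared") -> pd.DataFrame:
    """Per-pair betaNTI from a taxa-shuffle null.

    ``null_mode='shared'`` (default, the convention of picante-style
    implementations) evaluates every pair on one common set of ``n_null``
    tip-label permutations; ``'per_pair'`` derives an independent seeded
    null per pair (identical results serial or concurrent). ``pairs``
    restricts computation to an explicit list of (sample_a, sample_b) id
    tuples.

    Returns a frame with columns sample_a, sample_b, bmntd_obs, null_mean,
    null_sd, bnti. Pairs with a degenerate null (sd = 0) carry betaNTI 0
    when the observation equals the null (no phylogenetic divergence) and
    NaN otherwise.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    missing = set(table.asv_ids) - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"ASV absent from tree: {sorted(missing)[0]!r}")
    D = tree.patristic_matrix(order=table.asv_ids).values
    F = _mntd_weights(table, weighted)
    obs = _beta_mntd_from_weights(F, D)
    pairs = _resolve_pairs(table, within_groups, pairs)
    if null_mode == "shared":
        null_mean, null_sd = _null_bmntd_shared(F, D, pairs, n_null, seed)
    elif null_mode == "per_pair":
        null_mean, null_sd = {}, {}
        for (i, j) in pairs:
            m, s = _null_bmntd_pair(F, D, i, j, n_null,
                                    _pair_seed(seed, i, j))
            null_mean[(i, j)] = m
            null_sd[(i, j)] = s
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")
    ids = table.sample_ids
    rows = []
    for (i, j) in pairs:
        m, s = null_mean[(i, j)], null_sd[(i, j)]
        if s > 0:
            bnti = (obs[i, j] - m) / s
        elif np.isclose(obs[i, j], m):
            # degenerate null with matching observation (e.g. both samples
            # hold identical taxa sets): no phylogenetic divergence, z = 0
            bnti = 0.0
        else:
            bnti = np.nan
        rows.append((ids[i], ids[j], obs[i, j], m, s, bnti))
    return pd.DataFrame(rows, columns=[
        "sample_a", "sample_b", "bmntd_obs", "null_mean", "null_sd", "bnti",
    ])


def _resolve_pairs(table: CommunityTable, within_groups: bool,
                   pairs) -> list[tuple[int, int]]:
    if pairs is None:
        return _pair_list(table.sample_ids, table.group, within_groups)
    pos = {s: k for k, s in enumerate(table.sample_ids)}
    out = []
    for a, b in pairs:
        i, j = pos[a], pos[b]
        out.append((i, j) if i < j else (j, i))
    return out


def _null_bmntd_shared(F: np.ndarray, D: np.ndarray,
                       pairs: list[tuple[int, int]], n_null: int,
                       seed) -> tuple[dict, dict]:
    """Running mean/sd of betaMNTD over shared tip-label permutations,
    evaluated only for the requested pairs."""
    rng = np.random.default_rng(seed)
    S, T = F.shape
    involved = sorted({k for p in pairs for k in p})
    idx = {k: np.flatnonzero(F[k] > 0) for k in involved}
    total = np.zeros(len(pairs))
    total_sq = np.zeros(len(pairs))
    M = {}
    Fs = np.empty_like(F)
    for _ in range(n_null):
        perm = rng.permutation(T)
        for k in involved:
            M[k] = D[:, perm[idx[k]]].min(axis=1)
        Fs[:, perm] = F
        vals = np.fromiter(
            (0.5 * (Fs[i] @ M[j] + Fs[j] @ M[i]) for i, j in pairs),
            dtype=float, count=len(pairs),
        )
        total += vals
        total_sq += vals * vals
    mean = total / n_null
    var = np.maximum(total_sq / n_null - mean * mean, 0.0)
    sd = np.sqrt(var * n_null / max(n_null - 1, 1))
    return ({p: mean[k] for k, p in enumerate(pairs)},
            {p: sd[k] for k, p in enumerate(pairs)})


def _null_bmntd_pair(F: np.ndarray, D: np.ndarray, i: int, j: int,
                     n_null: int, seed_seq,
                     chunk: int = 128) -> tuple[float, float]:
    """Independent null for one pair, vectorized over permutation chunks."""
    rng = np.random.default_rng(seed_seq)
    idx_i = np.flatnonzero(F[i] > 0)
    idx_j = np.flatnonzero(F[j] > 0)
    fi = F[i, idx_i]
    fj = F[j, idx_j]
    T = F.shape[1]
    vals = np.empty(n_null)
    done = 0
    while done < n_null:
        b = min(chunk, n_null - done)
        perms = np.empty((b, T), dtype=np.intp)
        for r in range(b):
            perms[r] = rng.permutation(T)
        pi = perms[:, idx_i]          # (b, r_i)
        pj = perms[:, idx_j]          # (b, r_j)
        block = D[pi[:, :, None], pj[:, None, :]]  # (b, r_i, r_j)
        vals[done:done + b] = 0.5 * (
            (block.min(axis=2) * fi).sum(axis=1)
            + (block.min(axis=1) * fj).sum(axis=1)
        )
        done += b
    return float(vals.mean()), float(vals.std(ddof=1))


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def raup_crick_bray(table: CommunityTable, n_null: int = 999,
                    seed: int | None = None,
                    within_groups: bool = False,
                    pairs=None) -> pd.DataFrame:
    """Per-pair Bray-Curtis Raup-Crick index.

    The null preserves each sample's observed richness and total reads;
    membership is drawn without replacement with probability proportional
    to regional occupancy, and reads (one guaranteed per drawn taxon) are
    allocated by regional relative abundance. Ties in the null CDF count at
    half weight, keeping RC symmetric about 0.

    Returns a frame with columns sample_a, sample_b, bc_obs, rc_bray.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.counts.to_numpy()
    S, T = counts.shape
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    if regional.sum() == 0:
        raise ValidationError("empty community table")
    occ_w = occupancy / occupancy.sum()
    ab_w = regional / regional.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    pairs = _resolve_pairs(table, within_groups, pairs)
    ids = table.sample_ids
    rows = []
    for (i, j) in pairs:
        rng = np.random.default_rng(_pair_seed(seed, i, j))
        x = _null_assemblages(rng, T, int(richness[i]), int(totals[i]),
                              occ_w, ab_w, n_null)
        y = _null_assemblages(rng, T, int(richness[j]), int(totals[j]),
                              occ_w, ab_w, n_null)
        inter = np.minimum(x, y).sum(axis=1)
        null_bc = 1.0 - 2.0 * inter / (totals[i] + totals[j])
        obs = 1.0 - 2.0 * np.minimum(counts[i], counts[j]).sum() \
            / (totals[i] + totals[j])
        less = (null_bc < obs - 1e-12).sum()
        ties = (np.abs(null_bc - obs) <= 1e-12).sum()
        rc = 2.0 * ((less + 0.5 * ties) / n_null) - 1.0
        rows.append((ids[i], ids[j], obs, rc))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "bc_obs",
                                       "rc_bray"])


def _null_assemblages(rng, T: int, richness: int, total: int,
                      occ_w: np.ndarray, ab_w: np.ndarray,
                      n_null: int) -> np.ndarray:
    """(n_null, T) integer null count matrix for one sample."""
    # Gumbel top-k trick: weighted sampling without replacement, vectorized
    with np.errstate(divide="ignore"):
        logw = np.log(occ_w)
    keys = logw[None, :] + rng.gumbel(size=(n_null, T))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_null, T), dtype=np.int64)
    rows = np.repeat(np.arange(n_null), richness)
    extra = total - richness
    if extra < 0:
        raise ValidationError("sample total below richness")
    alloc = np.ones((n_null, richness), dtype=np.int64)
    if extra > 0:
        probs = ab_w[chosen]
        sums = probs.sum(axis=1, keepdims=True)
        # occupancy-only taxa with zero regional reads cannot occur; guard
        probs = np.where(sums > 0, probs / sums,
                         np.full_like(probs, 1.0 / richness))
        for r in range(n_null):
            alloc[r] += rng.multinomial(extra, probs[r])
    out[rows, chosen.ravel()] = alloc.ravel()
    return out


# ---------------------------------------------------------------------------
# classification & aggregation
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float) -> str:
    """Assign one of the five assembly-process classes.

    Selection classes depend on betaNTI only; boundary values (betaNTI = +-2,
    RC = +-0.95) fall to ``undominated`` by strict inequality.
    """
    if not np.isfinite(bnti):
        return "unclassified"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if abs(bnti) < BNTI_THRESHOLD:
        if rc > RC_THRESHOLD:
            return "dispersal_limitation"
        if rc < -RC_THRESHOLD:
            return "homogenizing_dispersal"
    return "undominated"


def assembly_table(table: CommunityTable, tree: PhyloTree,
                   n_null: int = 999, weighted: bool = True,
                   seed: int | None = None, within_groups: bool = True,
                   null_mode: str = "shared") -> pd.DataFrame:
    """Full per-pair table: betaMNTD, betaNTI, Bray-Curtis, RC, class."""
    nti = beta_nti(table, tree, n_null=n_null, weighted=weighted, seed=seed,
                   within_groups=within_groups, null_mode=null_mode)
    rc = raup_crick_bray(table, n_null=n_null, seed=seed,
                         within_groups=within_groups)
    out = nti.merge(rc, on=["sample_a", "sample_b"])
    out["process"] = [
        classify_pair(b, r) for b, r in zip(out["bnti"], out["rc_bray"])
    ]
    if table.group is not None:
        out.insert(2, "group", table.group.loc[out["sample_a"]].to_numpy())
    return out


@dataclass
class ProcessFractions:
    """Per-group class fractions (percent) and aggregate process shares."""

    table: pd.DataFrame  # one row per group

    def as_percent(self) -> pd.DataFrame:
        return self.table


def process_fractions(pairs: pd.DataFrame,
                      group_col: str | None = "group") -> ProcessFractions:
    """Aggregate classified pairs into per-group process fractions.

    Reported as percentages. ``deterministic`` = both selection classes
    (|betaNTI| > 2); ``stochastic`` = 100 - deterministic; ``homogenizing``
    = homogeneous selection + homogenizing dispersal; ``differentiating`` =
    variable selection + dispersal limitation.
    """
    df = pairs[pairs["process"].isin(PROCESS_CLASSES)].copy()
    if df.empty:
        raise ValidationError("no classified pairs")
    if group_col is None or group_col not in df.columns:
        df["_group"] = "all"
        group_col = "_group"
    rows = []
    for g, sub in df.groupby(group_col):
        n = len(sub)
        frac = {
            c: 100.0 * (sub["process"] == c).sum() / n
            for c in PROCESS_CLASSES
        }
        det = frac["homogeneous_selection"] + frac["variable_selection"]
        row = {"group": g, "n_pairs": n, **frac,
               "deterministic": det, "stochastic": 100.0 - det,
               "homogenizing": frac["homogeneous_selection"]
               + frac["homogenizing_dispersal"],
               "differentiating": frac["variable_selection"]
               + frac["dispersal_limitation"]}
        row["sorting_dispersal_ratio"] = sorting_dispersal_ratio(row)
        rows.append(row)
    return ProcessFractions(table=pd.DataFrame(rows))


def sorting_dispersal_ratio(fractions: dict | pd.Series) -> float:
    """(homogeneous + variable selection) / dispersal limitation.

    Infinite (with the sign of the numerator) when no pair is classified as
    dispersal limitation.
    """
    num = (fractions["homogeneous_selection"]
           + fractions["variable_selection"])
    den = fractions["dispersal_limitation"]
    if den == 0:
        return float("inf") if num > 0 else float("nan") if num == 0 else 0.0
    return float(num / den)
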