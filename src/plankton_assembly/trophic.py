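"""Trophic lake index (TLI), bloom flagging, environmental heterogeneity.

The composite TLI follows the weighted-sum convention for Chinese lakes:
each factor contributes a component index ``TLI_j = 10 (a_j + b_j ln x_j)``
and the composite is ``sum_j W_j TLI_j`` with correlation-derived weights
``W_j = r_j^2 / sum r^2``. The default factor set is Chl-a (ug/L), TP, TN
and COD (mg/L); both coefficients and weights are plain data and can be
swapped for any other convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core_io import EnvTable, SampleMetadata, ValidationError

__all__ = [
    "TLICoefficients", "TLIResult", "compute_tli", "classify_trophic_state",
    "flag_bloom", "env_heterogeneity", "HeterogeneityResult",
    "BLOOM_THRESHOLD", "TROPHIC_CUTPOINTS",
]

BLOOM_THRESHOLD = 40.0  # ug/L Chl-a

#: composite-TLI class boundaries (oligo/meso/light/middle/hyper eutrophic)
TROPHIC_CUTPOINTS = (30.0, 50.0, 60.0, 70.0)
TROPHIC_LABELS = ("oligotrophic", "mesotrophic", "light eutrophic",
                  "middle eutrophic", "hypereutrophic")


@dataclass
class TLICoefficients:
    """(a, b) per factor for TLI_j = 10 (a + b ln x), plus correlations r.

    Defaults are the widely used lake TLI(Sigma) constants; Chl-a enters in
    ug/L, TP/TN/COD in mg/L.
    """

    a: dict = field(default_factory=lambda: {
        "Chl_a": 2.5, "TP": 9.436, "TN": 5.453, "COD": 0.109,
    })
    b: dict = field(default_factory=lambda: {
        "Chl_a": 1.086, "TP": 1.624, "TN": 1.694, "COD": 2.661,
    })
    r: dict = field(default_factory=lambda: {
        "Chl_a": 1.0, "TP": 0.84, "TN": 0.82, "COD": 0.83,
    })

    @property
    def factors(self) -> list[str]:
        return list(self.a)

    def weights(self) -> dict:
        r2 = {k: v * v for k, v in self.r.items()}
        total = sum(r2.values())
        return {k: v / total for k, v in r2.items()}


@dataclass
class TLIResult:
    components: pd.DataFrame   # per-sample TLI_j per factor
    weights: dict
    composite: pd.Series
    trophic_class: pd.Series
    bloom: pd.Series


def compute_tli(env: EnvTable, coefficients: TLICoefficients | None = None,
                bloom_threshold: float = BLOOM_THRESHOLD,
                cutpoints=TROPHIC_CUTPOINTS) -> TLIResult:
    """Component and composite TLI per sample, with class label and bloom flag."""
    coef = coefficients or TLICoefficients()
    for f in coef.factors:
        if f not in env.data.columns:
            raise ValidationError(f"environment table lacks TLI factor {f!r}")
        if f not in coef.b or f not in coef.r:
            raise ValidationError(f"missing coefficient for factor {f!r}")
        col = env.data[f]
        if (col <= 0).any():
            bad = col.index[col <= 0][0]
            raise ValidationError(
                f"nonpositive {f!r} for sample {bad!r}: TLI needs ln(x)"
            )
    comps = pd.DataFrame({
        f: 10.0 * (coef.a[f] + coef.b[f] * np.log(env.data[f]))
        for f in coef.factors
    })
    weights = coef.weights()
    composite = sum(weights[f] * comps[f] for f in coef.factors)
    composite.name = "TLI"
    labels = composite.map(lambda v: classify_trophic_state(v, cutpoints))
    bloom = env.data["Chl_a"].map(
        lambda c: flag_bloom(c, bloom_threshold)
    ) if "Chl_a" in env.data.columns else pd.Series(False, index=env.data.index)
    return TLIResult(components=comps, weights=weights, composite=composite,
                     trophic_class=labels, bloom=bloom)


def classify_trophic_state(tli: float, cutpoints=TROPHIC_CUTPOINTS) -> str:
    """Map a composite TLI to a trophic-state label (defaults 30/50/60/70)."""
    if not np.isfinite(tli):
        raise ValueError("TLI must be finite")
    for cut, label in zip(cutpoints, TROPHIC_LABELS):
        if tli < cut:
            return label
    return TROPHIC_LABELS[-1]


def flag_bloom(chl: float, threshold: float = BLOOM_THRESHOLD,
               strict: bool = True) -> bool:
    """Algal-bloom flag: Chl-a strictly above the threshold (default 40 ug/L)."""
    if chl < 0:
        raise ValueError("Chl-a must be >= 0")
    return bool(chl > threshold) if strict else bool(chl >= threshold)


# ---------------------------------------------------------------------------
# environmental heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityResult:
    per_group: pd.DataFrame       # mean pairwise dist, mean dist-to-centroid
    per_sample: pd.Series         # distance to own group centroid
    contrasts: pd.DataFrame       # pairwise group tests, permutation p


def env_heterogeneity(env: EnvTable, meta: SampleMetadata | pd.Series,
                      variables=None, n_perm: int = 999,
                      seed: int | None = None) -> HeterogeneityResult:
    """Within-group dispersion in standardized physicochemical space.

    Variables are z-scored across all samples jointly; zero-variance
    variables are dropped with a warning. Heterogeneity per group is both
    the mean within-group pairwise Euclidean distance and the mean distance
    to the group centroid (PERMDISP-flavoured). Group contrasts compare
    mean distance-to-centroid by permuting group labels.
    """
    group = meta.group if isinstance(meta, SampleMetadata) else meta
    group = group.loc[env.data.index]
    sizes = group.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    variables = list(variables) if variables is not None else env.variables
    X = env.data[variables].astype(float)
    sd = X.std(ddof=0)
    dropped = [c for c in variables if sd[c] == 0]
    if dropped:
        import logging
        logging.getLogger("plankton_assembly").warning(
            "dropping zero-variance variables: %s", dropped)
        X = X.drop(columns=dropped)
    Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
    labels = group.to_numpy()
    stats_obs, per_sample = _dispersion(Z, labels)
    per_group = pd.DataFrame(stats_obs).set_index("group")
    groups = list(per_group.index)
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            a, b = groups[gi], groups[gj]
            obs = abs(per_group.loc[a, "mean_dist_to_centroid"]
                      - per_group.loc[b, "mean_dist_to_centroid"])
            mask = (labels == a) | (labels == b)
            sub = Z[mask]
            sub_labels = labels[mask]
            count = 0
            for _ in range(n_perm):
                perm_labels = rng.permutation(sub_labels)
                st, _ = _dispersion(sub, perm_labels)
                d = {s["group"]: s["mean_dist_to_centroid"] for s in st}
                count += abs(d[a] - d[b]) >= obs - 1e-12
            rows.append({"group_a": a, "group_b": b, "observed_diff": obs,
                         "p_value": (1 + count) / (1 + n_perm)})
    per_sample_s = pd.Series(per_sample, index=env.data.index,
                             name="dist_to_centroid")
    return HeterogeneityResult(per_group=per_group,
                               per_sample=per_sample_s,
                               contrasts=pd.DataFrame(rows))


def _dispersion(Z: np.ndarray, labels: np.ndarray):
    stats_rows = []
    per_sample = np.empty(len(Z))
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = Z[idx]
        centroid = sub.mean(axis=0)
        dc = np.linalg.norm(sub - centroid, axis=1)
        per_sample[idx] = dc
        if len(idx) > 1:
            pw = pdist(sub, metric="euclidean").mean()
        else:
            pw = 0.0
        stats_rows.append({"group": g, "n": len(idx),
                           "mean_pairwise_dist": float(pw),
                           "mean_dist_to_centroid": float(dc.mean())})
    return stats_rows, per_sample
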