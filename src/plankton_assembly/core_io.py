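"""Input containers, validation, filtering and shared matrix/tree primitives.

The pipeline consumes three artifacts: a sample x ASV count table (TSV), a
rooted Newick phylogeny whose tips are ASV identifiers, and per-sample
metadata/environment tables. Everything downstream (null models, neutral fit,
networks, TLI) runs off the aligned versions of these objects.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("plankton_assembly")

EARTH_RADIUS_KM = 6371.0

#: physicochemical variables the environment table may carry (units in docs)
ENV_VARIABLES = (
    "temperature", "pH", "DO", "turbidity", "EC",
    "TP", "SRP", "TN", "NH4_N", "NO3_N", "COD", "Ca", "Mg", "Fe", "Chl_a",
)


class ValidationError(ValueError):
    """Raised when an input artifact violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Sample x ASV count matrix with an optional per-sample group label.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, rows = samples, columns = ASVs.
    group : pandas.Series, optional
        Categorical label per sample (e.g. sampling month), indexed like
        ``counts``.
    """

    counts: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicate ASV id: {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[i]!r}, ASV {c.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        self.counts = c.astype(np.int64)
        if self.group is not None:
            self.group = self.group.reindex(c.index)
            if self.group.isna().any():
                missing = self.group.index[self.group.isna()][0]
                raise ValidationError(f"sample {missing!r} has no group label")

    # -- convenience accessors ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0][0]
            raise ValidationError(f"sample {empty!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        g = self.group.loc[sample_ids] if self.group is not None else None
        return CommunityTable(self.counts.loc[list(sample_ids)].copy(), g)

    def drop_empty_asvs(self) -> "CommunityTable":
        keep = self.counts.sum(axis=0) > 0
        return CommunityTable(self.counts.loc[:, keep].copy(), self.group)


@dataclass
class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths; tips are ASV ids."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels in tree")
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValidationError("negative branch length in tree")
        self._patristic_cache: tuple[tuple[str, ...], np.ndarray] | None = None

    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "PhyloTree":
        kw = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True,
                                 **kw)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   unquoted_underscores=True).strip()

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def prune_to(self, labels) -> "PhyloTree":
        keep = set(labels)
        present = [t for t in self.tree.taxon_namespace if t.label in keep]
        if not present:
            raise ValidationError("no requested tips present in tree")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa([t for t in tree.taxon_namespace if t.label in keep])
        return PhyloTree(tree)

    def patristic_matrix(self, order=None) -> "DistanceMatrix":
        """Pairwise tip-to-tip path-length matrix.

        Computed by a single postorder sweep: at each internal node the
        distances between tips of distinct child subtrees are the sums of
        their accumulated root-ward path lengths.
        """
        labels = self.tip_labels
        if self._patristic_cache is None:
            idx = {lab: i for i, lab in enumerate(labels)}
            n = len(labels)
            D = np.zeros((n, n))
            store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for node in self.tree.postorder_node_iter():
                if node.is_leaf():
                    store[id(node)] = (
                        np.array([idx[node.taxon.label]]),
                        np.zeros(1),
                    )
                    continue
                groups = []
                for child in node.child_nodes():
                    ci, cd = store.pop(id(child))
                    bl = child.edge.length or 0.0
                    groups.append((ci, cd + bl))
                for (ia, da), (ib, db) in itertools.combinations(groups, 2):
                    block = da[:, None] + db[None, :]
                    D[np.ix_(ia, ib)] = block
                    D[np.ix_(ib, ia)] = block.T
                store[id(node)] = (
                    np.concatenate([g[0] for g in groups]),
                    np.concatenate([g[1] for g in groups]),
                )
            self._patristic_cache = (tuple(labels), D)
        cached_labels, D = self._patristic_cache
        dm = DistanceMatrix(list(cached_labels), D.copy(), kind="patristic")
        if order is not None:
            dm = dm.reorder(order)
        return dm


@dataclass
class EnvTable:
    """Per-sample physicochemical measurements (one row per sample)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample id in environment table")
        if "pH" in self.data.columns:
            ph = self.data["pH"]
            if ((ph <= 0) | (ph >= 14)).any():
                bad = ph.index[(ph <= 0) | (ph >= 14)][0]
                raise ValidationError(f"pH out of (0, 14) for sample {bad!r}")
        conc = [c for c in self.data.columns if c not in ("pH", "temperature")]
        neg = self.data[conc] < 0
        if neg.any().any():
            col = neg.any()[neg.any()].index[0]
            raise ValidationError(f"negative value in variable {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Group label plus decimal-degree coordinates per sample."""

    data: pd.DataFrame  # columns: group, latitude, longitude

    def __post_init__(self) -> None:
        d = self.data
        if d.index.duplicated().any():
            raise ValidationError("duplicate sample id in metadata")
        for col in ("latitude", "longitude"):
            if col not in d.columns:
                continue
            lim = 90 if col == "latitude" else 180
            bad = d[col].abs() > lim
            if bad.any():
                raise ValidationError(
                    f"{col} out of range for sample {d.index[bad][0]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> pd.Series:
        return self.data["group"]


@dataclass
class DistanceMatrix:
    """Square symmetric matrix with ids and a kind tag."""

    ids: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if self.kind != "similarity" and (v < -1e-12).any():
            raise ValidationError("negative distances")
        if self.kind == "bray_curtis" and (v > 1 + 1e-12).any():
            raise ValidationError("Bray-Curtis values must lie in [0, 1]")
        self.values = v
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in pair order (i < j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_index(self) -> list[tuple[str, str]]:
        return [
            (self.ids[i], self.ids[j])
            for i, j in zip(*np.triu_indices(self.n, k=1))
        ]

    def reorder(self, order) -> "DistanceMatrix":
        order = list(order)
        pos = {lab: i for i, lab in enumerate(self.ids)}
        missing = [o for o in order if o not in pos]
        if missing:
            raise ValidationError(f"id {missing[0]!r} absent from matrix")
        idx = np.array([pos[o] for o in order])
        return DistanceMatrix(order, self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = None
    return df


def read_community_table(
    path,
    orientation: str = "samples_by_asvs",
    group: pd.Series | None = None,
) -> CommunityTable:
    """Read a count TSV; ``orientation`` declares which axis is on rows.

    ``orientation='asvs_by_samples'`` accepts the transposed (BIOM-style
    dense) layout and normalizes it to samples x ASVs.
    """
    df = _read_tsv(path)
    if orientation not in ("samples_by_asvs", "asvs_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "asvs_by_samples":
        df = df.T
    bad = df.map(lambda v: isinstance(v, str))
    if bad.any().any():
        r = bad.any(axis=1)
        c = bad.loc[r].any()
        raise ValidationError(
            f"non-numeric count at sample {df.index[r][0]!r}, "
            f"ASV {c[c].index[0]!r}"
        )
    table = CommunityTable(df, group)
    logger.info(
        "read community table: %d samples, %d ASVs, %d reads",
        table.n_samples, table.n_asvs, int(table.counts.to_numpy().sum()),
    )
    return table


def read_env_table(path) -> EnvTable:
    return EnvTable(_read_tsv(path))


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None,
                index_label=None) -> None:
    """Write a TSV with a '#'-comment provenance header line."""
    header = f"# plankton_assembly seed={seed} config_hash={config_hash}\n"
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index_label=index_label)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def write_community_table(table: CommunityTable, path, seed=None,
                          config_hash=None) -> None:
    write_table(table.counts, path, seed=seed, config_hash=config_hash,
                index_label="sample_id")


# ---------------------------------------------------------------------------
# filtering / rarefaction / alignment
# ---------------------------------------------------------------------------

def filter_low_count_asvs(table: CommunityTable, min_reads: int = 20
                          ) -> CommunityTable:
    """Drop ASVs whose total count across all samples is below ``min_reads``.

    Default mirrors the common denoising convention of discarding ASVs with
    fewer than 20 reads overall.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.counts.sum(axis=0)
    keep = totals >= min_reads
    if not keep.any():
        raise ValidationError(
            f"min_reads={min_reads} removes every ASV"
        )
    out = CommunityTable(table.counts.loc[:, keep].copy(), table.group)
    emptied = out.sample_totals() == 0
    if emptied.any():
        logger.warning(
            "samples left empty by ASV filter: %s",
            ", ".join(map(str, emptied.index[emptied])),
        )
    return out


def rarefy(table: CommunityTable, depth: int | str = "auto_min",
           seed: int | None = None) -> CommunityTable:
    """Subsample every sample without replacement to a common depth.

    ``depth='auto_min'`` uses the minimum sample total. All-zero ASV columns
    are dropped afterwards. Reproducible under a fixed ``seed``.
    """
    totals = table.sample_totals()
    if depth == "auto_min":
        depth = int(totals.min())
    depth = int(depth)
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValidationError(
            "samples shallower than requested depth: "
            + ", ".join(f"{s} ({t})" for s, t in shallow.items())
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.counts.index,
                      columns=table.counts.columns)
    return CommunityTable(df, table.group).drop_empty_asvs()


def align_inputs(
    table: CommunityTable,
    tree: PhyloTree | None = None,
    env: EnvTable | None = None,
    meta: SampleMetadata | None = None,
):
    """Restrict all artifacts to shared samples and to ASVs present as tips.

    Returns the aligned ``(table, tree, env, meta)`` tuple; absent artifacts
    pass through as None.
    """
    samples = list(table.sample_ids)
    for other in (env, meta):
        if other is not None:
            shared = [s for s in samples if s in set(other.sample_ids)]
            dropped = set(samples) - set(shared)
            if dropped:
                logger.warning("dropping samples without metadata: %s",
                               sorted(dropped))
            samples = shared
    if not samples:
        raise ValidationError("no samples shared across input artifacts")
    table = table.subset_samples(samples)

    if tree is not None:
        tips = set(tree.tip_labels)
        shared_asvs = [a for a in table.asv_ids if a in tips]
        if not shared_asvs:
            raise ValidationError("no ASVs shared between table and tree")
        extra_tips = tips - set(table.asv_ids)
        if extra_tips:
            logger.warning("pruning %d tree tips absent from table",
                           len(extra_tips))
        if len(shared_asvs) < table.n_asvs:
            logger.warning("dropping %d table ASVs absent from tree",
                           table.n_asvs - len(shared_asvs))
        table = CommunityTable(table.counts.loc[:, shared_asvs].copy(),
                               table.group)
        if extra_tips:
            tree = tree.prune_to(shared_asvs)

    if env is not None:
        env = EnvTable(env.data.loc[samples].copy())
    if meta is not None:
        meta = SampleMetadata(meta.data.loc[samples].copy())
    return table, tree, env, meta


# ---------------------------------------------------------------------------
# geographic distance
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance(meta: SampleMetadata) -> DistanceMatrix:
    d = meta.data
    for col in ("latitude", "longitude"):
        if col not in d.columns or d[col].isna().any():
            missing = (d.index[d[col].isna()][0]
                       if col in d.columns else d.index[0])
            raise ValidationError(f"missing {col} for sample {missing!r}")
    lat = np.radians(d["latitude"].to_numpy())
    lon = np.radians(d["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return DistanceMatrix(list(d.index), km, kind="geographic_km")
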