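"""End-to-end orchestration: config validation, per-group analysis loop,
consolidated report.

A run reads the count table, tree and metadata/environment tables, applies
the read filter (and optional rarefaction), then per group executes the
toggled stages: alpha/beta diversity, decomposition, distance decay,
null-model assembly partitioning, neutral fit, niche breadth, network, TLI
and heterogeneity. Every stage derives its own seed from the master seed by
stable hashing of (seed, stage, group), so adding or removing stages never
perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import assembly_table, process_fractions
from .betadiv import (
    bray_curtis_matrix, decompose_beta, distance_decay,
    mantel_correlogram, niche_distance, niche_values, shannon,
    similarity_from,
)
from .core_io import (
    CommunityTable, ValidationError, align_inputs, filter_low_count_asvs,
    geographic_distance, rarefy, read_community_table, read_env_table,
    read_metadata, write_table,
)
from .network import build_network, filter_prevalence, network_stats, \
    spearman_matrix
from .neutral import fit_sloan_model, levins_b
from .trophic import compute_tli, env_heterogeneity

logger = logging.getLogger("plankton_assembly")

ALL_ANALYSES = (
    "alpha", "beta", "decompose", "ddr", "correlogram", "assembly",
    "neutral", "niche", "network", "tli", "heterogeneity",
)

DEFAULT_CONFIG: dict = {
    "inputs": {
        "counts": None, "tree": None, "env": None, "metadata": None,
        "orientation": "samples_by_asvs",
    },
    "filters": {
        "min_reads": 20,
        "rarefy": True,
        "rarefy_depth": "auto_min",
        "filter_before_rarefy": True,
    },
    "analyses": list(ALL_ANALYSES),
    "params": {
        "n_null": 999,
        "n_perm": 999,
        "null_mode": "shared",
        "weighted_bmntd": True,
        "rho_min": 0.6,
        "p_max": 0.01,
        "prevalence_fraction": 0.5,
        "network_top_k": 5,
        "correlogram_classes": None,
    },
    "seed": 1,
    "outdir": "plankton_assembly_out",
}

_PARAM_DOMAINS = {
    ("filters", "min_reads"): lambda v: isinstance(v, int) and v >= 0,
    ("filters", "rarefy"): lambda v: isinstance(v, bool),
    ("filters", "filter_before_rarefy"): lambda v: isinstance(v, bool),
    ("params", "n_null"): lambda v: isinstance(v, int) and v >= 99,
    ("params", "n_perm"): lambda v: isinstance(v, int) and v >= 1,
    ("params", "null_mode"): lambda v: v in ("shared", "per_pair"),
    ("params", "weighted_bmntd"): lambda v: isinstance(v, bool),
    ("params", "rho_min"): lambda v: 0 <= v <= 1,
    ("params", "p_max"): lambda v: 0 < v <= 1,
    ("params", "prevalence_fraction"): lambda v: 0 < v < 1,
    ("params", "network_top_k"): lambda v: isinstance(v, int) and v >= 1,
    ("seed",): lambda v: isinstance(v, int),
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def validate_config(source) -> RunConfig:
    """Validate a YAML path or dict; raises ConfigError listing every
    violation (unknown keys, out-of-domain values)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    errors: list[str] = []
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, value in raw.items():
        if section not in merged:
            errors.append(f"unknown config key {section!r}")
            continue
        if isinstance(merged[section], dict):
            if not isinstance(value, dict):
                errors.append(f"section {section!r} must be a mapping")
                continue
            for k, v in value.items():
                if k not in merged[section]:
                    errors.append(f"unknown config key {section}.{k}")
                else:
                    merged[section][k] = v
        else:
            merged[section] = value
    for path, check in _PARAM_DOMAINS.items():
        node = merged
        for k in path[:-1]:
            node = node[k]
        v = node[path[-1]]
        if not check(v):
            errors.append(f"config value out of domain: "
                          f"{'.'.join(path)} = {v!r}")
    bad = [a for a in merged["analyses"] if a not in ALL_ANALYSES]
    for a in bad:
        errors.append(f"unknown analysis toggle {a!r}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(merged)


def stage_seed(master: int, stage: str, group: str = "") -> int:
    """Stable per-stage seed: SHA-256 of (master, stage, group), < 2^31."""
    key = f"{master}|{stage}|{group}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def run_pipeline(config: RunConfig | dict, table: CommunityTable = None,
                 tree=None, env=None, meta=None) -> dict:
    """Execute the configured stages and write per-stage outputs.

    Inputs may be passed pre-loaded (for library use) or read from the
    configured paths. Returns the consolidated report dict (also written as
    ``report.json`` in the output directory).
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    cfg = config.data
    seed = cfg["seed"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()

    if table is None:
        if cfg["inputs"]["counts"] is None:
            raise ValidationError("no count table provided")
        table = read_community_table(cfg["inputs"]["counts"],
                                     cfg["inputs"]["orientation"])
    from .core_io import PhyloTree
    if tree is None and cfg["inputs"]["tree"]:
        tree = PhyloTree.from_newick(cfg["inputs"]["tree"])
    if env is None and cfg["inputs"]["env"]:
        env = read_env_table(cfg["inputs"]["env"])
    if meta is None and cfg["inputs"]["metadata"]:
        meta = read_metadata(cfg["inputs"]["metadata"])
    if meta is not None and table.group is None:
        table = CommunityTable(table.counts, meta.group)

    table, tree, env, meta = align_inputs(table, tree, env, meta)

    f = cfg["filters"]
    if f["filter_before_rarefy"]:
        table = filter_low_count_asvs(table, f["min_reads"])
        if f["rarefy"]:
            table = rarefy(table, f["rarefy_depth"],
                           stage_seed(seed, "rarefy"))
    else:
        if f["rarefy"]:
            table = rarefy(table, f["rarefy_depth"],
                           stage_seed(seed, "rarefy"))
        table = filter_low_count_asvs(table, f["min_reads"])
    if tree is not None:
        table, tree, env, meta = align_inputs(table, tree, env, meta)

    analyses = set(cfg["analyses"])
    p = cfg["params"]
    report: dict = {
        "provenance": {
            "seed": seed, "config_hash": chash,
            "version": __version__,
            "n_samples": table.n_samples, "n_asvs": table.n_asvs,
        },
        "groups": {},
    }
    groups = (sorted(table.group.unique()) if table.group is not None
              else ["all"])

    def _write(df, name):
        write_table(df, outdir / f"{name}.tsv", seed=seed, config_hash=chash)

    for g in groups:
        sub = (table if g == "all"
               else table.subset_samples(
                   table.group.index[table.group == g]).drop_empty_asvs())
        genv = env if env is None or g == "all" else \
            type(env)(env.data.loc[sub.sample_ids].copy())
        gmeta = meta if meta is None or g == "all" else \
            type(meta)(meta.data.loc[sub.sample_ids].copy())
        gtree = tree if tree is None else tree.prune_to(sub.asv_ids)
        gr: dict = {}
        try:
            _run_group(gr, g, sub, gtree, genv, gmeta, analyses, p, seed,
                       _write)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage failure in group {g!r}: {exc}") from exc
        report["groups"][g] = gr

    # sample-level / cross-group stages
    if "tli" in analyses and env is not None:
        tli = compute_tli(env)
        _write(pd.DataFrame({"TLI": tli.composite,
                             "class": tli.trophic_class,
                             "bloom": tli.bloom}), "tli")
        report["tli"] = {
            "mean": round(float(tli.composite.mean()), 2),
            "range": [round(float(tli.composite.min()), 2),
                      round(float(tli.composite.max()), 2)],
            "bloom_samples": int(tli.bloom.sum()),
        }
    if "heterogeneity" in analyses and env is not None and \
            table.group is not None and table.group.nunique() > 1:
        het = env_heterogeneity(env, table.group, n_perm=p["n_perm"],
                                seed=stage_seed(seed, "heterogeneity"))
        _write(het.per_group, "heterogeneity")
        _write(het.contrasts, "heterogeneity_contrasts")
        report["heterogeneity"] = het.per_group[
            "mean_dist_to_centroid"].round(4).to_dict()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _run_group(gr, g, sub, tree, env, meta, analyses, p, seed, _write):
    if "alpha" in analyses:
        h = shannon(sub)
        gr["shannon_mean"] = round(float(h.mean()), 4)
        _write(h.to_frame(), f"shannon_{g}")
    bc = None
    if analyses & {"beta", "ddr", "assembly"}:
        bc = bray_curtis_matrix(sub)
        if "beta" in analyses:
            _write(bc.to_frame(), f"bray_curtis_{g}")
    if "decompose" in analyses:
        dec = decompose_beta(sub)
        _write(dec.pairs, f"beta_decomposition_{g}")
        valid = dec.pairs.dropna(subset=["D"])
        nonzero = valid[valid["D"] > 0]
        gr["mean_D"] = round(float(valid["D"].mean()), 4)
        gr["mean_repl_over_d"] = round(
            float((nonzero["Repl"] / nonzero["D"]).mean()), 4)
    if "ddr" in analyses and meta is not None and \
            "latitude" in meta.data.columns:
        geo = geographic_distance(meta)
        fit = distance_decay(similarity_from(bc), geo,
                             n_perm=p["n_perm"],
                             seed=stage_seed(seed, "ddr", g))
        gr["ddr"] = {"slope": fit.slope, "r_squared": fit.r_squared,
                     "mantel_r": fit.mantel_r, "mantel_p": fit.mantel_p}
    if "correlogram" in analyses and tree is not None and env is not None:
        nv = niche_values(sub, env)
        nd = niche_distance(nv)
        pdm = tree.patristic_matrix(order=list(nv.index))
        cg = mantel_correlogram(nd, pdm,
                                n_classes=p["correlogram_classes"],
                                n_perm=p["n_perm"],
                                seed=stage_seed(seed, "correlogram", g))
        _write(cg.classes, f"correlogram_{g}")
        first = cg.classes.dropna(subset=["mantel_r"]).iloc[0]
        gr["correlogram_first_class"] = {
            "mantel_r": float(first["mantel_r"]),
            "p_corrected": float(first["p_corrected"]),
        }
    if "assembly" in analyses and tree is not None:
        at = assembly_table(sub, tree, n_null=p["n_null"],
                            weighted=p["weighted_bmntd"],
                            seed=stage_seed(seed, "assembly", g),
                            within_groups=False,
                            null_mode=p["null_mode"])
        _write(at, f"assembly_pairs_{g}")
        at["process_group"] = g
        fr = process_fractions(at, group_col="process_group")
        _write(fr.table, f"process_fractions_{g}")
        row = fr.table.iloc[0]
        gr["process_fractions"] = {
            k: round(float(row[k]), 2) for k in (
                "homogeneous_selection", "variable_selection",
                "dispersal_limitation", "homogenizing_dispersal",
                "undominated", "deterministic", "stochastic",
            )
        }
        gr["sorting_dispersal_ratio"] = float(
            row["sorting_dispersal_ratio"])
    if "neutral" in analyses:
        fit = fit_sloan_model(sub)
        _write(fit.taxa, f"neutral_fit_{g}")
        gr["neutral"] = {"m": fit.m, "Nm": fit.Nm, "N": fit.N,
                         "r_squared": fit.r_squared}
    if "niche" in analyses:
        nb = levins_b(sub)
        _write(nb.bcom, f"niche_breadth_{g}")
        gr["bcom_weighted"] = float(nb.bcom["bcom_weighted"].iloc[0])
    if "network" in analyses:
        try:
            prev = filter_prevalence(sub, p["prevalence_fraction"])
            rho, pv = spearman_matrix(prev)
            edges = build_network(rho, pv, p["rho_min"], p["p_max"])
            if not edges.empty:
                st = network_stats(edges, k=p["network_top_k"])
                _write(edges, f"network_edges_{g}")
                gr["network"] = {
                    "n_nodes": st.n_nodes, "n_edges": st.n_edges,
                    "pos_neg_ratio": st.pos_neg_ratio,
                    "core_nodes": st.core_nodes,
                }
            else:
                gr["network"] = {"n_nodes": 0, "n_edges": 0}
        except ValidationError as exc:
            logger.warning("network stage skipped for %s: %s", g, exc)
            gr["network"] = {"skipped": str(exc)}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
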