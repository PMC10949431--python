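"""End-to-end orchestration of the temporal microbiome analysis.

One configuration drives the full stage order on real or simulated inputs,
per habitat x domain community: subsample (SRS) -> diversity / Bray-Curtis
-> PERMANOVA / PERMDISP -> climate PCA + dbRDA -> dissimilarity-time decay
-> core delineation (occupancy, contribution C, temporal groups) -> per-
habitat cross-domain network + hubs -> fungal guild abundances + ANOVA.
Every stage writes its result tables under the output directory and records
its parameters, seeds and row counts in ``manifest.json``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .core import (
    abundance_occupancy,
    cluster_core_groups,
    core_contribution,
    select_core,
)
from .diversity import bray_curtis, hill_diversity_table
from .guilds import anova_three_way, assign_guilds, guild_abundance, tukey_hsd
from .multivariate import climate_pca, dbrda, permanova, permdisp
from .network import NetworkConfig, estimate_network, identify_hubs
from .normalize import SubsampleConfig, srs_subsample
from .synthetic import (
    SynthConfig,
    generate_climate,
    generate_dataset,
    generate_guild_table,
)
from .temporal import build_decay_table, env_dissimilarity_vs_time, fit_time_decay

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "output_dir",
    "seed",
    "tables",
    "simulate",
    "subsample",
    "permanova",
    "dbrda",
    "decay",
    "core",
    "network",
    "guilds",
    "climate",
}

DEFAULT_TABLES = [
    {"habitat": h, "domain": d}
    for h in mio.HABITATS
    for d in mio.DOMAINS
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and community."""


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return validate_config(config)


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
    config = dict(config)
    config.setdefault("output_dir", "microtempo_out")
    config.setdefault("seed", 0)
    config.setdefault("tables", DEFAULT_TABLES)
    config.setdefault("simulate", {})
    config.setdefault("subsample", {})
    config.setdefault("permanova", {})
    config.setdefault("dbrda", {})
    config.setdefault("decay", {})
    config.setdefault("core", {})
    config.setdefault("network", {})
    config.setdefault("guilds", {})
    config.setdefault("climate", {})
    for key in ("simulate", "subsample", "permanova", "dbrda", "decay",
                "core", "network", "guilds", "climate"):
        if not isinstance(config[key], dict):
            raise ValueError(f"pipeline config key {key!r} must be a mapping")
    return config


def _stage(manifest: dict, name: str, context: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed for {context}: {exc}") from exc
    manifest["stages"].append(
        {"stage": name, "context": context, "seconds": round(time.perf_counter() - t0, 3)}
    )
    return result


def run_pipeline(config: dict, write: bool = True) -> dict:
    """Run every stage for every configured community; returns the manifest.

    The manifest also carries the headline numbers of each stage (PERMANOVA
    R2/p per term, decay slope and CI, core contribution C, network size,
    hub count) so a run is summarizable without re-reading result tables.
    """
    config = validate_config(config)
    out_dir = Path(config["output_dir"])
    seed = int(config["seed"])
    manifest: dict = {
        "seed": seed,
        "parameters": {k: config[k] for k in
                       ("simulate", "subsample", "permanova", "dbrda",
                        "core", "network")},
        "stages": [],
        "communities": {},
        "climate": {},
    }

    # --- simulate all communities (shared date design and climate)
    datasets = {}
    base_cfg = dict(config["simulate"])
    for i, spec in enumerate(config["tables"]):
        habitat, domain = spec["habitat"], spec["domain"]
        cfg = SynthConfig(
            habitat=habitat,
            domain=domain,
            asv_prefix=("B" if domain == "bacteria_archaea" else "F") + "ASV",
            seed=seed + 17 * i,
            **base_cfg,
        )
        datasets[(habitat, domain)] = _stage(
            manifest, "simulate", f"{habitat}/{domain}", generate_dataset, cfg
        )
    dates = sorted({
        pd.Timestamp(d)
        for (_, meta, _, _) in datasets.values()
        for d in meta["date"].unique()
    })
    climate = _stage(
        manifest, "climate", "shared", generate_climate, dates,
        seed=seed + 1000, **config["climate"],
    )

    # --- climate PCA + environmental time-decay diagnostic (shared)
    pca = _stage(manifest, "climate_pca", "shared", climate_pca, climate, dates)
    env_table, env_osc = _stage(
        manifest, "env_dissimilarity", "shared",
        env_dissimilarity_vs_time, climate, dates,
    )
    manifest["climate"] = {
        "pc_variance": [round(float(v), 4) for v in pca.variance_explained],
        "oscillation_diagnostic": round(float(env_osc), 4),
    }

    perm_cfg = {"n_perm": 199, "terms": ["season", "year", "season:year", "species"],
                **config["permanova"]}
    dbrda_cfg = {"n_perm": 99, **config["dbrda"]}
    core_cfg = {"threshold": 0.70, "k_max": 8, "gain_threshold": 0.05,
                **config["core"]}

    per_habitat_tables: dict[str, dict] = {}
    for (habitat, domain), (table, metadata, taxonomy, truth) in datasets.items():
        ctx = f"{habitat}/{domain}"
        entry: dict = {}
        cdir = out_dir / habitat / domain

        # SRS to the observed minimum depth (the study's rule) unless fixed
        c_min = config["subsample"].get("c_min", "auto")
        if c_min == "auto":
            c_min = int(table.counts.sum(axis=0).min())
        sub = _stage(
            manifest, "srs_subsample", ctx, srs_subsample, table,
            SubsampleConfig(c_min=int(c_min), seed=seed + 7),
        )
        entry["c_min"] = int(c_min)
        entry["n_samples"] = len(sub.sample_ids)
        meta_sub = metadata.loc[sub.sample_ids]

        diversity = _stage(manifest, "diversity", ctx, hill_diversity_table, sub)
        d_bc = _stage(manifest, "bray_curtis", ctx, bray_curtis, sub)

        perm = _stage(
            manifest, "permanova", ctx, permanova, d_bc, meta_sub,
            terms=list(perm_cfg["terms"]), n_perm=int(perm_cfg["n_perm"]),
            seed=seed + 11,
        )
        disp = _stage(
            manifest, "permdisp", ctx, permdisp, d_bc, meta_sub["season"]
        )
        entry["permanova"] = {
            t: {"R2": round(perm.r2(t), 4), "p": round(perm.p(t), 4)}
            for t in perm_cfg["terms"]
        }
        entry["permdisp"] = {"F": round(disp.F, 4), "p": round(disp.p, 4)}

        # dbRDA constrained on season, year, species and climate PC1/PC2
        constraints = meta_sub[["season", "species"]].astype(str).copy()
        constraints["year"] = meta_sub["year"].astype(str)
        pc = pca.date_scores.loc[meta_sub["date"]]
        constraints["PC1"] = pc["PC1"].to_numpy()
        constraints["PC2"] = pc["PC2"].to_numpy()
        ordination = _stage(
            manifest, "dbrda", ctx, dbrda, d_bc, constraints,
            n_perm=int(dbrda_cfg["n_perm"]), seed=seed + 13,
        )
        entry["dbrda_constrained_fraction"] = round(
            ordination.constrained_inertia / ordination.total_inertia, 4
        )

        decay_table = _stage(
            manifest, "decay_table", ctx, build_decay_table, d_bc, meta_sub
        )
        decay = _stage(manifest, "decay_fit", ctx, fit_time_decay, decay_table)
        entry["decay"] = {
            "slope_per_365d": round(decay.slope, 4),
            "ci": [round(decay.ci_low, 4), round(decay.ci_high, 4)],
            "p": round(decay.p, 6),
        }

        occ = _stage(manifest, "occupancy", ctx, abundance_occupancy, sub, meta_sub)
        core = _stage(manifest, "select_core", ctx, select_core, occ,
                      float(core_cfg["threshold"]))
        entry["n_core"] = len(core)
        if core:
            pairs, c_mean = _stage(
                manifest, "core_contribution", ctx, core_contribution,
                sub, core, meta_sub,
            )
            entry["core_contribution_C"] = round(c_mean, 4)
        if len(core) >= 2:
            groups = _stage(
                manifest, "core_groups", ctx, cluster_core_groups, sub, meta_sub,
                core, int(core_cfg["k_max"]), float(core_cfg["gain_threshold"]),
            )
            entry["core_k"] = int(groups.k)
            # group-level ANOVA on per-sample summed core-group abundance
            if write:
                mio.write_table(groups.z_profiles, cdir / "core_profiles.tsv")
                mio.write_table(
                    groups.labels.to_frame(), cdir / "core_groups.tsv"
                )

        if write:
            mio.write_table(diversity, cdir / "diversity.tsv", index=False)
            mio.write_distance_matrix(d_bc, cdir / "bray_curtis.tsv")
            mio.write_table(perm.table, cdir / "permanova.tsv")
            mio.write_table(ordination.term_table, cdir / "dbrda_terms.tsv")
            mio.write_table(decay_table, cdir / "decay_table.tsv", index=False)
            mio.write_table(occ, cdir / "occupancy.tsv", index=False)
            mio.write_count_table(sub, cdir / "counts_srs.tsv")

        per_habitat_tables.setdefault(habitat, {})[domain] = (
            table, metadata, taxonomy, core
        )
        manifest["communities"][ctx] = entry

    # --- cross-domain networks per habitat (needs both domains present)
    net_cfg_dict = dict(config["network"])
    run_networks = net_cfg_dict.pop("enabled", True)
    for habitat, doms in per_habitat_tables.items():
        if not run_networks or set(doms) != set(mio.DOMAINS):
            continue
        bact, bact_meta, _, bact_core = doms["bacteria_archaea"]
        fung, fung_meta, _, fung_core = doms["fungi"]
        net_config = NetworkConfig(seed=seed + 19, **net_cfg_dict)
        net = _stage(
            manifest, "network", habitat, estimate_network, bact, fung, net_config
        )
        hubs = _stage(
            manifest, "hubs", habitat, identify_hubs, net, [bact, fung],
            sorted(set(bact_core) | set(fung_core)),
        )
        manifest["communities"][habitat + "/network"] = {
            "n_nodes": int(len(net.nodes)),
            "n_edges": int(len(net.edges)),
            "lambda_selected": float(net.lambda_selected),
            "n_hubs": int(len(hubs)),
        }
        if write:
            ndir = out_dir / habitat
            mio.write_table(net.edges, ndir / "network_edges.tsv", index=False)
            mio.write_table(net.nodes, ndir / "network_centrality.tsv")
            mio.write_table(hubs, ndir / "network_hubs.tsv")

    # --- fungal guilds: lookup join, abundances, three-way ANOVA + Tukey
    for (habitat, domain), (table, metadata, taxonomy, truth) in datasets.items():
        if domain != "fungi":
            continue
        ctx = f"{habitat}/{domain}"
        guild_table = _stage(
            manifest, "guild_table", ctx, generate_guild_table, taxonomy,
            seed + 23, **config["guilds"],
        )
        assignment = _stage(
            manifest, "assign_guilds", ctx, assign_guilds, taxonomy, guild_table
        )
        gab = _stage(
            manifest, "guild_abundance", ctx, guild_abundance, table, assignment
        )
        # ANOVA on the most abundant classified guild
        classified = gab.drop(index="unclassified", errors="ignore")
        if len(classified) > 0:
            top = classified.mean(axis=1).idxmax()
            response = classified.loc[top]
            aov = _stage(
                manifest, "guild_anova", ctx, anova_three_way, response, metadata
            )
            cells = (
                metadata.loc[response.index, "season"].astype(str)
                + "_"
                + metadata.loc[response.index, "year"].astype(str)
            )
            _, letters = _stage(
                manifest, "guild_tukey", ctx, tukey_hsd, response, cells
            )
            manifest["communities"][ctx]["guild_anova"] = {
                "guild": str(top),
                "season_p": float(aov.loc["season", "p"]),
            }
            if write:
                gdir = out_dir / habitat / domain
                mio.write_table(gab, gdir / "guild_abundance.tsv")
                mio.write_table(aov, gdir / "guild_anova.tsv")
                mio.write_table(letters.to_frame(), gdir / "guild_tukey_letters.tsv")

    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
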