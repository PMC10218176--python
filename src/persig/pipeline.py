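"""End-to-end orchestration: simulate (or load) -> DEP calling -> mean
profile -> enrichment -> overlap significance -> network statistics ->
tissue bridging census, with a deterministic report bundle per stage and
a run manifest.

Reports are plain TSV/JSON with sorted keys and no timestamps, so two
runs with identical (inputs, config, seed) produce byte-identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dep, enrich, io, network, overlap
from .errors import PipelineError
from .simulate import SimConfig, simulate_gene_set_collection, \
    simulate_perturbagen_experiment, simulate_tissue_networks

logger = logging.getLogger(__name__)

STAGES = ["simulate", "dep_calling", "mean_profile", "enrichment",
          "overlap", "network_bridging"]


def default_config() -> dict:
    """Self-contained simulation-backed run configuration."""
    return {
        "alpha": 0.05,
        "n_perm": 200,
        "n_rand": 200,
        "sim": {"n_proteins": 600, "dep_fraction": 0.1,
                "effect_size_log2": 2.0, "noise_sd_log2": 0.4},
        "gene_sets": {"n_background": 20, "set_size_range": [15, 60],
                      "planted_size": 40, "planted_purity": 0.9},
        "tissues": {"n_tissues": 30, "universe_size": 80,
                    "edge_density": 0.04, "n_planted_bridges": 2,
                    "bridge_tissue_fraction": 0.5,
                    "max_nodes": 20, "min_confidence": 0.5},
    }


def _config_hash(config: dict, seed: int) -> str:
    canon = json.dumps({"config": config, "seed": seed}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: dict | None = None, out_dir="persig_run",
                 seed: int = 0) -> dict:
    """Run every stage on a simulated experiment and write the bundle.

    Returns the manifest dict (also written as ``manifest.json``).  A
    stage failure raises :class:`PipelineError` naming the stage, with
    the outputs of completed stages preserved on disk.
    """
    config = config if config is not None else default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in STAGES}
    manifest = {
        "persig_version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config_sha256": _config_hash(config, seed),
        "stages": [],
    }
    alpha = config.get("alpha", 0.05)
    state: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                io.write_json(manifest, out / "manifest.json")
                raise PipelineError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name,
                        time.perf_counter() - t0)
            manifest["stages"].append(name)
        return wrap

    @stage("simulate")
    def _simulate():
        sim_cfg = SimConfig(seed=stage_seeds["simulate"],
                            **config.get("sim", {}))
        matrix, truth = simulate_perturbagen_experiment(sim_cfg)
        state["matrix"], state["truth"], state["sim_cfg"] = matrix, truth, sim_cfg
        io.write_intensity_matrix(matrix, out / "intensity_matrix.tsv",
                                  out / "sample_annotation.tsv")

    @stage("dep_calling")
    def _dep():
        matrix, sim_cfg = state["matrix"], state["sim_cfg"]
        tables: dict[tuple, pd.DataFrame] = {}
        for dose in sim_cfg.doses:
            for comp in sim_cfg.compartments:
                ratios = dep.compute_log_ratios(matrix, dose, comp)
                tables[(dose, comp)] = dep.call_deps(ratios, alpha=alpha)
        state["dep_tables"] = tables
        summary = [{"dose": d, "compartment": c,
                    "n_dep": int(t["is_dep"].sum()),
                    "n_down": int((t.loc[t["is_dep"], "polarity"] == "down").sum())}
                   for (d, c), t in tables.items()]
        # per-dose totals pool the three compartment extracts (union)
        per_dose = {}
        for (d, c), t in tables.items():
            per_dose.setdefault(d, set()).update(dep.dep_ids(t))
        io.write_json({"cells": summary, "dose_union_counts":
                       {str(d): len(s) for d, s in per_dose.items()},
                       "dose_pooling": "union_across_compartments"},
                      out / "dep_summary.json")
        for (d, c), t in tables.items():
            t[dep.DEP_COLUMNS].to_csv(out / f"dep_d{d:g}_{c}.tsv", sep="\t")
        state["global_dep_ids"] = set().union(*(dep.dep_ids(t)
                                                for t in tables.values()))

    @stage("mean_profile")
    def _profile():
        sim_cfg = state["sim_cfg"]
        tables = state["dep_tables"]
        ref_dose = max(sim_cfg.doses)
        profile = dep.mean_profile([tables[(ref_dose, c)]
                                    for c in sim_cfg.compartments])
        state["profile"] = profile
        profile.to_csv(out / "mean_profile.tsv", sep="\t")
        cores = {}
        for comp in sim_cfg.compartments:
            core, polarity = dep.consistency_core(
                {d: tables[(d, comp)] for d in sim_cfg.doses})
            cores[comp] = sorted(core)
            polarity.to_csv(out / f"core_polarity_{comp}.tsv", sep="\t")
        state["cores"] = cores
        io.write_json({"core_sizes": {c: len(v) for c, v in cores.items()},
                       "cores": cores}, out / "consistency_cores.json")

    @stage("enrichment")
    def _enrichment():
        gs_cfg = config.get("gene_sets", {})
        truth, matrix = state["truth"], state["matrix"]
        sim_cfg = state["sim_cfg"]
        universe = matrix.protein_ids
        rng_local = np.random.default_rng(stage_seeds["enrichment"])
        dep_pool = sorted(truth.dep_ids(max(sim_cfg.doses),
                                        sim_cfg.compartments[0]))
        if dep_pool:
            size = min(gs_cfg.get("planted_size", 40), len(dep_pool))
            pool = dep_pool
        else:
            # null experiment: the "signature" is a random draw, so the
            # downstream overlap test exercises its calibrated null
            size = gs_cfg.get("planted_size", 40)
            pool = universe
        members = list(rng_local.choice(pool, size=size, replace=False))
        planted = [("PLANTED_SIGNATURE", members,
                    gs_cfg.get("planted_purity", 0.9) if dep_pool else 1.0)]
        truth.planted_sets = ["PLANTED_SIGNATURE"]
        collection = simulate_gene_set_collection(
            universe, gs_cfg.get("n_background", 20),
            tuple(gs_cfg.get("set_size_range", (15, 60))),
            planted=planted, seed=stage_seeds["enrichment"])
        state["collection"] = collection
        io.write_gmt(collection, out / "gene_sets.gmt")
        table = enrich.rank_collections(state["profile"], collection,
                                        n_perm=config.get("n_perm", 200),
                                        seed=stage_seeds["enrichment"])
        table.to_csv(out / "ks_ranking.tsv", sep="\t", index=False)
        ora = enrich.ora_enrichment(state["global_dep_ids"], collection,
                                    universe)
        ora.to_csv(out / "ora_results.tsv", sep="\t", index=False)
        state["ks_table"] = table

    @stage("overlap")
    def _overlap():
        truth, matrix = state["truth"], state["matrix"]
        universe = matrix.protein_ids
        signature = state["collection"]["PLANTED_SIGNATURE"].members \
            if "PLANTED_SIGNATURE" in state["collection"].set_names else set()
        results = {}
        if signature:
            t = overlap.overlap_test(state["global_dep_ids"], signature,
                                     universe, randomize="A",
                                     n_rand=config.get("n_rand", 200),
                                     seed=stage_seeds["overlap"])
            results["dep_vs_planted_signature"] = asdict(t)
        io.write_json(results, out / "overlap_tests.json")
        state["overlap_results"] = results

    @stage("network_bridging")
    def _network():
        t_cfg = config.get("tissues", {})
        n_uni = t_cfg.get("universe_size", 80)
        uni = [f"N{i:04d}" for i in range(1, n_uni - 1)] + ["MDC1", "PHB"]
        n_planted = t_cfg.get("n_planted_bridges", 2)
        planted = [f"N{i:04d}" for i in range(1, n_planted + 1)]
        graphs = simulate_tissue_networks(
            uni, n_tissues=t_cfg.get("n_tissues", 30),
            seed_a="MDC1", seed_b="PHB", planted_bridges=planted,
            bridge_tissue_fraction=t_cfg.get("bridge_tissue_fraction", 0.5),
            edge_density=t_cfg.get("edge_density", 0.04),
            seed=stage_seeds["network_bridging"])
        state["truth"].planted_bridges = planted
        results = network.bridge_tissues(
            "MDC1", "PHB", graphs,
            max_nodes=t_cfg.get("max_nodes", 20),
            min_confidence=t_cfg.get("min_confidence", 0.5))
        census = network.bridge_frequency(results)
        census.to_frame().to_csv(out / "bridge_frequency.tsv", sep="\t",
                                 index=False)
        stats_table = network.compare_to_random_networks(
            ["MDC1", "PHB", *planted], graphs[0],
            n_rand=min(config.get("n_rand", 200), 200),
            seed=stage_seeds["network_bridging"])
        stats_table.to_csv(out / "network_stats.tsv", sep="\t")
        io.write_json({
            "n_connector_proteins": len(census.counts),
            "mean_tissue_count": census.mean,
            "sd_tissue_count": census.sd,
            "sem_tissue_count": census.sem,
            "selected": sorted(census.selected),
            "planted_bridges": planted,
        }, out / "bridge_census.json")
        state["census"] = census

    io.write_json(manifest, out / "manifest.json")
    return manifest
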