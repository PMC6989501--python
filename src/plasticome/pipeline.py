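"""End-to-end orchestration from one YAML/dict configuration.

Runs the full analysis in seven stages — simulate (or load), phenotypes,
alpha diversity, plasticity, clustering, differential abundance, community
statistics — writing every stage's outputs under one directory together with
a manifest (config copy, package version, input hashes, per-stage wall time
and output files).  Structured log lines record the counts entering and
leaving every filter so exclusions are auditable.  Reruns with the same
config are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import phenotype_table
from .community_stats import classify_pb, pb_ratio, pcoa, permanova
from .diffabund import run_da
from .diversity import METRICS, alpha_table, distance_matrix
from .io_formats import (
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_count_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from .phylo_cluster import cut_tree
from .plasticity import plasticity_table
from .synthio import SimConfig, simulate_cohort

__all__ = ["validate_config", "run_pipeline"]

logger = logging.getLogger("plasticome")

_DEFAULTS = {
    "metrics": ["braycurtis"],
    "scale": "proportion",
    "alpha_depth": 11000,
    "cluster_height": 0.1,
    "da": {"mode": "categorical", "level": "asv", "alpha": 0.05},
    "permanova": {"n_perm": 999, "seed": 0},
}


def validate_config(config: dict) -> dict:
    """Validate and normalise a run configuration before any computation."""
    cfg = {**_DEFAULTS, **config}
    cfg["da"] = {**_DEFAULTS["da"], **config.get("da", {})}
    cfg["permanova"] = {**_DEFAULTS["permanova"], **config.get("permanova", {})}
    if "outdir" not in cfg:
        raise ValueError("config requires an 'outdir'")
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError("config requires exactly one of 'simulate' or 'inputs'")
    for metric in cfg["metrics"]:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
    needs_tree = any("unifrac" in m for m in cfg["metrics"]) or cfg["da"]["level"] == "cluster"
    if has_inputs:
        required = {"counts", "samples", "subjects", "taxonomy"}
        missing = required - set(cfg["inputs"])
        if missing:
            raise ValueError(f"inputs missing: {sorted(missing)}")
        if "tree" not in cfg["inputs"]:
            # alpha diversity always needs the tree, as do UniFrac/cluster
            raise ValueError("inputs require a 'tree' path")
    if needs_tree and has_sim and cfg["simulate"].get("n_taxa", 1000) < 2:
        raise ValueError("tree-based analyses need at least two taxa")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run all stages; returns (and writes) the manifest dictionary."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "input_hashes": {},
        "stages": {},
    }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.outputs: list[str] = []
                logger.info("stage %s: start", name)
                return self_inner

            def write(self_inner, filename, writer):
                path = outdir / filename
                writer(path)
                self_inner.outputs.append(filename)
                return path

            def __exit__(self_inner, exc_type, exc, tb):
                if exc_type is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_manifest(outdir, manifest)
                    return False
                manifest["stages"][name] = {
                    "status": "ok",
                    "outputs": self_inner.outputs,
                    "wall_time_s": round(time.perf_counter() - self_inner.t0, 3),
                }
                logger.info("stage %s: done", name)
                return True

        return _Stage()

    # ---- stage 1: simulate or load ---------------------------------------
    with stage("simulate") as st:
        if "simulate" in cfg:
            sim_cfg = SimConfig(**cfg["simulate"])
            table, metadata, tree, taxonomy, truth = simulate_cohort(sim_cfg)
            st.write("counts.tsv", lambda p: write_count_table(table, p))
            st.write("tree.nwk", lambda p: write_tree(tree, str(p)))
            st.write("taxonomy.tsv", lambda p: write_taxonomy(taxonomy, p))
            st.write(
                "samples.tsv",
                lambda p: write_metadata(metadata, p, outdir / "subjects.tsv"),
            )
            st.outputs.append("subjects.tsv")
            st.write(
                "truth.json",
                lambda p: p.write_text(json.dumps(truth.to_json_dict(), indent=1)),
            )
            manifest["config"]["simulate"] = asdict(sim_cfg) | {
                "sigma_plasticity": (
                    sim_cfg.sigma_plasticity
                    if isinstance(sim_cfg.sigma_plasticity, (int, float))
                    else list(map(float, sim_cfg.subject_sigmas()))
                )
            }
        else:
            paths = {k: Path(v) for k, v in cfg["inputs"].items()}
            for key, path in paths.items():
                manifest["input_hashes"][key] = _sha256(path)
            table = read_count_table(paths["counts"])
            metadata = read_metadata(paths["samples"], paths["subjects"])
            tree = read_tree(str(paths["tree"]))
            taxonomy = read_taxonomy(paths["taxonomy"])
        logger.info(
            "cohort: %d samples x %d features, %d subjects",
            *table.shape,
            metadata.n_subjects,
        )

    # ---- stage 2: phenotypes ---------------------------------------------
    with stage("phenotypes") as st:
        phen = phenotype_table(metadata.subjects)
        st.write("phenotypes.tsv", lambda p: phen.to_csv(p, sep="\t"))

    # ---- stage 3: alpha diversity ----------------------------------------
    with stage("alpha") as st:
        alpha = alpha_table(table, tree, m=cfg["alpha_depth"])
        st.write("alpha.tsv", lambda p: alpha.to_csv(p, sep="\t", header=True))

    # ---- stage 4: beta diversity + plasticity ----------------------------
    with stage("plasticity") as st:
        for metric in cfg["metrics"]:
            dm = distance_matrix(table, metric, scale=cfg["scale"], tree=tree)
            frame = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
            st.write(f"beta_{metric}.tsv", lambda p, fr=frame: fr.to_csv(p, sep="\t"))
        pt = plasticity_table(
            table, metadata, metrics=cfg["metrics"], scale=cfg["scale"], tree=tree
        )
        st.write("plasticity.tsv", lambda p: pt.to_csv(p, sep="\t", index=False))

    # ---- stage 5: phylogenetic clustering --------------------------------
    with stage("cluster") as st:
        ca = cut_tree(tree, cfg["cluster_height"])
        logger.info(
            "cluster: %d ASVs -> %d clusters at h=%.3g",
            len(ca.assignment),
            ca.n_clusters,
            cfg["cluster_height"],
        )
        st.write("clusters.tsv", lambda p: ca.assignment.to_csv(p, sep="\t", header=True))
        st.write("cluster_summary.tsv", lambda p: ca.summary.to_csv(p, sep="\t"))

    # ---- stage 6: differential abundance ---------------------------------
    with stage("da") as st:
        da = run_da(
            table,
            metadata,
            phenotypes=phen,
            mode=cfg["da"]["mode"],
            level=cfg["da"]["level"],
            tree=tree,
            cut_height=cfg["cluster_height"],
            alpha=cfg["da"]["alpha"],
        )
        for diet, feats in da.filtered_features.items():
            logger.info("prevalence filter (%s): %d features retained", diet, len(feats))
        for name, tab in da.tables.items():
            safe = name.replace("|", "_").replace("-", "")
            st.write(f"da_{safe}.tsv", lambda p, t=tab: t.to_csv(p, sep="\t"))
        st.write(
            "da_hyperparameters.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        "consensus_rho": da.consensus_rho,
                        "d0": da.d0 if da.d0 != float("inf") else "inf",
                        "s0_sq": da.s0_sq,
                        "residual_df": da.residual_df,
                    },
                    indent=1,
                )
            ),
        )

    # ---- stage 7: community statistics -----------------------------------
    with stage("community") as st:
        pb = pb_ratio(table, taxonomy, metadata=metadata)
        classes = classify_pb(pb)
        pb_frame = pd.DataFrame({"pb_ratio": pb.per_subject, "pb_class": classes})
        st.write("pb_ratio.tsv", lambda p: pb_frame.to_csv(p, sep="\t"))
        dm = distance_matrix(table, "braycurtis", scale="asinh_normalized")
        ord_res = pcoa(dm, n_axes=2)
        st.write("pcoa.tsv", lambda p: ord_res.coordinates.to_csv(p, sep="\t"))
        grouping = metadata.subjects.loc[
            metadata.samples.loc[list(dm.ids), "subject_id"], "diet"
        ]
        grouping.index = list(dm.ids)
        perm = permanova(
            dm, grouping, n_perm=cfg["permanova"]["n_perm"], seed=cfg["permanova"]["seed"]
        )
        st.write(
            "permanova.json",
            lambda p: p.write_text(json.dumps(asdict(perm), indent=1)),
        )

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
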