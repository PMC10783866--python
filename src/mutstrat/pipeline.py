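"""End-to-end orchestration: filter -> split -> smooth -> score -> screen ->
cluster -> validate, plus the randomized-mutation null run and a synthetic
demo dataset.

The heavy lifting lives in the stage modules; this module wires them
together, persists every intermediate as TSV and writes a JSON manifest
(seeds, parameters, stage hashes) so a rerun with the same config is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io
from .cohort import filter_cohort, orient_cluster_labels, split_cohort
from .errors import DataError, ParameterError
from .network import GeneNetwork, RWRParams, load_network, smooth_profile
from .nullmodel import bootstrap_patients, permute_within_patients
from .sdcn import (
    SDCNConfig,
    build_knn_graph,
    select_n_clusters,
    standardize_features,
    train_sdcn,
)
from .ssgsea import GeneSetCollection, activity_matrix
from .survival import cox_fit, km_estimate, logrank_test, screen_prognostic_pathways
from .synthetic import SyntheticSpec, generate_cohort, generate_network, generate_pathways, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_frames", "run_null_pipeline", "make_demo"]

#: compact architecture used by the shipped analyses; panel-scale feature
#: spaces (~100 pathways) do not need the original 500-500-2000 encoder
COMPACT_SDCN = SDCNConfig(
    encoder_dims=(64, 32),
    embedding_dim=10,
    pretrain_epochs=300,
    train_epochs=300,
    learning_rate=1e-3,
    k_neighbors=10,
)


@dataclass(frozen=True)
class PipelineConfig:
    edges: str
    mutations: str
    clinical: str
    gmt: str
    outdir: str = "results/pipeline"
    score_threshold: float = 700.0
    rwr: RWRParams = field(default_factory=RWRParams)
    ssgsea_alpha: float = 0.25
    normalize_activity: bool = True
    screening_alpha: float = 0.05
    sdcn: SDCNConfig = COMPACT_SDCN
    k_range: tuple[int, int] = (2, 10)
    n_train: int | None = None
    split_seed: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "rwr" in raw:
            raw["rwr"] = RWRParams(**raw["rwr"])
        if "sdcn" in raw:
            raw["sdcn"] = SDCNConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["sdcn"].items()
            })
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for name in ("edges", "mutations", "clinical", "gmt"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise ParameterError(f"config path {name}={path!r} does not exist")


def _cluster_cohort(
    activity: pd.DataFrame,
    pathway_list: list[str],
    records: pd.DataFrame,
    sdcn_cfg: SDCNConfig,
    k_range: tuple[int, int],
) -> tuple[Any, dict[int, float]]:
    """Standardize -> KNN graph -> silhouette-selected SDCN -> orient."""
    missing = [p for p in pathway_list if p not in activity.columns]
    if missing:
        raise DataError(f"pathways absent from activity matrix: {missing[:5]}")
    feats = standardize_features(activity[pathway_list])
    graph = build_knn_graph(feats, sdcn_cfg.k_neighbors)
    best_k, assignment, per_k = select_n_clusters(feats, graph, sdcn_cfg, k_range)
    assignment = orient_cluster_labels(assignment, records)
    return assignment, per_k


def run_pipeline_frames(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    network: GeneNetwork,
    pathways: GeneSetCollection,
    config: PipelineConfig,
) -> dict[str, Any]:
    """In-memory pipeline; returns every stage result keyed by name."""
    results: dict[str, Any] = {}
    mutations, clinical = filter_cohort(mutations, clinical)
    results["n_samples"] = len(mutations)

    if config.n_train is not None:
        split = split_cohort(clinical, config.n_train, config.split_seed)
        cohorts = {"training": list(split.training), "testing": list(split.testing)}
        results["split"] = split
    else:
        cohorts = {"training": list(mutations.index)}

    smoothed = {}
    activities = {}
    for name, ids in cohorts.items():
        sm = smooth_profile(
            mutations.loc[ids], network, config.rwr, on_unmapped_sample="error"
        )
        smoothed[name] = sm
        # the normalization divisor is computed per cohort
        activities[name] = activity_matrix(
            sm.values, pathways, alpha=config.ssgsea_alpha,
            normalize=config.normalize_activity,
        ).scores
    results["smoothed"] = smoothed
    results["activity"] = activities

    train_act = activities["training"]
    train_rec = clinical.loc[train_act.index]
    screened = screen_prognostic_pathways(train_act, train_rec, alpha=config.screening_alpha)
    results["prognostic"] = screened
    if screened.empty:
        raise DataError("screening retained zero pathways; cannot cluster")
    pathway_list = list(screened.index)

    sdcn_cfg = replace(config.sdcn, seed=config.seed)
    results["assignments"] = {}
    results["per_k_silhouette"] = {}
    results["logrank"] = {}
    results["km"] = {}
    results["cox"] = {}
    for name in cohorts:
        act = activities[name]
        rec = clinical.loc[act.index]
        assignment, per_k = _cluster_cohort(act, pathway_list, rec, sdcn_cfg, config.k_range)
        results["assignments"][name] = assignment
        results["per_k_silhouette"][name] = per_k
        chi2, dof, p = logrank_test(rec, assignment.labels)
        results["logrank"][name] = {"chi2": chi2, "df": dof, "p": p}
        results["km"][name] = km_estimate(rec, assignment.labels)
        frame = rec[["os_months", "os_event"]].copy()
        frame["cluster1"] = (assignment.labels == 1).astype(float)
        results["cox"][name] = cox_fit(frame, ["cluster1"])
    return results


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _persist(results: dict[str, Any], config: PipelineConfig) -> dict[str, str]:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame, **kw):
        path = os.path.join(outdir, name)
        io.write_matrix(df, path, **kw)
        paths[name] = path

    for name, sm in results["smoothed"].items():
        save(f"smoothed_{name}.tsv", sm.values)
    for name, act in results["activity"].items():
        save(f"activity_{name}.tsv", act)
    prog = results["prognostic"].copy()
    prog.to_csv(os.path.join(outdir, "prognostic_pathways.tsv"), sep="\t")
    paths["prognostic_pathways.tsv"] = os.path.join(outdir, "prognostic_pathways.tsv")
    for name, assignment in results["assignments"].items():
        df = pd.DataFrame(
            {"cluster": assignment.labels, "silhouette": assignment.silhouette}
        )
        save(f"assignment_{name}.tsv", df)
        for group, curve in results["km"][name].items():
            curve.to_csv(
                os.path.join(outdir, f"km_{name}_cluster{group}.tsv"), sep="\t", index=False
            )
    report = {
        "seed": config.seed,
        "split_seed": config.split_seed,
        "n_samples": results["n_samples"],
        "per_k_silhouette": results["per_k_silhouette"],
        "logrank": results["logrank"],
        "prognostic_count": int(len(results["prognostic"])),
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "hashes": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = os.path.join(outdir, "manifest.json")
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """File-based pipeline run: load inputs, execute, persist, manifest."""
    config.validate()
    network = load_network(config.edges, score_threshold=config.score_threshold)
    mutations = io.read_mutation_matrix(config.mutations)
    clinical = io.read_clinical(config.clinical)
    pathways = GeneSetCollection(sets=io.read_gmt(config.gmt))
    results = run_pipeline_frames(mutations, clinical, network, pathways, config)
    results["paths"] = _persist(results, config)
    return results


def run_null_pipeline_frames(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    network: GeneNetwork,
    pathways: GeneSetCollection,
    config: PipelineConfig,
    null_seed: int,
) -> dict[str, Any]:
    """Bootstrap + within-patient permutation, then smooth/score/screen and
    a fixed k=2 clustering; reports the null log-rank p.

    When the null screen retains nothing (possible: the matrix carries no
    signal), clustering falls back to all pathways so a null subtype split
    and its log-rank p are still reported.
    """
    mutations, clinical = filter_cohort(mutations, clinical)
    boot_mut, boot_rec, idx = bootstrap_patients(mutations, clinical, seed=null_seed)
    randomized = permute_within_patients(boot_mut, seed=null_seed + 1)
    null_mut = randomized.mutations

    sm = smooth_profile(null_mut, network, config.rwr, on_unmapped_sample="exclude")
    act = activity_matrix(
        sm.values, pathways, alpha=config.ssgsea_alpha, normalize=config.normalize_activity
    ).scores
    rec = boot_rec.loc[act.index]
    screened = screen_prognostic_pathways(act, rec, alpha=config.screening_alpha)
    pathway_list = list(screened.index) if not screened.empty else list(act.columns)

    sdcn_cfg = replace(config.sdcn, seed=config.seed, n_clusters=2)
    feats = standardize_features(act[pathway_list])
    graph = build_knn_graph(feats, sdcn_cfg.k_neighbors)
    assignment = train_sdcn(feats, graph, sdcn_cfg)
    assignment = orient_cluster_labels(assignment, rec)
    chi2, dof, p = logrank_test(rec, assignment.labels)
    return {
        "bootstrap_seed": null_seed,
        "permutation_seed": null_seed + 1,
        "bootstrap_indices": idx,
        "null_mutations": null_mut,
        "prognostic": screened,
        "assignment": assignment,
        "logrank": {"chi2": chi2, "df": dof, "p": p},
    }


def run_null_pipeline(config: PipelineConfig, null_seed: int = 11) -> dict[str, Any]:
    """File-based null run; reports the null log-rank p next to the real one."""
    config.validate()
    network = load_network(config.edges, score_threshold=config.score_threshold)
    mutations = io.read_mutation_matrix(config.mutations)
    clinical = io.read_clinical(config.clinical)
    pathways = GeneSetCollection(sets=io.read_gmt(config.gmt))

    real = run_pipeline_frames(mutations, clinical, network, pathways, config)
    null = run_null_pipeline_frames(mutations, clinical, network, pathways, config, null_seed)

    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    io.write_mutation_matrix(null["null_mutations"], os.path.join(outdir, "null_mutations.tsv"))
    summary = {
        "real_logrank": real["logrank"]["training"],
        "null_logrank": null["logrank"],
        "real_prognostic_count": int(len(real["prognostic"])),
        "null_prognostic_count": int(len(null["prognostic"])),
        "bootstrap_seed": null["bootstrap_seed"],
        "permutation_seed": null["permutation_seed"],
    }
    with open(os.path.join(outdir, "null_report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"real": real, "null": null, "summary": summary}


def make_demo(
    outdir: str = "results/demo_data", spec: SyntheticSpec | None = None
) -> dict[str, str]:
    """Write a synthetic demo cohort (edges, mutations, clinical, GMT)."""
    spec = spec or SyntheticSpec()
    network = generate_network(spec)
    pathways = generate_pathways(network, spec)
    mutations, clinical, _ = generate_cohort(network, pathways, spec)
    return write_cohort(outdir, network, pathways, mutations, clinical)
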