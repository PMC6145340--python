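"""End-to-end orchestration: phantom feature extraction and the full
cohort analysis (simulate -> cluster -> stability -> characterize).

A single global seed fans out to per-stage seeds through
``numpy.random.default_rng(seed).integers(2**31, size=...)`` (order:
simulate, cluster, stability, characterize), so each stage is independently
reproducible from the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .airway_metrics import segment_variables
from .characterize import associate, fit_tree, stepwise_forward_wilks, summarize_clusters
from .clustering import MicaClusterer, jaccard_stability, select_k
from .features import FeatureMatrix, assemble_features, default_manifest, write_feature_matrix
from .synthetic import CohortSpec, PhantomSpec
from .voxel_metrics import (
    adi_field,
    air_volume_change,
    classify_prm,
    jacobian_field,
    lung_shape,
    prm_fractions,
    tissue_fraction,
)

logger = logging.getLogger("micalung")

#: The published seven-variable tree set used for distillation by default.
TREE_CANDIDATES = [
    "Jacobian Total", "Dh* sLLL", "Dh* sRLL", "WT* sRUL",
    "WT* sRML", "beta_tissue LLL", "fSAD% Total",
]


def stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ("simulate", "cluster", "stability", "characterize")
    vals = rng.integers(2**31, size=len(names))
    return {n: int(v) for n, v in zip(names, vals)}


def phantom_voxel_summaries(spec: PhantomSpec | None = None) -> dict[str, float]:
    """Run every voxel metric on a phantom; keys follow the feature naming."""
    tlc, rv, disp, _ = synthetic.generate_phantom(spec)
    out: dict[str, float] = {}
    prm = classify_prm(tlc, rv)
    for region, frac in prm_fractions(prm).items():
        out[f"Emph% {region}"] = frac["Emph%"]
        out[f"fSAD% {region}"] = frac["fSAD%"]
    _, jmeans, _ = jacobian_field(disp, tlc.lobe_labels)
    for region, v in jmeans.items():
        out[f"Jacobian {region}"] = v
    _, ameans = adi_field(disp, tlc.lobe_labels)
    for region, v in ameans.items():
        out[f"ADI {region}"] = v
    for region, v in tissue_fraction(tlc).items():
        out[f"beta_tissue {region}"] = v
    out.update(air_volume_change(tlc, rv))
    out["lung_shape"] = lung_shape(tlc.lung_mask, tlc.spacing)
    return out


def phantom_subject_features(
    spec: PhantomSpec | None = None,
    sex: str = "male",
    age: float = 55.0,
    height: float = 172.0,
    airway_jitter: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """A complete 69-variable feature vector for one phantom subject."""
    summaries = phantom_voxel_summaries(spec)
    table = synthetic.generate_airway_table(jitter=airway_jitter, seed=seed)
    rows = segment_variables(table, sex=sex, age=age, height=height)
    return assemble_features(summaries, rows)


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "cohort": {},                # CohortSpec overrides
    "clustering": {
        "method": "kmeans",
        "k": 4,
        "k_grid": None,          # e.g. [2, 3, 4, 5, 6] to run model selection
        "n_components": "auto",
        "restarts": 50,
        "stability_B": 100,
    },
    "characterize": {
        "max_vars": 10,
        "f_to_enter": 3.84,
        "tree_candidates": TREE_CANDIDATES,
        "max_distinct_vars": 7,
    },
}


def _merged(config: dict[str, Any] | None) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict[str, Any] | None = None, outdir: str | Path = "mica_run") -> dict[str, Any]:
    """Run simulate -> cluster -> stability -> characterize, writing every
    artifact into ``outdir``; returns the key results as a dict."""
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    seeds = stage_seeds(seed)
    chash = _config_hash(cfg)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s, global seed %d, stage seeds %s", chash, seed, seeds)

        # ---- simulate
        spec = CohortSpec(**cfg["cohort"])
        matrix, clinical = synthetic.generate_cohort(spec, seed=seeds["simulate"])
        write_feature_matrix(matrix, outdir / "features.csv")
        clinical.to_csv(outdir / "clinical.csv", index_label="subject_id")
        smokers = synthetic.smokers_only(matrix)
        smoker_clin = clinical.loc[smokers.data.index]
        logger.info("cohort: %d smokers + %d healthy", len(smokers.data),
                    len(matrix.data) - len(smokers.data))

        # ---- cluster
        cc = cfg["clustering"]
        if cc.get("k_grid"):
            best_k, ktable = select_k(
                smokers.data, k_grid=cc["k_grid"], method=cc["method"],
                n_components=cc["n_components"], restarts=cc["restarts"],
                seed=seeds["cluster"],
            )
            ktable.to_csv(outdir / "model_selection.csv")
            logger.info("model selection over k=%s chose k=%d", cc["k_grid"], best_k)
            k = best_k
        else:
            k = cc["k"]
        est = MicaClusterer(
            method=cc["method"], k=k, n_components=cc["n_components"],
            restarts=cc["restarts"], random_state=seeds["cluster"],
        ).fit(smokers.data)
        labels = est.labels_
        est.centroids_.to_csv(outdir / "centroids.csv")
        pd.Series(labels + 1, index=smokers.data.index, name="cluster").to_csv(
            outdir / "labels.csv", index_label="subject_id"
        )
        pd.Series(est.indices_).to_csv(outdir / "internal_indices.csv", header=False)
        logger.info("clustered k=%d sizes=%s indices=%s", k,
                    est.cluster_sizes_.tolist(), est.indices_)
        try:
            from .plots import cluster_projection_plot, scree_plot
            scree_plot(est.pca_.eigenvalues, est.n_components_, outdir / "scree.png")
            cluster_projection_plot(est.scores_, labels, outdir / "clusters.png")
        except Exception as exc:  # plotting is best-effort
            logger.warning("plotting failed: %s", exc)

        # ---- stability
        report = jaccard_stability(
            smokers.data, est, B=cc["stability_B"], seed=seeds["stability"]
        )
        pd.DataFrame({
            "mean_jaccard": report.mean_jaccard,
            "dissolutions": report.dissolution_count,
        }, index=[f"cluster_{c+1}" for c in range(k)]).to_csv(outdir / "stability.csv")
        logger.info("bootstrap Jaccard (B=%d): per-cluster %s, min %.3f",
                    report.B, np.round(report.mean_jaccard, 3).tolist(),
                    report.min_mean_jaccard)

        # ---- characterize
        hc = cfg["characterize"]
        path = stepwise_forward_wilks(
            smokers.data, labels, max_vars=hc["max_vars"], f_to_enter=hc["f_to_enter"]
        )
        path.to_frame().to_csv(outdir / "selection_path.csv", index=False)
        tree = fit_tree(
            smokers.data, labels,
            candidate_variables=hc["tree_candidates"],
            max_distinct_vars=hc["max_distinct_vars"],
            random_state=seeds["characterize"],
        )
        tree.to_json(outdir / "tree.json")
        (outdir / "tree.txt").write_text(tree.to_rules() + "\n")
        assoc = associate(labels, smoker_clin.drop(columns=["true_cluster"]))
        assoc.to_csv(outdir / "associations.csv")
        summary = summarize_clusters(smokers.data, labels, variables=path.variables)
        summary.to_csv(outdir / "cluster_summary.csv")
        logger.info("selection path: %s", path.variables)
        logger.info("tree: %d variables, resubstitution accuracy %.3f",
                    len(tree.variables_used_), tree.accuracy_)

        results = {
            "config_hash": chash,
            "seed": seed,
            "k": int(k),
            "cluster_sizes": est.cluster_sizes_.tolist(),
            "n_components": int(est.n_components_),
            "internal_indices": est.indices_,
            "min_mean_jaccard": report.min_mean_jaccard,
            "selection_path": path.variables,
            "tree_variables": tree.variables_used_,
            "tree_accuracy": tree.accuracy_,
        }
        (outdir / "results.json").write_text(json.dumps(results, indent=2))
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
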