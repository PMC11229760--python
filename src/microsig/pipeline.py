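"""Orchestration: transform -> PELORA and transform -> iRF -> interpret.

The two analysis branches run independently on the same transformed
matrix per taxonomic rank and never feed each other; associations run on
raw abundances plus the metabolite matrix.  One root seed deterministically
derives a seed per (rank, module) via a hash, so re-running a config into
a fresh directory reproduces every output byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance_io import read_abundance_table
from .associations import spearman_matrix
from .interpret import (ale_curve, interaction_edges, pdp_surface,
                        select_ale_features, select_pdp_pairs)
from .irf import IterativeRandomForestClassifier, iterate_irf, mine_interactions
from .pelora import DEFAULT_LAMBDA_GRID, fit_pelora, tune_penalty
from .transforms import centroid, logit_zscore

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, *names: str) -> int:
    """Deterministic per-module seed: sha256 of "root:name:..." -> 31-bit int."""
    key = ":".join([str(root_seed), *names]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    abundance_paths: dict[str, str]      # rank -> TSV path
    metadata_path: str
    output_dir: str
    seed: int = 0
    ranks: list[str] = field(default_factory=list)  # default: all given
    metabolite_path: str | None = None
    run_pelora: bool = True
    run_irf: bool = True
    run_interpret: bool = True
    run_associations: bool = True
    pelora_params: dict = field(default_factory=dict)
    irf_params: dict = field(default_factory=dict)
    interpret_params: dict = field(default_factory=dict)
    associations_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _pelora_branch(z, y, outdir: Path, rank: str, seed: int, params: dict) -> list[Path]:
    lam = params.get("lam")
    max_clusters = params.get("max_clusters", 2)
    if lam is None:
        search = tune_penalty(
            z, y, lambda_grid=params.get("lambda_grid", DEFAULT_LAMBDA_GRID),
            n_boot=params.get("n_boot", 50), max_clusters=max_clusters,
            seed=seed, max_cluster_size=params.get("max_cluster_size"),
        )
        lam = search.chosen
    fit = fit_pelora(z, y, lam=lam, max_clusters=max_clusters)
    out_json = outdir / f"pelora_{rank}.json"
    _write_json({
        "rank": rank, "lambda": lam, "clusters": fit.clusters,
        "intercept": fit.intercept, "coefficients": list(fit.coefficients),
        "criterion_trace": fit.criterion_trace,
    }, out_json)
    out_cent = outdir / f"pelora_{rank}_centroids.tsv"
    fit.centroids.to_csv(out_cent, sep="\t", index_label="sample_id")
    # per-cluster report in the style of a published cluster table:
    # member group means/SDs on the Z scale plus the centroid comparison
    rows = []
    garr = np.asarray(y)
    for k, members in enumerate(fit.clusters, start=1):
        for m in members:
            col = z.values[m].to_numpy()
            rows.append({
                "cluster": k, "member": m,
                "mean_group0": col[garr == 0].mean(),
                "sd_group0": col[garr == 0].std(ddof=1),
                "mean_group1": col[garr == 1].mean(),
                "sd_group1": col[garr == 1].std(ddof=1),
            })
        cres = centroid(z, members, group=garr)
        rows.append({
            "cluster": k, "member": "(centroid)",
            "mean_group0": cres.group_means[0], "sd_group0": cres.group_sds[0],
            "mean_group1": cres.group_means[1], "sd_group1": cres.group_sds[1],
            "p_value": cres.p_value, "test": cres.test_used,
        })
    out_rep = outdir / f"pelora_{rank}_report.tsv"
    pd.DataFrame(rows).to_csv(out_rep, sep="\t", index=False)
    return [out_json, out_cent, out_rep]


def _irf_branch(z, y, outdir: Path, rank: str, seed: int, params: dict,
                run_interpret: bool, interpret_params: dict) -> list[Path]:
    K = params.get("K", 5)
    n_trees = params.get("n_trees", 500)
    X = z.values
    result = iterate_irf(X, y, K=K, n_trees=n_trees, seed=seed,
                         max_depth=params.get("max_depth", 10),
                         min_samples_leaf=params.get("min_samples_leaf", 1),
                         n_boot_ci=params.get("n_boot_ci", 1000))
    interactions = mine_interactions(
        X, y, K=K, n_boot=params.get("n_boot", 30),
        rit_depth=params.get("rit_depth", 5),
        rit_branch=params.get("rit_branch", 2),
        n_rit_trees=params.get("n_rit_trees", 500),
        seed=derive_seed(seed, "rit"), n_trees=n_trees,
        max_depth=params.get("max_depth", 10),
        min_samples_leaf=params.get("min_samples_leaf", 1),
    )
    result.interactions = interactions
    out_json = outdir / f"irf_{rank}.json"
    _write_json({
        "rank": rank, "K": K, "n_trees": n_trees,
        "auc": result.auc, "auc_ci": list(result.auc_ci),
        "vimp": {f: {"raw": r, "relative": v}
                 for f, r, v in zip(result.feature_names, result.vimp_raw,
                                    result.vimp_relative)},
        "interactions": [{"features": list(it.features),
                          "stability": it.stability} for it in interactions],
    }, out_json)
    out_oob = outdir / f"irf_{rank}_oob.tsv"
    pd.DataFrame({"sample_id": X.index, "oob_probability":
                  result.oob_probabilities}).to_csv(out_oob, sep="\t", index=False)
    out_edges = outdir / f"irf_{rank}_edges.tsv"
    pd.DataFrame(interaction_edges(interactions),
                 columns=["feature_a", "feature_b", "stability"]
                 ).to_csv(out_edges, sep="\t", index=False)
    written = [out_json, out_oob, out_edges]
    if run_interpret:
        est = IterativeRandomForestClassifier(
            n_iterations=K, n_trees=n_trees,
            max_depth=params.get("max_depth", 10),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed).fit(X, y)
        predict = lambda A: est.predict_proba(A)[:, 1]
        n_bins = interpret_params.get("n_bins", 20)
        grid_size = interpret_params.get("grid_size", 20)
        ale_rows = []
        for feat in select_ale_features(result.feature_names, result.vimp_relative):
            curve = ale_curve(predict, X, feat, n_bins=n_bins)
            for b in range(curve.effects.size):
                ale_rows.append({"feature": feat, "bin_upper": curve.edges[b + 1],
                                 "ale": curve.effects[b], "count": curve.counts[b]})
        out_ale = outdir / f"ale_{rank}.tsv"
        pd.DataFrame(ale_rows).to_csv(out_ale, sep="\t", index=False)
        written.append(out_ale)
        pdp_rows, risk_cells = [], []
        for pair in select_pdp_pairs(interactions):
            surf = pdp_surface(predict, X, pair, grid_size=grid_size)
            for a, vx in enumerate(surf.grid_x):
                for b, vy in enumerate(surf.grid_y):
                    pdp_rows.append({"feature_a": pair[0], "feature_b": pair[1],
                                     "x": vx, "y": vy,
                                     "probability": surf.values[a, b]})
                    if surf.high_risk[a, b]:
                        risk_cells.append({"pair": list(pair), "x": vx, "y": vy,
                                           "probability": surf.values[a, b]})
        out_pdp = outdir / f"pdp_{rank}.tsv"
        pd.DataFrame(pdp_rows).to_csv(out_pdp, sep="\t", index=False)
        out_risk = outdir / f"pdp_{rank}_high_risk.json"
        _write_json(risk_cells, out_risk)
        written += [out_pdp, out_risk]
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured branches; returns (and writes) the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ranks = config.ranks or list(config.abundance_paths)
    manifest: dict = {
        "microsig_version": __version__,
        "seed": config.seed,
        "ranks": ranks,
        "completed_stages": [],
        "outputs": {},
        "parameters": {
            "pelora": config.pelora_params, "irf": config.irf_params,
            "interpret": config.interpret_params,
            "associations": config.associations_params,
        },
    }
    written: list[Path] = []
    try:
        for rank in ranks:
            table = read_abundance_table(config.abundance_paths[rank], rank,
                                         config.metadata_path)
            z = logit_zscore(table)
            y = table.group.to_numpy()
            zpath = outdir / f"zmatrix_{rank}.tsv"
            z.values.to_csv(zpath, sep="\t", index_label="sample_id")
            _write_json({
                "rank": rank, "replacement_value": z.replacement_value,
                "feature_means": z.feature_means.to_dict(),
                "feature_sds": z.feature_sds.to_dict(),
                "dropped_features": z.dropped_features,
            }, outdir / f"transform_{rank}.json")
            written += [zpath, outdir / f"transform_{rank}.json"]
            manifest["completed_stages"].append(f"transform:{rank}")

            if config.run_pelora:
                written += _pelora_branch(
                    z, y, outdir, rank,
                    derive_seed(config.seed, rank, "pelora"),
                    config.pelora_params)
                manifest["completed_stages"].append(f"pelora:{rank}")
            if config.run_irf:
                written += _irf_branch(
                    z, y, outdir, rank,
                    derive_seed(config.seed, rank, "irf"),
                    config.irf_params, config.run_interpret,
                    config.interpret_params)
                manifest["completed_stages"].append(f"irf:{rank}")

        if config.run_associations and config.metabolite_path:
            rank = ranks[0]
            table = read_abundance_table(config.abundance_paths[rank], rank,
                                         config.metadata_path)
            metab = pd.read_csv(config.metabolite_path, sep="\t", index_col=0)
            metab = metab.loc[table.values.index]
            res = spearman_matrix(table.values, metab,
                                  alpha=config.associations_params.get("alpha", 0.05),
                                  fdr=config.associations_params.get("fdr", False))
            rho_p = outdir / "associations_rho.tsv"
            res.rho.to_csv(rho_p, sep="\t")
            pv_p = outdir / "associations_p.tsv"
            res.p.to_csv(pv_p, sep="\t")
            sig_p = outdir / "associations_significant.tsv"
            res.significant_pairs().to_csv(sig_p, sep="\t", index=False)
            written += [rho_p, pv_p, sig_p]
            manifest["completed_stages"].append("associations")
    except Exception as exc:  # record progress, then abort
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["outputs"] = {str(p.name): _sha256(p) for p in written}
        _write_json(manifest, outdir / "manifest.json")
        raise
    manifest["outputs"] = {str(p.name): _sha256(p) for p in written}
    _write_json(manifest, outdir / "manifest.json")
    return manifest
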