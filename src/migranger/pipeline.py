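"""End-to-end orchestration of the analysis stages.

Stage order: feature extraction → Box-Cox normalization and stationarity
verification → subpopulation discovery → feature selection → pooled Granger
causality → cross-condition comparison.  Every stage writes delimited outputs
into the run directory and the run closes with a provenance manifest (seeds,
parameters, row counts).  A stage failure halts the run with a stage-tagged
diagnostic; earlier outputs are retained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog
from .config import RunConfig
from .features import extract_features
from .granger import (EdgeCriterion, build_graph, assemble_chain,
                      compare_conditions, r2_surface)
from .io import read_tracked_tables, write_panel, feature_columns
from .population import (pca_svd, n_components_for_variance,
                         select_n_subpopulations)
from .selection import cva_rank_features, elastic_net_rank, spearman_matrix
from .transforms import normalize_panel, check_stationarity, transforms_sidecar

log = logging.getLogger("migranger")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    chash = config.config_hash()
    manifest = {"config_hash": chash, "master_seed": config.master_seed, "stages": {}}

    def _finish(stage, **info):
        manifest["stages"][stage] = info
        log.info("stage %s done: %s", stage, info)

    def _to_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
        # every output table carries the config hash in a header comment
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh, **kwargs)

    try:
        dataset = read_tracked_tables(config.input_dir)
    except Exception as exc:
        raise StageError("read", exc)

    # --- features ---------------------------------------------------------
    try:
        panel, cmac_feats, report, divisors = extract_features(
            dataset, config.reference_condition, smoothing=config.smoothing
        )
        write_panel(panel, out / "features_cell.csv", chash)
        write_panel(cmac_feats, out / "features_cmac.csv", chash)
        catalog.write_catalog_yaml(out / "catalog.yaml")
        with open(out / "parsing_report.json", "w") as fh:
            json.dump({**report.__dict__, "divisors": divisors}, fh, indent=1, default=str)
        _finish("features", cell_rows=len(panel), cmac_rows=len(cmac_feats))
    except Exception as exc:
        raise StageError("features", exc)

    # --- transforms -------------------------------------------------------
    try:
        norm, discarded, results = normalize_panel(
            panel, alpha=config.boxcox_alpha, keep=tuple(config.boxcox_keep)
        )
        write_panel(norm, out / "features_cell_normalized.csv", chash)
        with open(out / "transforms.json", "w") as fh:
            json.dump({"discarded": discarded,
                       "per_feature": transforms_sidecar(results)}, fh, indent=1)
        stat = check_stationarity(
            norm, alpha=config.stationarity_alpha,
            min_fraction=config.stationarity_min_fraction,
            min_track_length=config.stationarity_min_track_length,
        )
        with open(out / "stationarity.json", "w") as fh:
            json.dump(stat.verdicts, fh, indent=1)
        _finish("transforms", discarded=len(discarded),
                surviving=len(feature_columns(norm)))
    except Exception as exc:
        raise StageError("transforms", exc)

    ref = norm[norm["condition"] == config.reference_condition]

    # --- subpopulations ---------------------------------------------------
    if config.run_subpopulations:
        try:
            org = [f for f in feature_columns(ref) if f != catalog.BEHAVIORAL_FEATURE]
            X = ref[org].to_numpy(float)
            complete = np.isfinite(X).all(axis=1)
            scores, _, fractions = pca_svd(X[complete])
            npc = n_components_for_variance(fractions, config.pca_variance_target)
            best_k, fit, curve = select_n_subpopulations(
                scores[:, :npc],
                K_range=range(config.em_k_min, config.em_k_max + 1),
                restarts=config.em_restarts,
                final_restarts=config.em_final_restarts,
                seed=config.stage_seed("subpop"),
                aic_penalty=config.aic_penalty,
            )
            labels = pd.DataFrame({
                "row": np.where(complete)[0], "subpopulation": fit.labels,
            })
            _to_csv(labels, out / "subpopulations.csv", index=False)
            _to_csv(pd.DataFrame({"K": list(curve), "AIC": list(curve.values())}),
                    out / "aic_curve.csv", index=False)
            speed = ref[catalog.BEHAVIORAL_FEATURE].to_numpy(float)[complete]
            _write_subpopulation_comparison(out, X[complete], fit.labels, speed)
            _finish("subpopulations", best_K=best_k, n_components=npc)
        except Exception as exc:
            raise StageError("subpopulations", exc)

    # --- feature selection ------------------------------------------------
    if config.run_selection:
        try:
            cva_res = cva_rank_features(ref)
            _to_csv(cva_res.ranking, out / "cva_ranking.csv", index=False)
            en = elastic_net_rank(ref, l1_ratio=config.en_l1_ratio,
                                  n_alphas=config.en_n_alphas)
            _to_csv(en.ranking, out / "en_ranking.csv", index=False)
            _to_csv(pd.DataFrame({"alpha": en.alphas, "adjusted_r2": en.adjusted_r2}),
                    out / "en_path.csv", index=False)
            _to_csv(spearman_matrix(ref), out / "spearman_matrix.csv")
            _finish("selection", en_optimal_adj_r2=float(en.adjusted_r2[en.optimal_index]))
        except Exception as exc:
            raise StageError("selection", exc)

    # --- granger ----------------------------------------------------------
    if config.run_granger and config.granger_pairs:
        try:
            criterion = EdgeCriterion(config.edge_min_fraction_05,
                                      config.edge_min_fraction_0001)
            graphs = {}
            for cond in config.conditions:
                sub = norm[norm["condition"] == cond]
                graph = build_graph(sub, [tuple(p) for p in config.granger_pairs],
                                    condition=cond, L_max=config.lag_max,
                                    criterion=criterion)
                graphs[cond] = graph
                with open(out / f"graph_{cond}.json", "w") as fh:
                    fh.write(graph.to_json())
                for (src, tgt), grid in graph.grids.items():
                    tag = f"{_slug(cond)}__{_slug(src)}__{_slug(tgt)}"
                    np.savetxt(out / f"siggrid_{tag}.csv", grid.p_values,
                               delimiter=",", header=f"p-values {src} -> {tgt}")
                    surf = r2_surface(sub, tgt, src, L_max=config.lag_max)
                    np.savetxt(out / f"r2_surface_{tag}.csv", surf.adjusted_r2,
                               delimiter=",",
                               header=f"adjusted R2 {src} -> {tgt}")
            if config.chain:
                links, intact, broken = assemble_chain(
                    graphs[config.reference_condition], config.chain)
                with open(out / "chain_report.json", "w") as fh:
                    json.dump({"intact": intact, "first_break": broken,
                               "links": [l.__dict__ for l in links]}, fh, indent=1)
            if len(graphs) > 1:
                _to_csv(compare_conditions(graphs, config.reference_condition),
                        out / "plasticity_report.csv", index=False)
            _finish("granger", pairs=len(config.granger_pairs),
                    conditions=len(graphs))
        except Exception as exc:
            raise StageError("granger", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _write_subpopulation_comparison(out: Path, X: np.ndarray,
                                    labels: np.ndarray, speed: np.ndarray) -> None:
    """CVA scores, Mahalanobis distances, dendrogram and per-group KS tests
    of the behavioral feature for the discovered subpopulations."""
    from .population import (cva, hcluster_group_means, ks_two_sample,
                             mahalanobis_pairwise)

    res = cva(X, labels)
    scores = pd.DataFrame(res["scores"],
                          columns=[f"CV{i + 1}" for i in
                                   range(res["scores"].shape[1])])
    scores.insert(0, "subpopulation", labels)
    scores.to_csv(out / "cva_scores.csv", index=False)

    D, groups, excluded = mahalanobis_pairwise(X, labels)
    pd.DataFrame(D, index=groups, columns=groups).to_csv(out / "distances.csv")

    Z, order = hcluster_group_means(X, labels)
    with open(out / "dendrogram.json", "w") as fh:
        json.dump({"groups": [int(g) for g in order],
                   "linkage": Z.tolist(), "excluded": list(excluded)}, fh,
                  indent=1)

    ks = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            sa = speed[(labels == a) & np.isfinite(speed)]
            sb = speed[(labels == b) & np.isfinite(speed)]
            if len(sa) >= 10 and len(sb) >= 10:
                _, p, _ = ks_two_sample(sa, sb)
                ks.loc[a, b] = ks.loc[b, a] = p
    ks.to_csv(out / "ks_matrix.csv")


def _slug(name: str) -> str:
    keep = [c if c.isalnum() else "_" for c in name]
    return "".join(keep)[:48]
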