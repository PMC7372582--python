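"""End-to-end orchestration: simulate -> profile -> train -> hits -> cluster.

A single YAML/dict run configuration drives every stage.  One master seed
fans out to per-stage seeds through stable hashing of the stage name, so
any stage can be re-run in isolation and reproduce its part of a full
run.  Every output lands in a run directory listed in ``manifest.json``
together with a hash of the configuration, and ``report.json`` records
per-stage counts plus planted-truth recovery metrics when the input is a
synthetic screen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phenoscreen import io as psio
from phenoscreen.hits import (
    PhenotypicDistance,
    assemble_hit_table,
    call_phenotypic_hits,
    call_viability_hits,
    combine_hits,
    compute_zscores,
)
from phenoscreen.moa import MoARandomForest, build_training_set, harmonize_features, loco_cv
from phenoscreen.preprocess import profile_cell_line
from phenoscreen.profiles import cluster_cell_line_responses, response_matrix
from phenoscreen.synth import ScreenConfig, generate_screen, ground_truth_hit_set

__all__ = ["derive_seed", "run_pipeline", "screen_distances", "config_hash"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name folded with the master seed."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def screen_distances(
    wells: pd.DataFrame,
    n_components: int = 15,
    shrinkage: str | float | None = None,
    threshold_alpha: float = 0.001,
    threshold_method: str = "f",
) -> tuple[pd.DataFrame, float]:
    """Per-compound Mahalanobis distances for one line's screen wells.

    Fits PCA + DMSO reference on the well profiles, scores every well, and
    summarises per compound by the median over replicate wells.  Returns
    the long distance table and the line's null-calibrated threshold.
    """
    model = PhenotypicDistance(n_components=n_components, shrinkage=shrinkage).fit(wells)
    d2 = model.score_samples(wells)
    scored = wells[["cell_line", "compound", "role"]].copy()
    scored["mahalanobis"] = d2
    treated = scored[scored["role"] == "treatment"]
    out = treated.groupby(["compound", "cell_line"], as_index=False)["mahalanobis"].median()
    return out, model.null_threshold(alpha=threshold_alpha, method=threshold_method)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full synthetic-screen pipeline; returns the report dict."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    screen_cfg = ScreenConfig(**{**config.get("screen", {}), "seed": derive_seed(seed, "simulate")})
    pp = config.get("preprocess", {})
    hits_cfg = config.get("hits", {})
    moa_cfg = config.get("moa", {})

    manifest: dict = {"config_hash": config_hash(config), "seed": seed, "outputs": []}
    report: dict = {"seed": seed, "stages": {}}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    # --- simulate -----------------------------------------------------------
    screen = generate_screen(screen_cfg)
    emit("platemap.csv", lambda p: psio.write_platemap(screen.platemap, p))
    emit("annotations.csv", lambda p: screen.annotations.to_csv(p, index=False))
    nuclei = screen.nuclei_counts()
    emit("nuclei_counts.csv", lambda p: psio.write_nuclei_counts(nuclei, p))
    report["stages"]["simulate"] = {
        "cell_lines": list(screen.cell_lines),
        "n_compounds": int(screen.platemap["compound"].nunique() - 1),
        "n_wells": int(len(screen.platemap)),
    }

    # --- preprocess (per line) ---------------------------------------------
    wells_by_line: dict[str, pd.DataFrame] = {}
    pp_counts = {}
    for line in screen.cell_lines:
        cells = screen.cell_features(line)
        wells, line_report = profile_cell_line(cells, screen.platemap_for(line), **pp)
        wells_by_line[line] = wells
        emit(f"wells_{line}.csv", lambda p, w=wells: psio.write_profiles(w, p))
        emit(f"preprocess_{line}.txt", lambda p, r=line_report: Path(p).write_text(r.to_text()))
        pp_counts[line] = {
            "cells": line_report.n_cells,
            "images": line_report.n_images,
            "images_removed": line_report.n_images_removed,
            "features_dropped": len(line_report.dropped_features),
            "wells": line_report.n_wells,
        }
    report["stages"]["preprocess"] = pp_counts

    # --- MoA training and transfer validation -------------------------------
    moa_report = {}
    if screen_cfg.include_reference:
        labeled = {}
        for line in screen.cell_lines:
            w = wells_by_line[line]
            ref = w[(w["role"] == "vehicle_control") | w["compound"].isin(screen.annotations["compound"])]
            X, y = build_training_set(ref.reset_index(drop=True), screen.annotations)
            labeled[line] = (X, y)
        per_line_oob = {}
        for line, (X, y) in labeled.items():
            model = MoARandomForest(
                n_estimators=int(moa_cfg.get("n_estimators", 500)),
                random_state=derive_seed(seed, f"train:{line}"),
            ).fit(X, y)
            per_line_oob[line] = model.oob_error_
        moa_report["oob_error_per_line"] = per_line_oob
        moa_report["oob_error_mean"] = float(np.mean(list(per_line_oob.values())))

        eac = [l for l in screen.cell_lines if l in screen_cfg.eac_lines]
        if len(eac) >= 3:
            harmonized = harmonize_features({l: labeled[l][0] for l in eac})
            folds = loco_cv(
                {l: (harmonized[l], labeled[l][1]) for l in eac},
                n_estimators=int(moa_cfg.get("n_estimators", 500)),
                random_state=derive_seed(seed, "loco"),
            )
            moa_report["loco_accuracy"] = {l: r["accuracy"] for l, r in folds.items()}
        emit("moa_report.json", lambda p: Path(p).write_text(json.dumps(moa_report, indent=2)))
    report["stages"]["moa"] = moa_report

    # --- hit calling --------------------------------------------------------
    hit_report = {}
    if screen_cfg.include_screen:
        dist_frames, thresholds = [], {}
        for line in screen.cell_lines:
            w = wells_by_line[line]
            scr = w[w["plate"].str.contains("-SCR")].reset_index(drop=True)
            d, thr = screen_distances(
                scr,
                n_components=int(hits_cfg.get("n_components", 15)),
                shrinkage=hits_cfg.get("shrinkage"),
                threshold_alpha=float(hits_cfg.get("threshold_alpha", 0.001)),
                threshold_method=hits_cfg.get("threshold_method", "f"),
            )
            dist_frames.append(d)
            thresholds[line] = thr
        distances = pd.concat(dist_frames, ignore_index=True)
        emit("distances.csv", lambda p: distances.to_csv(p, index=False))

        threshold = hits_cfg.get("threshold", "null")
        pheno = call_phenotypic_hits(
            distances,
            screen_cfg.eac_lines,
            screen_cfg.control_lines,
            threshold=thresholds if threshold == "null" else float(threshold),
            min_eac_lines=int(hits_cfg.get("min_eac_lines", 2)),
        )
        zs = compute_zscores(nuclei, screen.platemap, per_plate=hits_cfg.get("zscore_per_plate", True))
        zs = zs[zs["compound"].str.startswith("scr_")].reset_index(drop=True)
        emit("zscores.csv", lambda p: zs.to_csv(p, index=False))
        viab = call_viability_hits(
            zs,
            screen_cfg.eac_lines,
            screen_cfg.control_lines,
            eac_threshold=float(hits_cfg.get("eac_threshold", -3.0)),
            margin=float(hits_cfg.get("margin", 2.0)),
            min_eac_lines=int(hits_cfg.get("min_eac_lines", 2)),
        )
        pheno_set = set(pheno.index[pheno["selective"]])
        viab_set = set(viab.index[viab["selective"]])
        combined = combine_hits(pheno_set, viab_set)
        table = assemble_hit_table(distances, zs, pheno, viab)
        emit("hit_table.csv", lambda p: psio.write_hit_table(table, p))
        emit("hits.json", lambda p: psio.write_hit_table(combined, p, as_json=True))

        truth_hits = ground_truth_hit_set(screen.truth, min_eac_lines=int(hits_cfg.get("min_eac_lines", 2)))
        called = set(combined["compound"])
        tp = len(called & truth_hits)
        hit_report = {
            "thresholds": thresholds,
            "n_phenotypic": len(pheno_set),
            "n_viability": len(viab_set),
            "n_overlap": len(pheno_set & viab_set),
            "n_union": len(called),
            "n_planted": len(truth_hits),
            "sensitivity": tp / len(truth_hits) if truth_hits else np.nan,
            "fdr": (len(called) - tp) / len(called) if called else 0.0,
        }

        # --- response clustering -------------------------------------------
        matrix, degenerate = response_matrix(zs, value_col="z")
        if matrix.shape[0] >= 3 and matrix.shape[1] >= 3:
            linkage = cluster_cell_line_responses(matrix)
            emit("cell_line_dendrogram.nwk", lambda p: Path(p).write_text(linkage.to_newick() + "\n"))
            emit("cell_line_linkage.json", lambda p: Path(p).write_text(json.dumps(linkage.to_merge_list(), indent=2)))
            hit_report["dropped_constant_rows"] = len(degenerate)
    report["stages"]["hits"] = hit_report

    emit("report.json", lambda p: Path(p).write_text(json.dumps(report, indent=2, default=float)))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config))
    return report
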