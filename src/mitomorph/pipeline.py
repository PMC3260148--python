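"""End-to-end pipeline orchestration.

A run executes the enabled stages in dependency order — simulate images,
segment + extract features, train + classify, aggregate per condition,
membrane-potential kinetics, Bax scoring, assembly of the combined condition
table, fuzzy directionality search — and writes a manifest (seeds, artifact
checksums) plus a report directory of CSV/JSON artifacts.  Per-stage seeds
are spawned deterministically from the global seed, so a run is
bit-reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bax import bax_population_fraction, score_bax_tiles
from .classify import aggregate_condition, major_class, predict_scores
from .features import extract_features
from .fuzzy import RMSE_THRESHOLD, exhaustive_search, mirror_select
from .imaging import segment_image
from .io import save_direction_graph, save_models_json
from .reference_data import BAX_POSITIVE_PERCENT, CONDITION_NFS_PERCENT
from .simulate import (
    CausalTableSpec,
    generate_bax_images,
    generate_condition_traces,
    generate_condition_table,
    generate_image_set,
)
from .tmrm import cluster_conditions, condition_profiles, extract_params_table, plot_heatmap
from .workflows import train_default_classifier

STAGES = ("images", "morphology", "tmrm", "bax", "table", "fuzzy")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "mitomorph_run",
    "stages": list(STAGES),
    "images": {"cells_per_condition": 12, "conditions": ["FM", "ceramide", "CCCP"]},
    "morphology": {"n_per_class": 30, "n_trees": 200},
    "tmrm": {"n_per_condition": 20},
    "bax": {"n_cells": 60, "conditions": ["BSS", "TNFa", "camptothecin"]},
    "table": {"n_conditions": 9},
    "fuzzy": {"threshold": RMSE_THRESHOLD, "normalize": False},
}


def validate_config(config: dict) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    for stage in config.get("stages", []):
        if stage not in STAGES:
            problems.append(f"unknown stage name: {stage!r}")
    if config.get("fuzzy", {}).get("threshold", RMSE_THRESHOLD) <= 0:
        problems.append("fuzzy.threshold must be positive")
    if config.get("table", {}).get("n_conditions", 9) < 5:
        problems.append("table.n_conditions must be >= 5")
    if config.get("morphology", {}).get("n_per_class", 30) < 1:
        problems.append("morphology.n_per_class must be >= 1")
    if config.get("tmrm", {}).get("n_per_condition", 20) < 1:
        problems.append("tmrm.n_per_condition must be >= 1")
    seed = config.get("seed", 0)
    if not isinstance(seed, (int, np.integer)):
        problems.append("seed must be an integer")
    return problems


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured stages; returns the run manifest.

    Artifacts land under ``config['outdir']``; the manifest records every
    file with a checksum, the per-stage seeds, and the package version.
    """
    cfg = _merged(config)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg["seed"]).spawn(len(STAGES))
    stage_seed = {s: int(ss.generate_state(1)[0] % 2**31) for s, ss in zip(STAGES, seeds)}
    enabled = cfg["stages"]
    artifacts: dict[str, str] = {}
    summary_tables: dict[str, pd.DataFrame] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        artifacts[name] = _checksum(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        if "morphology" in enabled:
            mcfg = cfg["morphology"]
            model, feats = train_default_classifier(
                n_per_class=mcfg["n_per_class"], seed=stage_seed["morphology"], n_trees=mcfg["n_trees"]
            )
            emit("training_features.csv", feats)

            icfg = cfg["images"]
            mixes = {}
            for c in icfg["conditions"]:
                arr = np.asarray(CONDITION_NFS_PERCENT[c], dtype=float)
                mixes[c] = (tuple(arr / arr.sum()), icfg["cells_per_condition"])
            images, cell_manifest = generate_image_set(mixes, seed=stage_seed["images"])
            emit("cell_manifest.csv", cell_manifest)
            rows = []
            for i, img in enumerate(images):
                seg = segment_image(img.dna, img.gfp)
                if not seg.cell_index:
                    continue
                f = extract_features(seg, img.gfp, img.pixel_size_um, image_id=str(i), condition=img.condition)
                s = predict_scores(model, f)
                s["condition"] = img.condition
                s["replicate"] = img.replicate
                s["major_class"] = np.atleast_1d(major_class(s))
                rows.append(s)
            scores = pd.concat(rows, ignore_index=True)
            emit("cell_scores.csv", scores)
            cond = aggregate_condition(scores)
            emit("condition_summary.csv", cond)
            summary_tables["morphology"] = cond

        if "tmrm" in enabled:
            tcfg = cfg["tmrm"]
            traces = generate_condition_traces(tcfg["n_per_condition"], seed=stage_seed["tmrm"])
            params = extract_params_table(traces)
            emit("tmrm_params.csv", params)
            prof = condition_profiles(traces)
            prof.to_csv(outdir / "tmrm_profiles.csv")
            artifacts["tmrm_profiles.csv"] = _checksum(outdir / "tmrm_profiles.csv")
            plot_heatmap(prof, outdir / "tmrm_heatmap.png")
            cl = cluster_conditions(prof)
            (outdir / "tmrm_dendrogram.json").write_text(
                json.dumps({"leaf_order": cl["leaf_order"], "linkage": cl["linkage"].tolist()})
            )
            artifacts["tmrm_dendrogram.json"] = _checksum(outdir / "tmrm_dendrogram.json")
            summary_tables["tmrm"] = (
                params.groupby("condition", sort=False)[["MAX", "Y_spread", "t_half_decay"]].mean().reset_index()
            )

        if "bax" in enabled:
            bcfg = cfg["bax"]
            rng = np.random.default_rng(stage_seed["bax"])
            all_scores = []
            for c in bcfg["conditions"]:
                frac = BAX_POSITIVE_PERCENT.get(c, 20.0) / 100.0
                tiles, _ = generate_bax_images(frac, bcfg["n_cells"], seed=int(rng.integers(2**31)))
                s = score_bax_tiles(tiles)
                s["condition"] = c
                s["replicate"] = s["cell_id"] % 3  # three pseudo-replicates
                all_scores.append(s)
            bax_scores = pd.concat(all_scores, ignore_index=True)
            emit("bax_scores.csv", bax_scores)
            bax_frac = bax_population_fraction(bax_scores)
            emit("bax_summary.csv", bax_frac)
            summary_tables["bax"] = bax_frac

        if "table" in enabled:
            tab = generate_condition_table(
                CausalTableSpec(n_conditions=cfg["table"]["n_conditions"]), seed=stage_seed["table"]
            )
            emit("condition_table.csv", tab)
            summary_tables["table"] = tab

        if "fuzzy" in enabled and "table" in summary_tables:
            fcfg = cfg["fuzzy"]
            models = exhaustive_search(
                summary_tables["table"], normalize=fcfg["normalize"]
            )
            save_models_json(models, outdir / "siso_models.json")
            artifacts["siso_models.json"] = _checksum(outdir / "siso_models.json")
            graph = mirror_select(models, threshold=fcfg["threshold"])
            save_direction_graph(graph, outdir / "direction_graph.json")
            artifacts["direction_graph.json"] = _checksum(outdir / "direction_graph.json")
            (outdir / "direction_graph.dot").write_text(graph.to_dot())
            artifacts["direction_graph.dot"] = _checksum(outdir / "direction_graph.dot")

        # combined per-condition report (radar-style CSV)
        combined = _combined_table(summary_tables)
        if combined is not None:
            emit("combined_conditions.csv", combined)

    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "stage_seeds": stage_seed,
        "stages": enabled,
        "artifacts": artifacts,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _combined_table(summary_tables: dict) -> pd.DataFrame | None:
    """Join per-condition outputs into one table with columns
    N, F, S, Bax, MAX, t1_2_decay, Y_spread."""
    if "morphology" not in summary_tables:
        return None
    m = summary_tables["morphology"]
    out = pd.DataFrame(
        {
            "condition": m["condition"],
            "N": m["networked_mean_pct"],
            "F": m["fragmented_mean_pct"],
            "S": m["swollen_mean_pct"],
        }
    )
    if "bax" in summary_tables:
        out = out.merge(
            summary_tables["bax"][["condition", "positive_pct"]].rename(columns={"positive_pct": "Bax"}),
            on="condition",
            how="left",
        )
    else:
        out["Bax"] = np.nan
    if "tmrm" in summary_tables:
        out = out.merge(
            summary_tables["tmrm"].rename(columns={"t_half_decay": "t1_2_decay"}),
            on="condition",
            how="left",
        )
    else:
        out[["MAX", "Y_spread", "t1_2_decay"]] = np.nan
    return out[["condition", "N", "F", "S", "Bax", "MAX", "t1_2_decay", "Y_spread"]]
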