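"""File-format helpers: TIFF images and label masks, CSV tables, JSON graphs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate.images import CellTruth, LabeledImage


def save_image_set(images: list[LabeledImage], manifest: pd.DataFrame, outdir) -> pd.DataFrame:
    """Write images + label masks as TIFF and an image-level manifest CSV.

    Each image ``i`` produces ``img_{i:04d}.tif`` (2-channel 16-bit),
    ``img_{i:04d}_nuclei.tif`` / ``_cells.tif`` / ``_mito.tif`` (int32 label
    masks) and a truth JSON.  Returns the image-level manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        stem = f"img_{i:04d}"
        tifffile.imwrite(outdir / f"{stem}.tif", np.moveaxis(img.image, -1, 0))
        tifffile.imwrite(outdir / f"{stem}_nuclei.tif", img.nucleus_labels)
        tifffile.imwrite(outdir / f"{stem}_cells.tif", img.cell_labels)
        tifffile.imwrite(outdir / f"{stem}_mito.tif", img.mito_labels)
        truth = {
            str(cid): {"fractions": list(t.fractions), "mito_classes": {str(k): v for k, v in t.mito_classes.items()}}
            for cid, t in img.truth.items()
        }
        (outdir / f"{stem}_truth.json").write_text(json.dumps(truth))
        rows.append(
            {
                "image": f"{stem}.tif",
                "condition": img.condition,
                "replicate": img.replicate,
                "pixel_size_um": img.pixel_size_um,
                "n_cells": len(img.truth),
            }
        )
    image_manifest = pd.DataFrame(rows)
    image_manifest.to_csv(outdir / "manifest.csv", index=False)
    manifest.to_csv(outdir / "cells.csv", index=False)
    return image_manifest


def load_image(path) -> LabeledImage:
    """Load one image (and its masks/truth, when present) written by
    :func:`save_image_set`."""
    path = Path(path)
    stem = path.stem
    arr = tifffile.imread(path)
    image = np.moveaxis(arr, 0, -1)
    d = path.parent

    def _opt(suffix):
        p = d / f"{stem}{suffix}.tif"
        return tifffile.imread(p) if p.exists() else np.zeros(image.shape[:2], np.int32)

    truth_path = d / f"{stem}_truth.json"
    truth = {}
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = {
            int(cid): CellTruth(
                fractions=tuple(v["fractions"]),
                mito_classes={int(k): c for k, c in v["mito_classes"].items()},
            )
            for cid, v in raw.items()
        }
    manifest = d / "manifest.csv"
    pixel = 0.1
    condition = None
    if manifest.exists():
        m = pd.read_csv(manifest)
        row = m[m["image"] == path.name]
        if len(row):
            pixel = float(row.iloc[0]["pixel_size_um"])
            condition = row.iloc[0]["condition"]
    return LabeledImage(
        image=image,
        pixel_size_um=pixel,
        nucleus_labels=_opt("_nuclei"),
        cell_labels=_opt("_cells"),
        mito_labels=_opt("_mito"),
        truth=truth,
        condition=condition,
    )


def save_direction_graph(graph, path) -> None:
    payload = {
        "threshold": graph.threshold,
        "edges": [{"from": a, "to": b, "rmse": r} for a, b, r in graph.edges],
        "discarded": [{"from": a, "to": b, "rmse": r} for a, b, r in graph.discarded],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_models_json(models, path) -> None:
    payload = [
        {
            "input": m.input_var,
            "output": m.output_var,
            "hypothesis": m.hypothesis,
            "rmse": m.rmse,
            "premises": [
                {"label": mf.label, "c": mf.c, "sigma": mf.sigma} for mf in m.premises
            ],
            "consequents": np.asarray(m.consequents).tolist(),
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
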