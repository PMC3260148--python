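"""Convenience workflows combining simulation, segmentation and features.

These are the package's equivalents of the bench protocol: build training
sets of cropped single-cell images per morphology class, extract features,
train/evaluate the classifier, and classify cells in situ inside full
multi-cell images against their ground truth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .classify import RFModel, major_class, predict_scores, train_rf
from .features import FEATURE_COLUMNS, extract_features
from .imaging import segment_image
from .simulate import CLASS_NAMES, generate_cell_image, generate_image_set

_MIX = {
    "networked": (1.0, 0.0, 0.0),
    "fragmented": (0.0, 1.0, 0.0),
    "swollen": (0.0, 0.0, 1.0),
}


def build_training_features(
    n_per_class: int,
    seed: int = 0,
    n_batches: int = 2,
    crop_shape: tuple[int, int] = (200, 200),
) -> pd.DataFrame:
    """Features of cropped single-cell images, ``n_per_class`` per class.

    Each cropped cell is rendered, segmented and measured exactly as full
    images are.  Cells are tagged with a synthetic experimental batch
    (alternating), mirroring training sets assembled from separate imaging
    sessions.  Returns a DataFrame with the 69 feature columns plus
    ``label`` and ``batch``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls in CLASS_NAMES:
            made = 0
            while made < n_per_class:
                img = generate_cell_image(
                    _MIX[cls],
                    1,
                    image_shape=crop_shape,
                    seed=int(rng.integers(2**31)),
                    cell_radius_px=(55, 75),
                )
                seg = segment_image(img.dna, img.gfp)
                if len(seg.cell_index) != 1:
                    continue  # segmentation failed on this render; draw again
                feats = extract_features(seg, img.gfp, img.pixel_size_um)
                feats["label"] = cls
                feats["batch"] = made % n_batches
                rows.append(feats)
                made += 1
    return pd.concat(rows, ignore_index=True)


def classify_in_situ(
    model: RFModel,
    n_cells: int,
    seed: int = 0,
    cells_per_image: int = 6,
) -> pd.DataFrame:
    """Classify cells inside full multi-cell images against ground truth.

    Pure-class multi-cell images are generated (classes cycled evenly),
    segmented from scratch, and every segmented cell is matched to the
    ground-truth cell with which it overlaps most.  Returns one row per
    matched cell with the true class, predicted major class, and scores.
    """
    per_class = int(np.ceil(n_cells / len(CLASS_NAMES)))
    spec = {cls: (_MIX[cls], per_class) for cls in CLASS_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        images, _ = generate_image_set(spec, seed=seed, cells_per_image=cells_per_image)
        rows = []
        for img_i, img in enumerate(images):
            seg = segment_image(img.dna, img.gfp)
            if not seg.cell_index:
                continue
            feats = extract_features(seg, img.gfp, img.pixel_size_um, image_id=str(img_i))
            scores = predict_scores(model, feats)
            pred = np.atleast_1d(major_class(scores))
            for row_i, cell_id in enumerate(feats["cell_id"]):
                seg_mask = seg.cell_labels == cell_id
                overlap = np.bincount(img.cell_labels[seg_mask])
                overlap[0] = 0
                if overlap.sum() == 0:
                    continue
                true_cell = int(np.argmax(overlap))
                fr = img.truth[true_cell].fractions
                true_cls = CLASS_NAMES[int(np.argmax(fr))]
                rows.append(
                    {
                        "image_id": img_i,
                        "cell_id": cell_id,
                        "true_class": true_cls,
                        "predicted_class": pred[row_i],
                        **{c: float(scores.iloc[row_i][c]) for c in CLASS_NAMES},
                    }
                )
    return pd.DataFrame(rows)


def train_default_classifier(
    n_per_class: int = 60, seed: int = 0, n_trees: int = 500
) -> tuple[RFModel, pd.DataFrame]:
    """Train a forest on a freshly generated cropped-cell training set."""
    feats = build_training_features(n_per_class, seed=seed)
    model = train_rf(
        feats,
        feats["label"].to_numpy(),
        feats["batch"].to_numpy(),
        n_trees=n_trees,
        seed=seed,
        feature_names=list(FEATURE_COLUMNS),
    )
    return model, feats
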