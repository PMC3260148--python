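"""Per-cell morphology feature extraction: the 69-feature schema.

Each cell yields exactly 69 real-valued features in four groups:

* nucleus shape (6): area, perimeter, form factor, eccentricity, solidity,
  extent;
* cell shape (6): the same set on the cell outline;
* mitochondrial aggregates (21): count, total area, cell-area fraction,
  mean and StDev of the six per-mitochondrion shape features, mean and StDev
  of mitochondrion-to-nucleus centroid distance, mean nearest-neighbour
  centroid distance, median area, median perimeter, and the fraction of
  cellular GFP intensity integrated over mitochondria;
* Zernike (36): per-cell mean magnitude |Z(n, m)| of per-mitochondrion
  Zernike moments for all degrees n <= 10, m >= 0, n - m even.

Lengths are reported in micrometers and areas in square micrometers
(perimeter = Crofton 4-direction estimate x pixel size; form factor =
4*pi*area/perimeter^2).  Cells with zero mitochondria get declared defaults
(count 0, aggregate statistics 0) and are flagged by the segmentation stage.
"""

from __future__ import annotations

from math import factorial

import numpy as np
import pandas as pd
from skimage.measure import perimeter_crofton, regionprops

from .imaging import SegmentationResult

#: (n, m) index pairs of the 36 Zernike magnitudes, lexicographic order.
ZERNIKE_INDICES: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(11) for m in range(n + 1) if (n - m) % 2 == 0
)

_SHAPE_FEATURES = ("area", "perimeter", "form_factor", "eccentricity", "solidity", "extent")

FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"nuc_{f}" for f in _SHAPE_FEATURES)
    + tuple(f"cell_{f}" for f in _SHAPE_FEATURES)
    + (
        "mito_count",
        "mito_total_area",
        "mito_area_fraction",
    )
    + tuple(f"mito_{f}_mean" for f in _SHAPE_FEATURES)
    + tuple(f"mito_{f}_sd" for f in _SHAPE_FEATURES)
    + (
        "mito_nucleus_dist_mean",
        "mito_nucleus_dist_sd",
        "mito_nn_dist_mean",
        "mito_area_median",
        "mito_perimeter_median",
        "mito_intensity_fraction",
    )
    + tuple(f"zernike_{n}_{m}" for n, m in ZERNIKE_INDICES)
)

assert len(FEATURE_COLUMNS) == 69


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_nm evaluated at rho (n <= 10: direct sum)."""
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_magnitudes(mask: np.ndarray, max_degree: int = 10) -> np.ndarray:
    """Zernike moment magnitudes of a binary mask on its enclosing disk.

    The mask is centred at its centroid and scaled by the maximum centroid
    distance (its minimum enclosing disk); moments are averaged over the
    object pixels, so magnitudes are invariant to translation, scale, and —
    being magnitudes — rotation.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    radius = np.sqrt(dy**2 + dx**2).max()
    if radius == 0:  # single pixel
        radius = 1.0
    rho = np.sqrt(dy**2 + dx**2) / radius
    theta = np.arctan2(dy, dx)
    indices = [(n, m) for n, m in ZERNIKE_INDICES if n <= max_degree]
    mags = np.empty(len(indices))
    npix = mask.sum()
    for i, (n, m) in enumerate(indices):
        v = _radial_poly(n, m, rho) * np.exp(-1j * m * theta)
        mags[i] = np.abs((n + 1) / np.pi * v.sum() / npix)
    return mags


def _shape_features(mask: np.ndarray, pixel_size_um: float) -> dict[str, float]:
    props = regionprops(mask.astype(np.uint8))[0]
    area = props.area * pixel_size_um**2
    per = perimeter_crofton(mask, directions=4) * pixel_size_um
    ff = 4 * np.pi * area / per**2 if per > 0 else 0.0
    return {
        "area": float(area),
        "perimeter": float(per),
        "form_factor": float(ff),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
    }


def _crop(labels: np.ndarray, obj_id: int) -> np.ndarray:
    ys, xs = np.nonzero(labels == obj_id)
    return (labels[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1] == obj_id)


def extract_features(
    segmentation: SegmentationResult,
    gfp_channel: np.ndarray,
    pixel_size_um: float,
    image_id: str | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """One row per cell with the 69 feature columns plus metadata.

    Metadata columns (``cell_id``, optional ``image_id``/``condition``)
    precede the feature block; downstream consumers select
    :data:`FEATURE_COLUMNS`.
    """
    gfp = np.asarray(gfp_channel, dtype=float)
    rows = []
    nuc_centroids = {
        p.label: p.centroid for p in regionprops(segmentation.nucleus_labels)
    }
    mito_props = {p.label: p for p in regionprops(segmentation.mito_labels)}
    for cell_id, (nuc_id, mito_ids) in sorted(segmentation.cell_index.items()):
        row: dict[str, float] = {}
        cell_mask = _crop(segmentation.cell_labels, cell_id)
        nuc_mask = _crop(segmentation.nucleus_labels, nuc_id)
        for k, v in _shape_features(nuc_mask, pixel_size_um).items():
            row[f"nuc_{k}"] = v
        for k, v in _shape_features(cell_mask, pixel_size_um).items():
            row[f"cell_{k}"] = v

        n_mito = len(mito_ids)
        row["mito_count"] = float(n_mito)
        if n_mito == 0:
            for f in _SHAPE_FEATURES:
                row[f"mito_{f}_mean"] = 0.0
                row[f"mito_{f}_sd"] = 0.0
            row.update(
                mito_total_area=0.0,
                mito_area_fraction=0.0,
                mito_nucleus_dist_mean=0.0,
                mito_nucleus_dist_sd=0.0,
                mito_nn_dist_mean=0.0,
                mito_area_median=0.0,
                mito_perimeter_median=0.0,
                mito_intensity_fraction=0.0,
            )
            for n, m in ZERNIKE_INDICES:
                row[f"zernike_{n}_{m}"] = 0.0
        else:
            per_mito = {f: [] for f in _SHAPE_FEATURES}
            centroids = []
            zmags = np.zeros(len(ZERNIKE_INDICES))
            for mid in mito_ids:
                m_mask = _crop(segmentation.mito_labels, mid)
                for k, v in _shape_features(m_mask, pixel_size_um).items():
                    per_mito[k].append(v)
                centroids.append(mito_props[mid].centroid)
                zmags += zernike_magnitudes(m_mask)
            zmags /= n_mito
            for f in _SHAPE_FEATURES:
                vals = np.asarray(per_mito[f])
                row[f"mito_{f}_mean"] = float(vals.mean())
                row[f"mito_{f}_sd"] = float(vals.std())  # population StDev
            areas = np.asarray(per_mito["area"])
            row["mito_total_area"] = float(areas.sum())
            row["mito_area_fraction"] = float(areas.sum() / row["cell_area"])
            ncy, ncx = nuc_centroids[nuc_id]
            dists = (
                np.sqrt(
                    [(cy - ncy) ** 2 + (cx - ncx) ** 2 for cy, cx in centroids]
                )
                * pixel_size_um
            )
            row["mito_nucleus_dist_mean"] = float(dists.mean())
            row["mito_nucleus_dist_sd"] = float(dists.std())
            if n_mito > 1:
                pts = np.asarray(centroids)
                dd = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
                np.fill_diagonal(dd, np.inf)
                row["mito_nn_dist_mean"] = float(dd.min(axis=1).mean() * pixel_size_um)
            else:
                row["mito_nn_dist_mean"] = 0.0
            row["mito_area_median"] = float(np.median(areas))
            row["mito_perimeter_median"] = float(np.median(per_mito["perimeter"]))
            cell_intensity = gfp[segmentation.cell_labels == cell_id].sum()
            mito_intensity = gfp[
                (segmentation.cell_labels == cell_id) & (segmentation.mito_labels > 0)
            ].sum()
            row["mito_intensity_fraction"] = float(
                mito_intensity / cell_intensity if cell_intensity > 0 else 0.0
            )
            for i, (n, m) in enumerate(ZERNIKE_INDICES):
                row[f"zernike_{n}_{m}"] = float(zmags[i])

        meta: dict[str, object] = {"cell_id": cell_id}
        if image_id is not None:
            meta["image_id"] = image_id
        if condition is not None:
            meta["condition"] = condition
        rows.append({**meta, **{c: row[c] for c in FEATURE_COLUMNS}})
    if not rows:
        raise ValueError("segmentation contains no cells")
    return pd.DataFrame(rows)
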