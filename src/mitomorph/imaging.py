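"""Image-analysis pipeline: illumination correction and segmentation.

The chain mirrors a standard high-content workflow: correct the smooth
illumination field, segment nuclei from the DNA channel (primary objects),
propagate cell boundaries from the GFP channel seeded by the nuclei
(secondary objects), then segment individual mitochondria within each cell
(tertiary objects) by white-top-hat enhancement and per-cell thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, remove_small_objects, white_tophat
from skimage.segmentation import watershed


@dataclass
class SegmentationResult:
    """Label rasters plus the per-cell object index.

    ``cell_index`` maps cell id -> (nucleus id, list of mitochondrion ids);
    background is 0 everywhere.  ``flags`` records cells with anomalies
    (border contact, no mitochondrial foreground, seed outside foreground).
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    mito_labels: np.ndarray
    cell_index: dict[int, tuple[int, list[int]]]
    flags: dict[int, list[str]] = field(default_factory=dict)


def correct_illumination(channel: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Divide out a smooth background field; rescale to preserve the mean.

    The field is a wide Gaussian blur of the image itself (sigma defaults to
    image_size / 8), which captures lamp/vignetting gradients but not
    cell-scale structure.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D raster")
    if img.sum() <= 0:
        raise ValueError("cannot correct an all-zero image")
    if sigma is None:
        sigma = max(img.shape) / 8.0
    background = gaussian(img, sigma=sigma, preserve_range=True)
    background = np.clip(background, np.finfo(float).eps, None)
    corrected = img / background
    corrected *= img.mean() / corrected.mean()
    return corrected


def segment_nuclei(
    dna_channel: np.ndarray,
    min_size_px: int = 200,
    split_min_distance_px: int = 15,
) -> np.ndarray:
    """Otsu threshold + hole filling + watershed split + small-object filter."""
    img = np.asarray(dna_channel, dtype=float)
    smoothed = gaussian(img, sigma=2, preserve_range=True)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:  # constant image
        warnings.warn("no foreground found in DNA channel", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    fg = smoothed > thr
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=min_size_px - 1)
    if not fg.any():
        warnings.warn("no foreground found in DNA channel", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    # split touching nuclei on the distance transform
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=split_min_distance_px, labels=cc_label(fg), exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        return cc_label(fg).astype(np.int32)
    labels = watershed(-dist, markers, mask=fg)
    labels = remove_small_objects(labels, max_size=min_size_px - 1)
    return _relabel_sequential(labels)


def infer_cell_boundaries(
    gfp_channel: np.ndarray,
    nucleus_labels: np.ndarray,
    smooth_sigma: float = 3.0,
    nucleus_dilation_px: int = 5,
) -> np.ndarray:
    """Seeded propagation of cell boundaries from the GFP channel.

    Foreground = thresholded smoothed GFP channel, unioned with the dilated
    nuclei; cells are the watershed basins of the inverted smoothed intensity
    seeded at the nuclei.  Each returned region contains its seed nucleus
    entirely.

    The GFP channel is trimodal (background, diffuse cytosol, bright
    mitochondria), so a plain two-class Otsu lands between cytosol and
    mitochondria and would shrink cells to their brightest organelles; the
    lowest threshold of a three-class Otsu on log intensity (stable against
    the wide dynamic range of the organelle signal) separates background from
    cytosol instead.
    """
    if nucleus_labels.max() == 0:
        raise ValueError("need at least one nucleus seed")
    img = np.asarray(gfp_channel, dtype=float)
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    try:
        thr = np.expm1(threshold_multiotsu(np.log1p(np.clip(smoothed, 0, None)), classes=3)[0])
    except ValueError:  # fewer than 3 grey levels
        thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    fg |= dilation(nucleus_labels > 0, disk(nucleus_dilation_px))
    labels = watershed(-smoothed, markers=nucleus_labels.astype(np.int32), mask=fg)
    # guarantee nucleus containment even where the GFP foreground is weak
    missing = (nucleus_labels > 0) & (labels != nucleus_labels)
    labels[missing] = nucleus_labels[missing]
    return labels.astype(np.int32)


def segment_mitochondria(
    gfp_channel: np.ndarray,
    cell_labels: np.ndarray,
    tophat_radius_px: int = 20,
    min_size_px: int = 4,
) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Per-cell mitochondrion segmentation.

    White top-hat (disk structuring element) removes the diffuse cytosolic
    background and any constant offset; a per-cell Otsu threshold on the
    enhanced image then separates mitochondria, which are labeled by
    8-connected components and size-filtered.  Cells with no mitochondrial
    foreground yield an empty list (not an error).

    Returns the global mitochondrion label raster and a map
    cell id -> mitochondrion ids.
    """
    if cell_labels.max() == 0:
        raise ValueError("need at least one cell")
    img = np.asarray(gfp_channel, dtype=float)
    mito_labels = np.zeros(img.shape, dtype=np.int32)
    per_cell: dict[int, list[int]] = {}
    selem = disk(tophat_radius_px)
    next_id = 1
    for cell_id in np.unique(cell_labels)[1:] if 0 in cell_labels else np.unique(cell_labels):
        cell_mask = cell_labels == cell_id
        ys, xs = np.nonzero(cell_mask)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        pad = tophat_radius_px + 1
        y0p, x0p = max(y0 - pad, 0), max(x0 - pad, 0)
        y1p, x1p = min(y1 + pad, img.shape[0]), min(x1 + pad, img.shape[1])
        crop = img[y0p:y1p, x0p:x1p]
        crop_mask = cell_mask[y0p:y1p, x0p:x1p]
        enhanced = white_tophat(crop, selem)
        vals = enhanced[crop_mask]
        per_cell[int(cell_id)] = []
        if vals.size == 0 or vals.max() <= 0:
            continue
        try:
            thr = threshold_otsu(vals)
        except ValueError:
            continue
        fg = (enhanced > thr) & crop_mask
        fg = remove_small_objects(fg, max_size=min_size_px - 1)
        if not fg.any():
            continue
        labels = cc_label(fg, connectivity=2)
        ids = []
        for obj in range(1, labels.max() + 1):
            obj_mask = labels == obj
            mito_labels[y0p:y1p, x0p:x1p][obj_mask] = next_id
            ids.append(next_id)
            next_id += 1
        per_cell[int(cell_id)] = ids
    return mito_labels, per_cell


def segment_image(
    dna_channel: np.ndarray,
    gfp_channel: np.ndarray,
    correct: bool = True,
    nucleus_min_size_px: int = 200,
    tophat_radius_px: int = 20,
    mito_min_size_px: int = 4,
) -> SegmentationResult:
    """Full segmentation chain on a two-channel image."""
    dna = correct_illumination(dna_channel) if correct else np.asarray(dna_channel, float)
    gfp = correct_illumination(gfp_channel) if correct else np.asarray(gfp_channel, float)
    nuclei = segment_nuclei(dna, min_size_px=nucleus_min_size_px)
    if nuclei.max() == 0:
        return SegmentationResult(
            nucleus_labels=nuclei,
            cell_labels=np.zeros_like(nuclei),
            mito_labels=np.zeros_like(nuclei),
            cell_index={},
        )
    cells = infer_cell_boundaries(gfp, nuclei)
    mito, per_cell = segment_mitochondria(
        gfp, cells, tophat_radius_px=tophat_radius_px, min_size_px=mito_min_size_px
    )
    flags: dict[int, list[str]] = {}
    border = np.zeros(cells.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    cell_index: dict[int, tuple[int, list[int]]] = {}
    for cell_id in sorted(per_cell):
        cell_index[cell_id] = (cell_id, per_cell[cell_id])
        cell_flags = []
        if (cells[border] == cell_id).any():
            cell_flags.append("touches_border")
        if not per_cell[cell_id]:
            cell_flags.append("no_mitochondria")
        if cell_flags:
            flags[cell_id] = cell_flags
    return SegmentationResult(
        nucleus_labels=nuclei,
        cell_labels=cells,
        mito_labels=mito,
        cell_index=cell_index,
        flags=flags,
    )


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels)[1:] if 0 in labels else np.unique(labels), start=1):
        out[labels == old] = new
    return out
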