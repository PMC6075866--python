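"""Nuclear segmentation, cytoplasm-ring expansion and per-cell quantification.

Nuclei are found on the nuclear (DNA) channel of the reference cycle by Otsu
thresholding, split with a distance-transform-seeded watershed, and expanded
outward by a fixed number of pixels (3 px at 10X, 6 px at 40X) to approximate
the cell boundary; the cytoplasm is the ring between the two. Mean and
integrated intensities are then measured per compartment across every cycle
and channel of the registered stack.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import expand_labels, watershed

from .imgprep import CycleStack

__all__ = [
    "ThresholdError",
    "binarize_nuclei",
    "split_nuclei",
    "expand_cytoplasm",
    "quantify",
    "segment_nuclei",
    "expansion_px_for_objective",
]

#: centripetal cytoplasm expansion in pixels keyed to objective magnification
EXPANSION_PX = {"10X": 3, "40X": 6}


class ThresholdError(RuntimeError):
    """Raised when the nuclear image has no separable foreground."""


def expansion_px_for_objective(objective: str) -> int:
    """Cytoplasm expansion distance for a given objective ('10X' -> 3 px, '40X' -> 6 px)."""
    try:
        return EXPANSION_PX[objective.upper()]
    except KeyError:
        raise ValueError(f"unknown objective {objective!r}; expected one of {sorted(EXPANSION_PX)}")


def binarize_nuclei(
    nuclear_image: np.ndarray,
    min_area: int = 20,
    max_hole: int = 10,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Otsu-threshold the nuclear channel into a foreground mask.

    A mild Gaussian denoise (``smooth_sigma``) precedes thresholding so shot
    noise does not fragment faint nuclei. Holes smaller than ``max_hole`` px
    are filled and objects below ``min_area`` px removed.
    """
    img = np.asarray(nuclear_image, float)
    if np.ptp(img) == 0:
        raise ThresholdError("nuclear image is constant; no foreground to threshold")
    if smooth_sigma > 0:
        from skimage.filters import gaussian

        img = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        raise ThresholdError("Otsu threshold produced an empty foreground")
    mask = remove_small_holes(mask, max_size=max_hole)
    mask = remove_small_objects(mask, max_size=min_area)
    return mask


def split_nuclei(mask: np.ndarray, min_separation: int = 5) -> np.ndarray:
    """Split touching nuclei by watershed on the negative distance transform.

    Seeds are local maxima of the Euclidean distance transform separated by at
    least ``min_separation`` px (roughly the expected nuclear radius); each
    watershed basin becomes one nucleus label. Empty masks yield empty labels.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, np.int32)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_separation, labels=mask, exclude_border=False
    )
    seeds = np.zeros(mask.shape, np.int32)
    next_id = 1
    for y, x in peaks:
        seeds[y, x] = next_id
        next_id += 1
    # every connected component keeps at least one seed, else small nuclei
    # (no interior distance peak) would be silently dropped by the watershed
    comps, n_comp = ndimage.label(mask)
    seeded = set(np.unique(comps[seeds > 0])) - {0}
    for comp_id in range(1, n_comp + 1):
        if comp_id in seeded:
            continue
        sub = comps == comp_id
        y, x = np.unravel_index(np.argmax(np.where(sub, dist, -1)), mask.shape)
        seeds[y, x] = next_id
        next_id += 1
    labels = watershed(-dist, markers=seeds, mask=mask)
    return labels.astype(np.int32)


def expand_cytoplasm(
    nucleus_labels: np.ndarray, n_pixels: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Grow every nucleus outward by ``n_pixels`` to form the cell; ring = cytoplasm.

    Expansion is simultaneous for all labels; contested pixels go to the
    nearest nucleus (Euclidean), so neighboring cells never overlap and growth
    halts at the equidistance boundary. Returns (cell_labels,
    cytoplasm_labels); cytoplasm is the cell minus its nucleus.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    nucleus_labels = np.asarray(nucleus_labels)
    cell = expand_labels(nucleus_labels, distance=n_pixels)
    cyto = cell.copy()
    cyto[nucleus_labels > 0] = 0
    return cell, cyto


def _per_label_stats(
    values: np.ndarray, labels: np.ndarray, ids: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean / integrated intensity over valid pixels per label; counts of valid pixels."""
    lab = np.where(valid, labels, 0)
    sums = ndimage.sum_labels(values, lab, ids)
    counts = ndimage.sum_labels(np.ones_like(values), lab, ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return means, sums, counts


def quantify(
    nucleus_labels: np.ndarray,
    cell_labels: np.ndarray,
    cytoplasm_labels: np.ndarray,
    stack: CycleStack,
    field_id: int = 0,
    max_invalid_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-cell intensity table across all cycles, channels and compartments.

    Columns follow ``cyc{c}_ch{k}_{compartment}_{mean|int}``. Integrated
    intensity is the plain pixel sum, so ``int == mean * n_valid_pixels``
    exactly. Cells touching the image border, or with more than
    ``max_invalid_frac`` invalid pixels in any cycle, are flagged
    ``valid=False`` (kept, not dropped — integrity analysis needs the counts).
    """
    ids = np.unique(nucleus_labels)
    ids = ids[ids > 0]
    compartments = {"nuc": nucleus_labels, "cell": cell_labels, "cyto": cytoplasm_labels}
    base_cols = [
        "cell_id", "centroid_x", "centroid_y", "nucleus_area", "cell_area",
        "field_id", "valid",
    ]
    if ids.size == 0:
        cols = base_cols + [
            f"cyc{c}_ch{k}_{comp}_{stat}"
            for c in range(1, stack.n_cycles + 1)
            for k in range(stack.n_channels)
            for comp in compartments
            for stat in ("mean", "int")
        ]
        return pd.DataFrame(columns=cols)

    cy, cx = np.array(ndimage.center_of_mass(np.ones_like(nucleus_labels),
                                             nucleus_labels, ids)).T
    nuc_area = ndimage.sum_labels(np.ones_like(nucleus_labels, float), nucleus_labels, ids)
    cell_area = ndimage.sum_labels(np.ones_like(cell_labels, float), cell_labels, ids)

    border = np.zeros(cell_labels.shape, bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(cell_labels[border])) - {0}

    table: dict[str, np.ndarray] = {
        "cell_id": ids.astype(int),
        "centroid_x": cx,
        "centroid_y": cy,
        "nucleus_area": nuc_area,
        "cell_area": cell_area,
        "field_id": np.full(ids.size, field_id, int),
    }
    valid_flag = np.array([i not in border_ids for i in ids])
    cell_npix = ndimage.sum_labels(np.ones_like(cell_labels, float), cell_labels, ids)
    for c in range(1, stack.n_cycles + 1):
        v = stack.valid[c - 1]
        valid_npix = ndimage.sum_labels(v.astype(float), cell_labels, ids)
        frac_invalid = 1.0 - np.where(cell_npix > 0, valid_npix / cell_npix, 0.0)
        cycle_ok = frac_invalid <= max_invalid_frac
        valid_flag &= cycle_ok
        for k in range(stack.n_channels):
            img = stack.data[c - 1, k]
            for comp, lab in compartments.items():
                means, sums, _ = _per_label_stats(img, lab, ids, v)
                means = np.where(cycle_ok, means, np.nan)
                sums = np.where(cycle_ok, sums, np.nan)
                table[f"cyc{c}_ch{k}_{comp}_mean"] = means
                table[f"cyc{c}_ch{k}_{comp}_int"] = sums
    table["valid"] = valid_flag
    df = pd.DataFrame(table).sort_values("cell_id").reset_index(drop=True)
    return df[base_cols + [c for c in df.columns if c not in base_cols]]


def segment_nuclei(
    nuclear_image: np.ndarray,
    min_separation: int = 5,
    min_area: int = 20,
    expansion_px: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full segmentation chain: threshold, watershed split, cytoplasm expansion.

    Returns (nucleus_labels, cell_labels, cytoplasm_labels).
    """
    mask = binarize_nuclei(nuclear_image, min_area=min_area)
    nuc = split_nuclei(mask, min_separation=min_separation)
    cell, cyto = expand_cytoplasm(nuc, n_pixels=expansion_px)
    return nuc, cell, cyto
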