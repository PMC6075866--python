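"""Per-cycle quality control: fluorophore inactivation, tissue integrity,
dynamic range, distribution overlap/concordance and nominal optical resolution.

Cyclic immunofluorescence alternates staining with chemical fluorophore
inactivation; these diagnostics quantify how completely dye is extinguished
between cycles (inactivation fold), how much tissue detaches over repeated
handling (integrity curve), how separable signal is from background (dynamic
range, log10 of the 95th/5th intensity percentile ratio), and how concordant
two staining runs are (overlap score: ratio of the overlapping to the total
area under the two intensity distributions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "QCReport",
    "inactivation_fold",
    "match_nuclei",
    "integrity_curve",
    "dynamic_range",
    "overlap_score",
    "classify_concordance",
    "nominal_resolution",
]

_EPS = np.finfo(float).eps


@dataclass
class QCReport:
    """Aggregated cycle-QC results."""

    inactivation_folds: dict = field(default_factory=dict)  # (cycle, channel) -> fold
    integrity: list = field(default_factory=list)  # per-cycle retained fraction
    dynamic_ranges: dict = field(default_factory=dict)  # (cycle, channel) -> DR log10
    overlaps: dict = field(default_factory=dict)  # (name_a, name_b) -> (score, class)
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "inactivation_folds": {f"{c}_{k}": v for (c, k), v in self.inactivation_folds.items()},
            "integrity": list(map(float, self.integrity)),
            "dynamic_ranges": {f"{c}_{k}": v for (c, k), v in self.dynamic_ranges.items()},
            "overlaps": {f"{a}|{b}": [s, cls] for (a, b), (s, cls) in self.overlaps.items()},
            "parameters": self.parameters,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def inactivation_fold(
    pre_bleach: np.ndarray, post_bleach: np.ndarray, background: float = 0.0
) -> float:
    """Fold reduction of the median per-cell intensity across a bleach step.

    fold = (median(pre) - background) / max(median(post) - background, eps).
    Medians make the estimate robust to segmentation outliers.
    """
    pre = np.asarray(pre_bleach, float)
    post = np.asarray(post_bleach, float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("empty cell set")
    num = np.median(pre) - background
    den = max(np.median(post) - background, _EPS)
    return float(max(num, 0.0) / den)


def match_nuclei(
    table_a: pd.DataFrame, table_b: pd.DataFrame, max_dist: float
) -> tuple[np.ndarray, float]:
    """Greedy mutual-nearest-neighbor matching of cell centroids across cycles.

    Two cells match when each is the other's nearest neighbor and they lie
    within ``max_dist`` px (registered coordinates). Returns (pairs of
    positional indices, retained fraction = matched / |table_a|).
    """
    if len(table_a) == 0:
        return np.empty((0, 2), int), 0.0
    if len(table_b) == 0:
        return np.empty((0, 2), int), 0.0
    xa = table_a[["centroid_x", "centroid_y"]].to_numpy()
    xb = table_b[["centroid_x", "centroid_y"]].to_numpy()
    ta, tb = cKDTree(xa), cKDTree(xb)
    d_ab, j_ab = tb.query(xa)  # nearest b for each a
    _, i_ba = ta.query(xb)  # nearest a for each b
    mutual = (i_ba[j_ab] == np.arange(len(xa))) & (d_ab <= max_dist)
    pairs = np.column_stack([np.nonzero(mutual)[0], j_ab[mutual]])
    return pairs, float(len(pairs) / len(xa))


def integrity_curve(cell_tables: list[pd.DataFrame]) -> np.ndarray:
    """Nucleus counts per cycle normalized to cycle 1.

    Values can slightly exceed 1 — cycle-to-cycle segmentation fluctuation —
    which is expected, not an error.
    """
    if len(cell_tables) < 2:
        raise ValueError("need at least two cycles")
    counts = np.array([len(t) for t in cell_tables], float)
    if counts[0] == 0:
        raise ValueError("no nuclei detected at cycle 1")
    return counts / counts[0]


def dynamic_range(values: np.ndarray) -> float:
    """log10 ratio of the 95th to 5th percentile intensity.

    Intensities below the 5th percentile are treated as background noise, so
    the ratio is a rough signal-to-noise estimate; it is invariant to positive
    rescaling of the intensities.
    """
    v = np.asarray(values, float)
    if v.size < 20:
        raise ValueError("need at least 20 values for stable percentiles")
    p5, p95 = np.percentile(v, [5, 95])
    if p5 <= 0:
        raise ValueError(
            "5th percentile is non-positive; add a background offset before computing DR"
        )
    return float(np.log10(p95 / p5))


def overlap_score(values_a: np.ndarray, values_b: np.ndarray, n_bins: int = 100) -> float:
    """Concordance of two intensity distributions in [0, 1].

    Both samples are histogram-estimated as unit-area densities on a shared
    support (union of their 0.1–99.9 percentile ranges); the score is the
    trapezoidal integral of the pointwise minimum divided by that of the
    pointwise maximum — 1 for identical histograms, 0 for disjoint supports.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(np.percentile(a, 0.1), np.percentile(b, 0.1))
    hi = max(np.percentile(a, 99.9), np.percentile(b, 99.9))
    if hi <= lo:  # all values identical in both samples
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    da, _ = np.histogram(np.clip(a, lo, hi), bins=edges, density=True)
    db, _ = np.histogram(np.clip(b, lo, hi), bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    overlap_auc = np.trapezoid(np.minimum(da, db), centers)
    total_auc = np.trapezoid(np.maximum(da, db), centers)
    if total_auc <= 0:
        return 1.0
    return float(np.clip(overlap_auc / total_auc, 0.0, 1.0))


def classify_concordance(score: float) -> str:
    """Overlap-score band: > 0.8 high, 0.6–0.8 moderate (inclusive), < 0.6 low."""
    if not (0.0 <= score <= 1.0):
        raise ValueError("score must lie in [0, 1]")
    if score > 0.8:
        return "high"
    if score >= 0.6:
        return "moderate"
    return "low"


def nominal_resolution(
    wavelength_nm: float, numerical_aperture: float, mode: str = "widefield"
) -> float:
    """Nominal optical resolution in µm: 0.61·λ/NA (widefield) or 0.4·λ/NA (confocal)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if not (0.0 < numerical_aperture <= 1.7):
        raise ValueError("numerical aperture must lie in (0, 1.7]")
    factors = {"widefield": 0.61, "confocal": 0.4}
    try:
        factor = factors[mode]
    except KeyError:
        raise ValueError(f"mode must be one of {sorted(factors)}")
    return factor * wavelength_nm / numerical_aperture / 1000.0
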