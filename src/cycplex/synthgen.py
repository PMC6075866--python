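"""Synthetic multiplexed-tissue image generator.

Produces multi-cycle, multi-channel tiled image sets with known ground truth:
cell positions and sizes, per-cluster lognormal marker expression, tumor/stroma
region labels, per-cycle rigid stage drift, multiplicative illumination shading,
cycle-decaying autofluorescence, Poisson/read noise and per-cycle cell dropout.
Every downstream stage of the pipeline (correction, stitching, registration,
segmentation, QC, phenotyping, spatial statistics) can therefore be tested
against a truth manifest instead of real slide scans.

Conventions: 0-based pixel indices, (row, col) = (y, x), origin top-left.
Channel 0 of every cycle is the nuclear (DNA) stain; the remaining channels
carry marker signal. Marker index for (cycle c, channel k>=1) is
``(c - 1) * (channels_per_cycle - 1) + (k - 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PhantomConfig",
    "TissuePhantom",
    "AcquisitionModel",
    "PlacementError",
    "generate_phantom",
    "render_cycles",
    "render_ideal_canvas",
    "simulate_bleach_pair",
    "marker_index",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell density is infeasible under the hard-core constraint."""


def marker_index(cycle: int, channel: int, channels_per_cycle: int = 4) -> int:
    """Column of the expression matrix imaged at (cycle, channel); channel 0 is nuclear."""
    if channel < 1:
        raise ValueError("channel 0 is the nuclear stain, not a marker")
    return (cycle - 1) * (channels_per_cycle - 1) + (channel - 1)


@dataclass
class PhantomConfig:
    """Parameters of the ground-truth tissue.

    ``cluster_medians`` is a (K, n_markers) array of per-cluster lognormal
    medians (the lognormal ``exp(mu)``); ``lognormal_sigma`` is the shared
    log-scale sd. ``dropout_rate`` is the fraction of cells that detach by the
    final cycle; dropout is spatially biased toward sparse areas with strength
    ``dropout_density_bias`` (0 = unbiased).
    """

    n_cells: int = 500
    canvas_shape: tuple[int, int] = (480, 480)  # (height, width) px
    nuclear_radius: float = 6.0  # px (~8 µm nucleus at 0.65 µm/px)
    radius_jitter: float = 0.5  # sd of per-cell radius perturbation, px
    n_clusters: int = 3
    cluster_weights: tuple[float, ...] | None = None
    n_markers: int | None = None  # defaults to 3 markers/cycle × n_cycles
    cluster_medians: np.ndarray | None = None  # (K, n_markers)
    lognormal_sigma: float = 0.35
    nuclear_brightness: float = 3000.0  # peak-scaled amplitude units
    dropout_rate: float = 0.25
    dropout_density_bias: float = 0.5
    n_cycles: int = 3
    pixel_size_um: float = 0.65
    margin: float = 12.0  # keep-out border, px
    region_split: float = 0.5  # tumor occupies x < split * width

    def resolve(self, rng: np.random.Generator) -> "PhantomConfig":
        cfg = PhantomConfig(**{**self.__dict__})
        if cfg.n_markers is None:
            cfg.n_markers = 3 * cfg.n_cycles
        if cfg.cluster_weights is None:
            cfg.cluster_weights = tuple(np.full(cfg.n_clusters, 1.0 / cfg.n_clusters))
        w = np.asarray(cfg.cluster_weights, float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("cluster weights must sum to 1")
        if cfg.n_clusters < 1:
            raise ValueError("need at least one cluster")
        if cfg.cluster_medians is None:
            # Each cluster is bright (median e^7) in its own block of markers and
            # dim (e^5) elsewhere -> well-separated lognormal mixture spanning
            # ~1 log10 of dynamic range, comparable to the nuclear stain.
            med = np.full((cfg.n_clusters, cfg.n_markers), np.exp(5.0))
            block = max(1, cfg.n_markers // cfg.n_clusters)
            for k in range(cfg.n_clusters):
                lo = (k * block) % cfg.n_markers
                med[k, lo : lo + block] = np.exp(7.0)
            cfg.cluster_medians = med
        cfg.cluster_medians = np.asarray(cfg.cluster_medians, float)
        if cfg.cluster_medians.shape != (cfg.n_clusters, cfg.n_markers):
            raise ValueError("cluster_medians must be (n_clusters, n_markers)")
        return cfg


@dataclass
class TissuePhantom:
    """Ground-truth synthetic tissue."""

    cells: pd.DataFrame  # cell_id, x, y, radius, region, cluster, dropout_cycle
    expression: np.ndarray  # (n_cells, n_markers), arbitrary fluorescence units
    canvas_shape: tuple[int, int]
    pixel_size_um: float
    region_split_x: float  # tumor/stroma boundary column
    config: PhantomConfig

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def surviving(self, cycle: int) -> np.ndarray:
        """Boolean mask of cells still attached at the given 1-based cycle."""
        dc = self.cells["dropout_cycle"].to_numpy()
        return ~(np.isfinite(dc) & (dc <= cycle))

    def region_mask(self) -> np.ndarray:
        """Boolean mask, True where the canvas belongs to the tumor region."""
        h, w = self.canvas_shape
        mask = np.zeros((h, w), bool)
        mask[:, : int(round(self.region_split_x))] = True
        return mask


@dataclass
class AcquisitionModel:
    """Tiled multi-cycle acquisition: grid layout, drift, shading, background and noise."""

    grid_shape: tuple[int, int] = (2, 2)  # (rows, cols) of tiles
    tile_shape: tuple[int, int] = (256, 256)
    overlap: float = 0.1  # fraction of tile size shared with the neighbor
    n_cycles: int = 3
    channels_per_cycle: int = 4
    offsets: np.ndarray | None = None  # (n_cycles, 3): dx, dy px, theta rad
    max_offset_px: float = 5.0  # used when offsets drawn randomly
    max_rotation_deg: float = 0.0
    shading_strength: float = 0.25  # 0 disables shading
    autofluorescence: np.ndarray | None = None  # per-cycle amplitude, non-increasing
    autofluorescence_start: float = 200.0
    autofluorescence_decay: float = 0.5  # geometric decay per cycle
    read_noise_sigma: float = 3.0
    photon_scale: float = 0.1  # photons per intensity unit for Poisson noise; 0 disables

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap < 0.5):
            raise ValueError("overlap fraction must lie in (0, 0.5)")
        if self.autofluorescence is not None:
            af = np.asarray(self.autofluorescence, float)
            if np.any(np.diff(af) > 1e-12):
                raise ValueError("autofluorescence amplitudes must be non-increasing")

    def autofluorescence_schedule(self) -> np.ndarray:
        """Per-cycle additive background amplitude (non-increasing across cycles)."""
        if self.autofluorescence is not None:
            return np.asarray(self.autofluorescence, float)
        c = np.arange(self.n_cycles)
        return self.autofluorescence_start * self.autofluorescence_decay**c

    @property
    def stride(self) -> tuple[int, int]:
        th, tw = self.tile_shape
        return (int(round(th * (1 - self.overlap))), int(round(tw * (1 - self.overlap))))

    def mosaic_shape(self) -> tuple[int, int]:
        rows, cols = self.grid_shape
        th, tw = self.tile_shape
        sy, sx = self.stride
        return (th + (rows - 1) * sy, tw + (cols - 1) * sx)


def _place_hardcore(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement with hard-core rejection (min spacing 1.5 radii)."""
    if cfg.n_cells == 0:
        return np.empty((0, 2))
    h, w = cfg.canvas_shape
    min_d = 1.5 * cfg.nuclear_radius
    max_attempts = 10 * cfg.n_cells * max(
        1, int(np.ceil((h * w) / max(1.0, cfg.n_cells * np.pi * min_d**2)))
    )
    # grid-bucketed neighbor lookup keeps placement O(n)
    cell = max(min_d, 1.0)
    buckets: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed {len(pts)}/{cfg.n_cells} cells in {attempts} attempts; "
                "density infeasible under the hard-core constraint"
            )
        x = rng.uniform(cfg.margin, w - cfg.margin)
        y = rng.uniform(cfg.margin, h - cfg.margin)
        bi, bj = int(y // cell), int(x // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in buckets.get((bi + di, bj + dj), ()):
                    px, py = pts[idx]
                    if (px - x) ** 2 + (py - y) ** 2 < min_d**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((bi, bj), []).append(len(pts))
            pts.append((x, y))
    return np.asarray(pts)


def _sample_dropout(
    xy: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell dropout cycle (NaN = never), biased toward low-density areas."""
    n = len(xy)
    drop = np.full(n, np.nan)
    if n == 0 or cfg.dropout_rate <= 0 or cfg.n_cycles < 2:
        return drop
    n_drop = rng.binomial(n, cfg.dropout_rate)
    if n_drop == 0:
        return drop
    if cfg.dropout_density_bias > 0 and n > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        kth = min(5, n - 1)
        d, _ = tree.query(xy, k=kth + 1)
        local = d[:, kth]  # distance to 5th neighbor: large = sparse
        s = local / local.mean()
        weights = np.exp(cfg.dropout_density_bias * (s - 1.0))
    else:
        weights = np.ones(n)
    p = weights / weights.sum()
    chosen = rng.choice(n, size=min(n_drop, n), replace=False, p=p)
    drop[chosen] = rng.integers(2, cfg.n_cycles + 1, size=len(chosen))
    return drop


def generate_phantom(config: PhantomConfig, seed: int) -> TissuePhantom:
    """Draw a ground-truth tissue phantom; deterministic for a fixed seed.

    Cells are placed by dart throwing with hard-core rejection, assigned a
    cluster by the mixture weights, and given lognormal marker expression with
    per-cluster medians. Region labels split the canvas into tumor (left of
    the split column) and stroma.
    """
    rng = np.random.default_rng(seed)
    cfg = config.resolve(rng)
    xy = _place_hardcore(cfg, rng)
    n = len(xy)
    radii = np.clip(
        cfg.nuclear_radius + rng.normal(0, cfg.radius_jitter, n),
        0.5 * cfg.nuclear_radius,
        1.5 * cfg.nuclear_radius,
    )
    clusters = rng.choice(cfg.n_clusters, size=n, p=np.asarray(cfg.cluster_weights)) + 1
    mu = np.log(cfg.cluster_medians)  # (K, M)
    expr = np.exp(rng.normal(mu[clusters - 1], cfg.lognormal_sigma)) if n else np.empty(
        (0, cfg.n_markers)
    )
    split_x = cfg.region_split * cfg.canvas_shape[1]
    regions = np.where(xy[:, 0] < split_x, "tumor", "stroma") if n else np.array([], dtype=object)
    dropout = _sample_dropout(xy, cfg, rng)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=int),
            "x": xy[:, 0] if n else np.array([]),
            "y": xy[:, 1] if n else np.array([]),
            "radius": radii,
            "region": regions,
            "cluster": clusters if n else np.array([], dtype=int),
            "dropout_cycle": dropout,
        }
    )
    return TissuePhantom(
        cells=cells,
        expression=np.asarray(expr, float),
        canvas_shape=cfg.canvas_shape,
        pixel_size_um=cfg.pixel_size_um,
        region_split_x=split_x,
        config=cfg,
    )


def _render_points(
    shape: tuple[int, int],
    xy: np.ndarray,
    radii: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Sum of isotropic Gaussian disks (sigma = radius/2, truncated at 3 sigma).

    ``amplitudes`` scale the kernel so its untruncated integral equals the
    amplitude times 2*pi*sigma^2 — i.e. the peak value is the amplitude.
    """
    img = np.zeros(shape, float)
    h, w = shape
    for (x, y), r, a in zip(xy, radii, amplitudes):
        sigma = r / 2.0
        ext = 3.0 * sigma
        x0, x1 = int(np.floor(x - ext)), int(np.ceil(x + ext)) + 1
        y0, y1 = int(np.floor(y - ext)), int(np.ceil(y + ext)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        kern = np.where(d2 <= ext**2, a * np.exp(-d2 / (2 * sigma**2)), 0.0)
        img[y0:y1, x0:x1] += kern
    return img


def _shading_field(shape: tuple[int, int], strength: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth strictly-positive multiplicative field with spatial mean 1."""
    h, w = shape
    if strength <= 0:
        return np.ones(shape)
    yy, xx = np.mgrid[0:h, 0:w]
    cx = w * rng.uniform(0.3, 0.7)
    cy = h * rng.uniform(0.3, 0.7)
    s = max(h, w) * 0.6
    field = np.exp(-(((xx - cx) / s) ** 2 + ((yy - cy) / s) ** 2) * strength * 4)
    field /= field.mean()
    return np.clip(field, 0.05, None)


def render_ideal_canvas(
    phantom: TissuePhantom, cycle: int, channel: int, channels_per_cycle: int = 4
) -> np.ndarray:
    """Noiseless, shading-free, unshifted canvas for one (cycle, channel)."""
    alive = phantom.surviving(cycle)
    cells = phantom.cells[alive]
    xy = cells[["x", "y"]].to_numpy()
    radii = cells["radius"].to_numpy()
    if channel == 0:
        amp = np.full(len(cells), phantom.config.nuclear_brightness)
    else:
        m = marker_index(cycle, channel, channels_per_cycle)
        amp = phantom.expression[alive.nonzero()[0], m]
    return _render_points(phantom.canvas_shape, xy, radii, amp)


def render_cycles(
    phantom: TissuePhantom,
    acq: AcquisitionModel,
    seed: int,
    out_dir: str | Path | None = None,
) -> dict:
    """Render the acquisition: per-cycle drifted, shaded, noisy tiles plus truth.

    Returns a dict with ``tiles`` mapping (cycle, channel, row, col) -> uint16
    array, ``offsets`` the applied per-cycle rigid transforms (dx, dy, theta),
    ``autofluorescence`` the background schedule, ``shading`` the per-channel
    multiplicative fields on the mosaic canvas, and ``ideal_mosaics`` the
    noiseless unshifted canvases. If ``out_dir`` is given, tiles are written as
    16-bit TIFFs named ``cyc{c:02d}_ch{k}_r{row}_c{col}.tif`` together with a
    JSON truth manifest and a ground-truth cell CSV.
    """
    rng = np.random.default_rng(seed)
    mosaic_shape = acq.mosaic_shape()
    ph, pw = phantom.canvas_shape
    if ph > mosaic_shape[0] or pw > mosaic_shape[1]:
        raise ValueError(
            f"phantom canvas {phantom.canvas_shape} does not fit the "
            f"stitched mosaic {mosaic_shape} implied by the tile grid"
        )
    if acq.offsets is not None:
        offsets = np.asarray(acq.offsets, float)
    else:
        offsets = np.zeros((acq.n_cycles, 3))
        if acq.n_cycles > 1:
            offsets[1:, 0] = rng.uniform(-acq.max_offset_px, acq.max_offset_px, acq.n_cycles - 1)
            offsets[1:, 1] = rng.uniform(-acq.max_offset_px, acq.max_offset_px, acq.n_cycles - 1)
            offsets[1:, 2] = np.deg2rad(
                rng.uniform(-acq.max_rotation_deg, acq.max_rotation_deg, acq.n_cycles - 1)
            )
    af = acq.autofluorescence_schedule()
    # shading is an optical property of the light path: one field per channel,
    # identical for every tile position
    shading = {
        k: _shading_field(acq.tile_shape, acq.shading_strength, rng)
        for k in range(acq.channels_per_cycle)
    }
    sy, sx = acq.stride
    th, tw = acq.tile_shape
    tiles: dict[tuple[int, int, int, int], np.ndarray] = {}
    ideal: dict[tuple[int, int], np.ndarray] = {}

    from scipy import ndimage

    for c in range(1, acq.n_cycles + 1):
        dx, dy, theta = offsets[c - 1]
        for k in range(acq.channels_per_cycle):
            canvas = np.zeros(mosaic_shape)
            canvas[:ph, :pw] = render_ideal_canvas(phantom, c, k, acq.channels_per_cycle)
            ideal[(c, k)] = canvas
            moved = canvas
            if abs(theta) > 1e-12:
                moved = ndimage.rotate(moved, np.rad2deg(theta), reshape=False, order=1)
            if abs(dx) > 1e-12 or abs(dy) > 1e-12:
                moved = ndimage.shift(moved, (dy, dx), order=1)
            img = moved + af[c - 1]
            for r in range(acq.grid_shape[0]):
                for col in range(acq.grid_shape[1]):
                    y0, x0 = r * sy, col * sx
                    tile = img[y0 : y0 + th, x0 : x0 + tw] * shading[k]
                    if acq.photon_scale > 0:
                        tile = (
                            rng.poisson(np.clip(tile, 0, None) * acq.photon_scale)
                            / acq.photon_scale
                        )
                    if acq.read_noise_sigma > 0:
                        tile = tile + rng.normal(0, acq.read_noise_sigma, tile.shape)
                    tiles[(c, k, r, col)] = np.clip(tile, 0, 65535).astype(np.uint16)

    result = {
        "tiles": tiles,
        "offsets": offsets,
        "autofluorescence": af,
        "shading": shading,
        "ideal_mosaics": ideal,
        "grid_shape": acq.grid_shape,
        "tile_shape": acq.tile_shape,
        "overlap": acq.overlap,
        "mosaic_shape": mosaic_shape,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (c, k, r, col), tile in tiles.items():
            tifffile.imwrite(out / f"cyc{c:02d}_ch{k}_r{r}_c{col}.tif", tile)
        manifest = {
            "offsets": offsets.tolist(),
            "autofluorescence": af.tolist(),
            "grid_shape": list(acq.grid_shape),
            "tile_shape": list(acq.tile_shape),
            "overlap": acq.overlap,
            "mosaic_shape": list(mosaic_shape),
            "channels_per_cycle": acq.channels_per_cycle,
            "n_cycles": acq.n_cycles,
            "pixel_size_um": phantom.pixel_size_um,
        }
        (out / "truth_manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        truth = phantom.cells.copy()
        for m in range(phantom.expression.shape[1]):
            truth[f"expr_m{m}"] = phantom.expression[:, m]
        truth.to_csv(out / "truth_cells.csv", index=False)
    return result


def simulate_bleach_pair(
    n_cells: int,
    fold: float,
    seed: int,
    background: float = 50.0,
    median: float = 2000.0,
    sigma: float = 0.4,
    noise: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell mean intensities before and after fluorophore inactivation.

    Pre-bleach means are lognormal over a constant background; post-bleach
    signal is attenuated by ``fold`` with the background retained. Returns
    (pre, post, background).
    """
    rng = np.random.default_rng(seed)
    signal = np.exp(rng.normal(np.log(median), sigma, n_cells))
    pre = background + signal + rng.normal(0, noise, n_cells)
    post = background + signal / fold + rng.normal(0, noise, n_cells)
    return np.clip(pre, 0, None), np.clip(post, 0, None), background
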