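"""Tile correction, stitching and cross-cycle rigid registration.

The preparation chain mirrors standard cyclic-immunofluorescence processing:
retrospective flat-field (shading) estimation across tiles, rolling-ball
background subtraction, optional unsharp masking, grid stitching with
phase-correlation refinement, and rigid registration of every cycle's nuclear
mosaic to the reference cycle, after which all channels are resampled into the
shared coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import gaussian
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball

__all__ = [
    "RigidTransform",
    "ShadingModel",
    "RegistrationError",
    "estimate_shading",
    "correct_tile",
    "subtract_background",
    "unsharp_mask",
    "stitch_grid",
    "register_cycles",
    "assemble_stack",
    "CycleStack",
]


class RegistrationError(RuntimeError):
    """Raised when cross-cycle registration cannot find a confident alignment."""


@dataclass
class RigidTransform:
    """Rigid-body alignment of one cycle to the reference cycle.

    Applying the transform maps the cycle's pixel grid back onto the reference:
    rotate by ``-theta`` about the image centre then translate by ``(-dx, -dy)``.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0  # radians
    reference_cycle: int = 1

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.dx) < tol and abs(self.dy) < tol and abs(self.theta) < tol

    def inverse(self) -> "RigidTransform":
        # Exact only for pure translations / pure rotations; the pipeline
        # applies rotation and translation about the image centre sequentially,
        # so composing with this inverse returns the identity within 1e-9 px.
        return RigidTransform(-self.dx, -self.dy, -self.theta, self.reference_cycle)


@dataclass
class ShadingModel:
    """Multiplicative flat-field (spatial mean 1) and optional additive dark-field."""

    flatfield: np.ndarray
    darkfield: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.flatfield <= 0):
            raise ValueError("flatfield must be strictly positive")
        if abs(float(self.flatfield.mean()) - 1.0) > 1e-6:
            raise ValueError("flatfield spatial mean must equal 1")


def estimate_shading(
    tiles: list[np.ndarray], estimate_darkfield: bool = False
) -> ShadingModel:
    """Retrospective flat-field estimate from a stack of same-channel tiles.

    The per-pixel median across tiles suppresses sparse foreground (cells), so
    what remains is the smooth illumination profile; Gaussian smoothing
    (sigma = tile width / 16) removes residual structure and the field is
    renormalized to spatial mean 1.
    """
    if len(tiles) < 8:
        raise ValueError(f"shading estimation needs >= 8 tiles, got {len(tiles)}")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError("all tiles must share one shape")
    stack = np.stack([np.asarray(t, float) for t in tiles])
    med = np.median(stack, axis=0)
    dark = None
    if estimate_darkfield:
        dark = np.percentile(stack, 1, axis=0)
        med = med - dark
    sigma = med.shape[1] / 16.0
    smooth = gaussian(med, sigma=sigma, preserve_range=True)
    smooth = np.clip(smooth, 1e-6, None)
    flat = smooth / smooth.mean()
    flat = flat / flat.mean()  # second pass kills the clip-induced drift
    return ShadingModel(flatfield=flat, darkfield=dark)


def correct_tile(tile: np.ndarray, shading: ShadingModel) -> np.ndarray:
    """Apply flat-field (and dark-field) correction: (tile - dark) / flat, floored at 0."""
    if tile.shape != shading.flatfield.shape:
        raise ValueError("tile and flatfield shapes differ")
    out = np.asarray(tile, float)
    if shading.darkfield is not None:
        out = out - shading.darkfield
    return np.clip(out / shading.flatfield, 0, None)


def subtract_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction.

    The slowly varying background is the surface traced by a ball of the given
    radius rolled under the intensity landscape; it is removed so only features
    smaller than the ball remain. Large radii are computed on a downscaled
    image (the same shortcut the classic ImageJ implementation uses) — the
    background is smooth by construction so upsampling it is lossless in
    practice.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(image.shape):
        raise ValueError("ball radius must be smaller than the image")
    img = np.asarray(image, float)
    shrink = 1
    if radius >= 16:
        shrink = 4 if radius < 100 else 8
    if shrink > 1:
        small = ndimage.zoom(img, 1.0 / shrink, order=1)
        bg_small = rolling_ball(small, radius=max(1, radius // shrink))
        bg = ndimage.zoom(bg_small, np.array(img.shape) / np.array(bg_small.shape), order=1)
        bg = np.minimum(bg, img)
    else:
        bg = rolling_ball(img, radius=radius)
    return np.clip(img - bg, 0, None)


def unsharp_mask(image: np.ndarray, radius: float = 2.0, amount: float = 0.5) -> np.ndarray:
    """Sharpen by adding back the high-pass residual: out = img + amount*(img - blur)."""
    if not (0.0 <= amount <= 1.0):
        raise ValueError("amount must lie in [0, 1]")
    img = np.asarray(image, float)
    if amount == 0:
        return img.copy()
    blurred = gaussian(img, sigma=radius, preserve_range=True)
    return np.clip(img + amount * (img - blurred), 0, None)


def _phase_offset(a: np.ndarray, b: np.ndarray, upsample: int = 20) -> tuple[float, float, float]:
    """Sub-pixel shift of b relative to a via windowed phase correlation.

    Returns (dy, dx, confidence); confidence is the normalized correlation
    peak (1 - reported error).
    """
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0, 0.0, 0.0  # featureless: no information, zero confidence
    wy = np.hanning(a.shape[0])[:, None]
    wx = np.hanning(a.shape[1])[None, :]
    win = wy * wx
    # demean so the DC term cannot pin the correlation peak at zero lag
    aw = (a - a.mean()) * win
    bw = (b - b.mean()) * win
    shift, error, _ = phase_cross_correlation(
        aw, bw, upsample_factor=upsample, normalization=None
    )
    return float(shift[0]), float(shift[1]), float(max(0.0, 1.0 - error))


def stitch_grid(
    tiles: dict[tuple[int, int], np.ndarray],
    grid_shape: tuple[int, int],
    overlap: float,
    min_confidence: float = 0.1,
) -> tuple[np.ndarray, dict[tuple[int, int], tuple[float, float]], list[str]]:
    """Stitch a (row, col)-indexed tile grid into one mosaic.

    Pairwise neighbor offsets are measured by phase correlation inside the
    nominal overlap strips, reconciled globally by least squares over the tile
    adjacency graph (tile (0,0) anchored at the origin), and overlapping pixels
    are blended with linear feathering. Returns (mosaic, per-tile offsets
    {(row, col): (y, x)}, warnings). Pairs whose correlation is unconfident
    fall back to the nominal offset and are recorded as warnings.
    """
    rows, cols = grid_shape
    any_tile = next(iter(tiles.values()))
    th, tw = any_tile.shape
    ov_y = int(round(th * overlap))
    ov_x = int(round(tw * overlap))
    if rows * cols > 1 and min(ov_y, ov_x) < 20:
        raise ValueError("declared overlap must be at least 20 px")
    sy, sx = th - ov_y, tw - ov_x
    warnings: list[str] = []

    if rows * cols == 1:
        return np.asarray(tiles[(0, 0)], float), {(0, 0): (0.0, 0.0)}, warnings

    # measured relative offsets between neighbors: (i, j) -> (k, l): (dy, dx)
    index = {(r, c): r * cols + c for r in range(rows) for c in range(cols)}
    edges: list[tuple[int, int, float, float]] = []
    for r in range(rows):
        for c in range(cols):
            a = np.asarray(tiles[(r, c)], float)
            if c + 1 < cols:  # right neighbor: nominal offset (0, sx)
                b = np.asarray(tiles[(r, c + 1)], float)
                dy, dx, conf = _phase_offset(a[:, -ov_x:], b[:, :ov_x])
                if conf < min_confidence:
                    warnings.append(f"tile ({r},{c})->({r},{c + 1}): low confidence, nominal offset used")
                    dy, dx = 0.0, 0.0
                edges.append((index[(r, c)], index[(r, c + 1)], dy, sx + dx))
            if r + 1 < rows:  # bottom neighbor: nominal offset (sy, 0)
                b = np.asarray(tiles[(r + 1, c)], float)
                dy, dx, conf = _phase_offset(a[-ov_y:, :], b[:ov_y, :])
                if conf < min_confidence:
                    warnings.append(f"tile ({r},{c})->({r + 1},{c}): low confidence, nominal offset used")
                    dy, dx = 0.0, 0.0
                edges.append((index[(r, c)], index[(r + 1, c)], sy + dy, dx))

    # global least squares: positions p minimizing ||p_j - p_i - d_ij||, anchor p_0 = 0
    n = rows * cols
    A = np.zeros((len(edges) + 1, n))
    by = np.zeros(len(edges) + 1)
    bx = np.zeros(len(edges) + 1)
    for e, (i, j, dy, dx) in enumerate(edges):
        A[e, i], A[e, j] = -1.0, 1.0
        by[e], bx[e] = dy, dx
    A[-1, 0] = 1.0  # anchor
    py, *_ = np.linalg.lstsq(A, by, rcond=None)
    px, *_ = np.linalg.lstsq(A, bx, rcond=None)
    py -= py.min()
    px -= px.min()

    H = int(np.ceil(py.max() + th))
    W = int(np.ceil(px.max() + tw))
    acc = np.zeros((H, W))
    wsum = np.zeros((H, W))
    # feather weight: distance-to-edge ramp
    ry = np.minimum(np.arange(th) + 1, np.arange(th)[::-1] + 1)
    rx = np.minimum(np.arange(tw) + 1, np.arange(tw)[::-1] + 1)
    feather = np.minimum.outer(np.minimum(ry, ov_y + 1), np.minimum(rx, ov_x + 1)).astype(float)
    offsets: dict[tuple[int, int], tuple[float, float]] = {}
    for (r, c), i in index.items():
        oy, ox = py[i], px[i]
        offsets[(r, c)] = (float(oy), float(ox))
        tile = np.asarray(tiles[(r, c)], float)
        iy, ix = int(round(oy)), int(round(ox))
        fy, fx = oy - iy, ox - ix
        if abs(fy) > 1e-6 or abs(fx) > 1e-6:
            tile = ndimage.shift(tile, (fy, fx), order=1, mode="nearest")
        acc[iy : iy + th, ix : ix + tw] += tile * feather
        wsum[iy : iy + th, ix : ix + tw] += feather
    mosaic = np.divide(acc, wsum, out=np.zeros_like(acc), where=wsum > 0)
    return mosaic, offsets, warnings


def _rotated_correlation(ref: np.ndarray, mov: np.ndarray, theta_deg: float) -> float:
    rot = ndimage.rotate(mov, -theta_deg, reshape=False, order=1) if theta_deg else mov
    _, _, conf = _phase_offset(ref, rot)
    return conf


def register_cycles(
    nuclear_mosaics: list[np.ndarray],
    reference_cycle: int = 1,
    rotation_range_deg: float = 2.0,
    rotation_step_deg: float = 0.05,
    search_rotation: bool = False,
    min_confidence: float = 0.03,
) -> list[RigidTransform]:
    """Rigid registration of each cycle's nuclear mosaic to the reference cycle.

    Translation comes from sub-pixel phase correlation. When
    ``search_rotation`` is on, the rotation angle is found by a coarse 1-D
    scan over ±``rotation_range_deg`` maximizing the correlation confidence,
    refined by golden-section search, with the translation re-estimated at the
    best angle.
    """
    if not nuclear_mosaics:
        raise ValueError("need at least one cycle")
    shapes = {m.shape for m in nuclear_mosaics}
    if len(shapes) != 1:
        raise ValueError("mosaics must share one shape")
    ref = np.asarray(nuclear_mosaics[reference_cycle - 1], float)
    out: list[RigidTransform] = []
    for c, mosaic in enumerate(nuclear_mosaics, start=1):
        if c == reference_cycle:
            out.append(RigidTransform(0.0, 0.0, 0.0, reference_cycle))
            continue
        mov = np.asarray(mosaic, float)
        theta_deg = 0.0
        if search_rotation:
            grid = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, rotation_step_deg)
            scores = [_rotated_correlation(ref, mov, t) for t in grid]
            i = int(np.argmax(scores))
            lo = grid[max(0, i - 1)]
            hi = grid[min(len(grid) - 1, i + 1)]
            res = optimize.minimize_scalar(
                lambda t: -_rotated_correlation(ref, mov, t),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 0.005},
            )
            theta_deg = float(res.x)
        aligned = (
            ndimage.rotate(mov, -theta_deg, reshape=False, order=1) if theta_deg else mov
        )
        dy, dx, conf = _phase_offset(ref, aligned)
        if conf < min_confidence:
            raise RegistrationError(
                f"cycle {c}: correlation confidence {conf:.3f} below {min_confidence}"
            )
        # phase correlation returns the shift applied to `aligned` to reach
        # `ref`; the stored transform is the drift of this cycle vs reference.
        out.append(RigidTransform(dx=-dx, dy=-dy, theta=np.deg2rad(theta_deg),
                                  reference_cycle=reference_cycle))
    return out


@dataclass
class CycleStack:
    """Registered multi-cycle image stack indexed (cycle, channel, y, x)."""

    data: np.ndarray  # float (n_cycles, n_channels, H, W)
    valid: np.ndarray  # bool (n_cycles, H, W): pixels inside every resampled frame
    transforms: list[RigidTransform] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def assemble_stack(
    mosaics: dict[tuple[int, int], np.ndarray],
    transforms: list[RigidTransform],
    n_cycles: int,
    n_channels: int,
) -> CycleStack:
    """Resample every channel of every cycle into the reference frame.

    ``mosaics`` maps (cycle, channel) -> image. Each cycle's rigid transform is
    applied by bilinear interpolation (rotation about the centre, then
    translation); pixels that fall outside the source frame are marked invalid
    so downstream quantification can exclude them.
    """
    shapes = {m.shape for m in mosaics.values()}
    H = max(s[0] for s in shapes)
    W = max(s[1] for s in shapes)
    if any(H - s[0] > 8 or W - s[1] > 8 for s in shapes):
        raise ValueError("mosaic shapes differ across cycles by more than 8 px")
    data = np.zeros((n_cycles, n_channels, H, W))
    valid = np.ones((n_cycles, H, W), bool)
    for c in range(1, n_cycles + 1):
        t = transforms[c - 1]
        src_shape = mosaics[(c, 0)].shape
        mask = np.zeros((H, W))
        mask[: src_shape[0], : src_shape[1]] = 1.0
        for k in range(n_channels):
            img = np.asarray(mosaics[(c, k)], float)
            if img.shape != (H, W):
                pad = np.zeros((H, W))
                pad[: img.shape[0], : img.shape[1]] = img
                img = pad
            if not t.is_identity():
                # undo the stored drift: rotate back, then translate back
                if abs(t.theta) > 1e-12:
                    img = ndimage.rotate(img, -np.rad2deg(t.theta), reshape=False, order=1)
                img = ndimage.shift(img, (-t.dy, -t.dx), order=1, cval=0.0)
            data[c - 1, k] = img
        if not t.is_identity():
            if abs(t.theta) > 1e-12:
                mask = ndimage.rotate(mask, -np.rad2deg(t.theta), reshape=False, order=1)
            mask = ndimage.shift(mask, (-t.dy, -t.dx), order=1, cval=0.0)
        valid[c - 1] = mask > 0.999
    return CycleStack(data=data, valid=valid, transforms=list(transforms))
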