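"""Standard-format I/O: tile indexing, CSV/JSON/TIFF writers with stable hashing.

All JSON is written with sorted keys and floats at 17 significant digits so a
re-run with identical inputs produces byte-identical artifacts.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TILE_PATTERN",
    "read_tiles",
    "write_celltable",
    "read_celltable",
    "write_json",
    "write_image",
    "write_stack_ome",
]

TILE_PATTERN = re.compile(r"cyc(?P<cycle>\d+)_ch(?P<channel>\d+)_r(?P<row>\d+)_c(?P<col>\d+)\.tif$")


def read_tiles(directory: str | Path, pattern: re.Pattern = TILE_PATTERN) -> tuple[dict, list]:
    """Index tiles by (cycle, channel, row, col); validate shape/dtype uniformity.

    Returns (tiles, gaps) where gaps lists any (cycle, channel, row, col)
    missing from the complete cycle × channel × grid product.
    """
    directory = Path(directory)
    tiles: dict[tuple[int, int, int, int], np.ndarray] = {}
    for f in sorted(directory.glob("*.tif")):
        m = pattern.search(f.name)
        if not m:
            continue
        key = tuple(int(m.group(g)) for g in ("cycle", "channel", "row", "col"))
        tiles[key] = tifffile.imread(f)
    if not tiles:
        raise FileNotFoundError(f"no tiles matching the naming pattern in {directory}")
    shapes = {t.shape for t in tiles.values()}
    dtypes = {t.dtype for t in tiles.values()}
    if len(shapes) > 1 or len(dtypes) > 1:
        raise ValueError(f"tiles are not uniform: shapes={shapes}, dtypes={dtypes}")
    cycles = sorted({k[0] for k in tiles})
    channels = sorted({k[1] for k in tiles})
    rows = sorted({k[2] for k in tiles})
    cols = sorted({k[3] for k in tiles})
    gaps = [
        (c, k, r, col)
        for c in cycles
        for k in channels
        for r in rows
        for col in cols
        if (c, k, r, col) not in tiles
    ]
    return tiles, gaps


def _format_float(x) -> str:
    return repr(float(x)) if isinstance(x, (float, np.floating)) else str(x)


def write_celltable(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with fixed column order and 17-significant-digit floats."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_celltable(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    """UTF-8 JSON with sorted keys (hash-stable across runs)."""
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=1, default=_json_default),
        encoding="utf-8",
    )


def write_image(image: np.ndarray, path: str | Path, dtype=np.float32) -> None:
    """Single-plane grayscale TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype))


def write_stack_ome(stack_data: np.ndarray, path: str | Path, pixel_size_um: float) -> None:
    """OME-TIFF export of the assembled (cycle, channel, y, x) stack."""
    data = np.asarray(stack_data, np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "TCYX",
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeY": pixel_size_um,
        },
    )
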