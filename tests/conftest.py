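"""Shared fixtures: a small phantom, a rendered acquisition and the prepared stack.

Everything is generated in-process from seeds; no fixture files ship with the
package. Session scope keeps the expensive render/prep chain to one execution.
"""

import numpy as np
import pytest

from cycplex import imgprep, segquant, synthgen


@pytest.fixture(scope="session")
def phantom():
    """Default-scale phantom: ~500 cells, 3 cycles, no dropout (segmentation tests)."""
    cfg = synthgen.PhantomConfig(
        n_cells=500, canvas_shape=(480, 480), n_cycles=3, dropout_rate=0.0
    )
    return synthgen.generate_phantom(cfg, seed=11)


@pytest.fixture(scope="session")
def rendered(phantom):
    """Tiled rendering of the default phantom with drift, shading and noise."""
    acq = synthgen.AcquisitionModel(
        grid_shape=(2, 2),
        tile_shape=(256, 256),
        overlap=0.1,
        n_cycles=3,
        max_offset_px=5.0,
        shading_strength=0.25,
    )
    return synthgen.render_cycles(phantom, acq, seed=12), acq


@pytest.fixture(scope="session")
def prepared(rendered):
    """Corrected, stitched, registered stack from the rendered tiles."""
    result, acq = rendered
    tiles = result["tiles"]
    channels = sorted({k[1] for k in tiles})
    cycles = sorted({k[0] for k in tiles})
    shading = {
        k: imgprep.estimate_shading(
            [t for key, t in sorted(tiles.items()) if key[1] == k]
        )
        for k in channels
    }
    mosaics = {}
    for c in cycles:
        for k in channels:
            grid = {
                (r, col): imgprep.correct_tile(np.asarray(t, float), shading[k])
                for (cc, kk, r, col), t in tiles.items()
                if cc == c and kk == k
            }
            mosaic, _, _ = imgprep.stitch_grid(grid, acq.grid_shape, acq.overlap)
            mosaics[(c, k)] = imgprep.subtract_background(mosaic, radius=50)
    transforms = imgprep.register_cycles([mosaics[(c, 0)] for c in cycles])
    stack = imgprep.assemble_stack(mosaics, transforms, len(cycles), len(channels))
    return stack, transforms, result


@pytest.fixture(scope="session")
def segmented(prepared):
    """Label images plus the quantified cell table for the prepared stack."""
    stack, _, _ = prepared
    nuc, cell, cyto = segquant.segment_nuclei(stack.data[0, 0])
    table = segquant.quantify(nuc, cell, cyto, stack)
    return nuc, cell, cyto, table
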