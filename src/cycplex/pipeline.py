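"""End-to-end orchestration: simulate → prep → segment → qc → phenotype → spatial.

Each stage reads and writes only documented plain formats (TIFF, CSV, JSON)
inside the configured output directory, so stages can be re-run independently;
a run manifest records per-artifact SHA-256 hashes, the config hash and
warnings. Deterministic stages reproduce identical hashes on identical inputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cycleqc, imgprep, io, phenotyping, segquant, spatial, synthgen
from .config import RunConfig

__all__ = ["RunManifest", "PipelineError", "MissingInputError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "prep", "segment", "qc", "phenotype", "spatial")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


class MissingInputError(PipelineError):
    def __init__(self, stage: str, missing: str, produced_by: str):
        super().__init__(stage, f"missing input {missing!r}; run the '{produced_by}' stage first")
        self.produced_by = produced_by


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str], t0: float, t1: float) -> None:
        self.stages.append(
            {"stage": stage, "outputs": outputs, "started": t0, "finished": t1}
        )

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_outputs(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in paths}


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise MissingInputError(stage, str(path), produced_by)
    return path


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    phantom_cfg = synthgen.PhantomConfig(
        n_cells=cfg.n_cells,
        canvas_shape=_canvas_shape(cfg),
        n_clusters=cfg.n_clusters,
        n_markers=(cfg.channels_per_cycle - 1) * cfg.n_cycles,
        dropout_rate=cfg.dropout_rate,
        n_cycles=cfg.n_cycles,
        pixel_size_um=cfg.pixel_size_um,
    )
    phantom = synthgen.generate_phantom(phantom_cfg, seed=cfg.seed_simulate)
    acq = synthgen.AcquisitionModel(
        grid_shape=(cfg.grid_rows, cfg.grid_cols),
        tile_shape=(cfg.tile_size, cfg.tile_size),
        overlap=cfg.overlap,
        n_cycles=cfg.n_cycles,
        channels_per_cycle=cfg.channels_per_cycle,
        max_offset_px=cfg.max_offset_px,
        max_rotation_deg=cfg.max_rotation_deg,
        shading_strength=cfg.shading_strength,
    )
    tile_dir = out / "tiles"
    synthgen.render_cycles(phantom, acq, seed=cfg.seed_simulate + 1, out_dir=tile_dir)
    return sorted(tile_dir.glob("*")) + []


def _canvas_shape(cfg: RunConfig) -> tuple[int, int]:
    acq = synthgen.AcquisitionModel(
        grid_shape=(cfg.grid_rows, cfg.grid_cols),
        tile_shape=(cfg.tile_size, cfg.tile_size),
        overlap=cfg.overlap,
    )
    h, w = acq.mosaic_shape()
    return (h, w)


def _stage_prep(cfg: RunConfig, out: Path, manifest: RunManifest) -> list[Path]:
    tile_dir = _require(out / "tiles", "prep", "simulate")
    tiles, gaps = io.read_tiles(tile_dir)
    if gaps:
        manifest.warnings.append(f"prep: missing tiles {gaps}")
    cycles = sorted({k[0] for k in tiles})
    channels = sorted({k[1] for k in tiles})
    written: list[Path] = []

    shading = {}
    if cfg.shading_correction:
        for k in channels:
            same = [t for (c, kk, r, cc), t in sorted(tiles.items()) if kk == k]
            shading[k] = imgprep.estimate_shading(same)
            p = out / f"shading_ch{k}.tif"
            io.write_image(shading[k].flatfield, p)
            written.append(p)

    mosaics: dict[tuple[int, int], np.ndarray] = {}
    for c in cycles:
        for k in channels:
            grid = {}
            for (cc, kk, r, col), t in tiles.items():
                if cc == c and kk == k:
                    img = np.asarray(t, float)
                    if cfg.shading_correction:
                        img = imgprep.correct_tile(img, shading[k])
                    grid[(r, col)] = img
            rows = 1 + max(r for r, _ in grid)
            cols = 1 + max(col for _, col in grid)
            mosaic, _, warns = imgprep.stitch_grid(grid, (rows, cols), cfg.overlap)
            manifest.warnings.extend(f"prep cyc{c} ch{k}: {w}" for w in warns)
            mosaic = imgprep.subtract_background(mosaic, radius=cfg.rolling_ball_radius)
            if cfg.unsharp:
                mosaic = imgprep.unsharp_mask(mosaic, cfg.unsharp_radius, cfg.unsharp_amount)
            mosaics[(c, k)] = mosaic

    transforms = imgprep.register_cycles(
        [mosaics[(c, 0)] for c in cycles], search_rotation=cfg.search_rotation
    )
    stack = imgprep.assemble_stack(mosaics, transforms, len(cycles), len(channels))
    for c in cycles:
        for k in channels:
            p = out / f"reg_cyc{c:02d}_ch{k}.tif"
            io.write_image(stack.data[c - 1, k], p)
            written.append(p)
        p = out / f"valid_cyc{c:02d}.tif"
        io.write_image(stack.valid[c - 1].astype(np.uint8), p, dtype=np.uint8)
        written.append(p)
    p = out / "transforms.json"
    io.write_json(
        {
            "transforms": [
                {"cycle": c, "dx": t.dx, "dy": t.dy, "theta": t.theta}
                for c, t in zip(cycles, transforms)
            ]
        },
        p,
    )
    written.append(p)
    return written


def _load_stack(cfg: RunConfig, out: Path, stage: str) -> imgprep.CycleStack:
    import tifffile

    cycles = range(1, cfg.n_cycles + 1)
    channels = range(cfg.channels_per_cycle)
    data = []
    valid = []
    for c in cycles:
        chans = []
        for k in channels:
            p = _require(out / f"reg_cyc{c:02d}_ch{k}.tif", stage, "prep")
            chans.append(tifffile.imread(p).astype(float))
        data.append(np.stack(chans))
        valid.append(tifffile.imread(out / f"valid_cyc{c:02d}.tif").astype(bool))
    return imgprep.CycleStack(data=np.stack(data), valid=np.stack(valid), transforms=[])


def _stage_segment(cfg: RunConfig, out: Path) -> list[Path]:
    stack = _load_stack(cfg, out, "segment")
    nuc, cell, cyto = segquant.segment_nuclei(
        stack.data[0, 0],
        min_separation=cfg.min_separation,
        min_area=cfg.min_area,
        expansion_px=cfg.expansion_px,
    )
    table = segquant.quantify(nuc, cell, cyto, stack)
    written = []
    for name, lab in (("nucleus", nuc), ("cell", cell), ("cytoplasm", cyto)):
        p = out / f"labels_{name}.tif"
        io.write_image(lab, p, dtype=np.int32)
        written.append(p)
    p = out / "celltable.csv"
    io.write_celltable(table, p)
    written.append(p)
    # per-cycle nuclear segmentation (integrity analysis needs raw counts per cycle)
    for c in range(1, cfg.n_cycles + 1):
        nc = segquant.split_nuclei(
            segquant.binarize_nuclei(stack.data[c - 1, 0], min_area=cfg.min_area),
            min_separation=cfg.min_separation,
        )
        ids = np.unique(nc)
        ids = ids[ids > 0]
        from scipy import ndimage

        if ids.size:
            cy, cx = np.array(
                ndimage.center_of_mass(np.ones_like(nc), nc, ids)
            ).T
        else:
            cy = cx = np.array([])
        df = pd.DataFrame({"cell_id": ids, "centroid_x": cx, "centroid_y": cy})
        p = out / f"nuclei_cyc{c:02d}.csv"
        io.write_celltable(df, p)
        written.append(p)
    return written


def _stage_qc(cfg: RunConfig, out: Path) -> list[Path]:
    _require(out / "celltable.csv", "qc", "segment")
    table = io.read_celltable(out / "celltable.csv")
    per_cycle = [
        io.read_celltable(_require(out / f"nuclei_cyc{c:02d}.csv", "qc", "segment"))
        for c in range(1, cfg.n_cycles + 1)
    ]
    report = cycleqc.QCReport(parameters={"n_bins": cfg.n_bins, "config_hash": cfg.hash()})
    report.integrity = list(cycleqc.integrity_curve(per_cycle))
    valid = table[table["valid"].astype(bool)] if "valid" in table else table
    for c in range(1, cfg.n_cycles + 1):
        for k in range(cfg.channels_per_cycle):
            col = f"cyc{c}_ch{k}_cell_mean"
            if col not in valid.columns:
                continue
            v = valid[col].dropna().to_numpy()
            if len(v) >= 20 and np.percentile(v, 5) > 0:
                report.dynamic_ranges[(c, k)] = cycleqc.dynamic_range(v)
    # cross-cycle concordance of each marker channel's cell-mean distribution
    for k in range(1, cfg.channels_per_cycle):
        for c in range(1, cfg.n_cycles):
            a = valid[f"cyc{c}_ch{k}_cell_mean"].dropna().to_numpy()
            b = valid[f"cyc{c + 1}_ch{k}_cell_mean"].dropna().to_numpy()
            if len(a) and len(b):
                s = cycleqc.overlap_score(a, b, n_bins=cfg.n_bins)
                report.overlaps[(f"cyc{c}_ch{k}", f"cyc{c + 1}_ch{k}")] = (
                    s,
                    cycleqc.classify_concordance(s),
                )
    p_json = out / "qc_report.json"
    p_json.write_text(report.to_json())
    p_csv = out / "integrity.csv"
    pd.DataFrame(
        {"cycle": np.arange(1, cfg.n_cycles + 1), "retained": report.integrity}
    ).to_csv(p_csv, index=False, float_format="%.17g")
    return [p_json, p_csv]


def _stage_phenotype(cfg: RunConfig, out: Path) -> list[Path]:
    table = io.read_celltable(_require(out / "celltable.csv", "phenotype", "segment"))
    fm = phenotyping.transform_intensities(table, method=cfg.transform, cofactor=cfg.cofactor)
    fm = phenotyping.normalize_channels(fm, *cfg.norm_percentiles)
    curve, chosen = phenotyping.select_k(
        fm, list(cfg.k_range), restarts=cfg.restarts, seed=cfg.seed_phenotype
    )
    model = phenotyping.fit_emgm(fm, chosen, restarts=cfg.restarts, seed=cfg.seed_phenotype)
    p_model = out / "phenotype_model.json"
    io.write_json(
        {
            "k": model.k,
            "weights": model.weights,
            "means": model.means,
            "covariances": model.covariances,
            "nll": model.nll,
            "selection_curve": curve.to_dict(orient="list"),
        },
        p_model,
    )
    assigned = table.copy()
    assigned["phenotype"] = -1
    id_to_cluster = dict(zip(fm.cell_ids, model.assignments))
    assigned["phenotype"] = assigned["cell_id"].map(id_to_cluster).fillna(-1).astype(int)
    p_table = out / "celltable_phenotyped.csv"
    io.write_celltable(assigned, p_table)
    written = [p_model, p_table]
    if len(fm.values) >= 3 * cfg.tsne_perplexity:
        emb = phenotyping.embed_tsne(fm, perplexity=cfg.tsne_perplexity, seed=cfg.seed_phenotype)
        p_emb = out / "tsne.csv"
        pd.DataFrame(
            {"cell_id": fm.cell_ids, "tsne1": emb[:, 0], "tsne2": emb[:, 1]}
        ).to_csv(p_emb, index=False, float_format="%.17g")
        written.append(p_emb)
    return written


def _stage_spatial(cfg: RunConfig, out: Path, manifest: RunManifest) -> list[Path]:
    table = io.read_celltable(
        _require(out / "celltable_phenotyped.csv", "spatial", "phenotype")
    )
    table = table[table["valid"].astype(bool)].reset_index(drop=True)
    canvas = _canvas_shape(cfg)
    written = []

    # field-wise entropy per marker channel (fields need > n_sample cells)
    grid = spatial.grid_fields(table, cfg.field_size, cfg.field_size)
    marker_cols = [
        c for c in table.columns if c.endswith("_cell_mean") and "_ch0_" not in c
    ]
    rows = []
    rng_seed = cfg.seed_spatial
    for col in marker_cols:
        all_v = table[col].dropna().to_numpy()
        if len(all_v) <= cfg.entropy_n_sample:
            continue
        e_sample = spatial.field_entropy(all_v, cfg.entropy_n_sample, seed=rng_seed)
        for fid, n in grid.counts.items():
            if n <= cfg.entropy_n_sample:
                continue
            sel = grid.field_ids[grid.field_ids == fid].index
            v = table.set_index("cell_id").loc[sel, col].dropna().to_numpy()
            if len(v) <= cfg.entropy_n_sample:
                continue
            e = spatial.field_entropy(v, cfg.entropy_n_sample, seed=rng_seed)
            rows.append(
                {
                    "field_row": fid[0], "field_col": fid[1], "channel": col,
                    "entropy": e,
                    "entropy_normalized": float(spatial.normalize_entropy(np.array([e]), e_sample)[0]),
                }
            )
    p_ent = out / "entropy_map.csv"
    pd.DataFrame(rows, columns=["field_row", "field_col", "channel", "entropy",
                                "entropy_normalized"]).to_csv(
        p_ent, index=False, float_format="%.17g"
    )
    written.append(p_ent)
    if not rows:
        manifest.warnings.append(
            "spatial: no field exceeded the entropy sample size; entropy map is empty"
        )

    # region assignment from the first marker channel as the stromal proxy
    stromal = marker_cols[0]
    regions, stroma_mask = spatial.assign_regions(table, stromal, canvas)
    # gates on the two brightest marker channels
    gate_cols = marker_cols[1:3] if len(marker_cols) >= 3 else marker_cols
    gates = {c: spatial.gate_positive(table, c) for c in gate_cols}
    counts = spatial.bootstrap_counts(table, gates, regions, cfg.n_boot, seed=cfg.seed_spatial)
    p_counts = out / "bootstrap_counts.csv"
    counts.to_csv(p_counts, index=False, float_format="%.17g")
    written.append(p_counts)

    # kNN densities and co-occurrence of the two gated populations
    step = 8.0
    gy = np.arange(0, canvas[0], step)
    gx = np.arange(0, canvas[1], step)
    names = list(gates)
    if len(names) >= 2:
        pts = {
            n: table.loc[gates[n], ["centroid_x", "centroid_y"]].to_numpy() for n in names[:2]
        }
        if all(len(p) >= cfg.knn_k for p in pts.values()):
            da = spatial.knn_density(pts[names[0]], gy, gx, k=cfg.knn_k)
            db = spatial.knn_density(pts[names[1]], gy, gx, k=cfg.knn_k)
            # cell-derived stroma mask lives on its own grid; resample to ours
            from scipy import ndimage

            zoom = (len(gy) / stroma_mask.shape[0], len(gx) / stroma_mask.shape[1])
            mask = ndimage.zoom(stroma_mask.astype(float), zoom, order=0) > 0.5
            cooc, means, hot = spatial.cooccurrence_map(
                da, db, {"stroma": mask, "tumor": ~mask}
            )
            p_cooc = out / "cooccurrence.tif"
            io.write_image(cooc, p_cooc)
            written.append(p_cooc)
            p_means = out / "cooccurrence_regions.json"
            io.write_json({"region_means": means}, p_means)
            written.append(p_means)
    return written


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> RunManifest:
    """Execute the requested stages in dependency order; returns the run manifest.

    The manifest (stage list, output hashes, config hash, warnings) is written
    to ``<output_dir>/manifest.json`` even when a stage fails.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = RunManifest(config_hash=cfg.hash(), version=__version__)
    ordered = [s for s in STAGES if s in stages]
    try:
        for stage in ordered:
            t0 = time.time()
            if stage == "simulate":
                outputs = _stage_simulate(cfg, out)
            elif stage == "prep":
                outputs = _stage_prep(cfg, out, manifest)
            elif stage == "segment":
                outputs = _stage_segment(cfg, out)
            elif stage == "qc":
                outputs = _stage_qc(cfg, out)
            elif stage == "phenotype":
                outputs = _stage_phenotype(cfg, out)
            else:
                outputs = _stage_spatial(cfg, out, manifest)
            manifest.record(stage, _hash_outputs(outputs), t0, time.time())
    except PipelineError:
        io.write_json(manifest.to_dict(), out / "manifest.json")
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        io.write_json(manifest.to_dict(), out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc
    io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
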