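"""Run configuration: one YAML document driving the full pipeline.

Defaults follow the published processing parameters: rolling-ball radius 50 px,
cytoplasm expansion 3 px (10X objective) or 6 px (40X), kNN k = 4, entropy
sample size 1000 cells, 100 bootstrap rounds, 30 EM restarts, t-SNE perplexity
30, 1st/99th normalization percentiles and 5th/95th dynamic-range percentiles.
Unknown keys are rejected so typos fail loudly, and the config hash is recorded
in every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    # paths
    input_dir: str = "tiles"
    output_dir: str = "out"
    # acquisition / synthesis
    grid_rows: int = 2
    grid_cols: int = 2
    tile_size: int = 256
    overlap: float = 0.1
    n_cycles: int = 3
    channels_per_cycle: int = 4
    pixel_size_um: float = 0.65
    n_cells: int = 500
    n_clusters: int = 3
    dropout_rate: float = 0.25
    max_offset_px: float = 5.0
    max_rotation_deg: float = 0.0
    shading_strength: float = 0.25
    # prep
    rolling_ball_radius: int = 50
    unsharp: bool = False
    unsharp_radius: float = 2.0
    unsharp_amount: float = 0.5
    shading_correction: bool = True
    search_rotation: bool = False
    # segmentation
    objective: str = "10X"  # 3 px expansion; '40X' -> 6 px
    min_separation: int = 5
    min_area: int = 20
    # qc
    n_bins: int = 100
    dr_percentiles: tuple[float, float] = (5.0, 95.0)
    # phenotyping
    transform: str = "asinh"
    cofactor: float = 5.0
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    restarts: int = 30
    tsne_perplexity: float = 30.0
    # spatial
    knn_k: int = 4
    field_size: float = 240.0
    entropy_n_sample: int = 1000
    n_boot: int = 100
    # seeds, one per stochastic stage
    seed_simulate: int = 0
    seed_phenotype: int = 0
    seed_spatial: int = 0

    def hash(self) -> str:
        """Hash of the scientific configuration; file locations excluded."""
        d = asdict(self)
        d.pop("input_dir", None)
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def expansion_px(self) -> int:
        from .segquant import expansion_px_for_objective

        return expansion_px_for_objective(self.objective)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unknown keys raise ConfigError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("dr_percentiles", "norm_percentiles", "k_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
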