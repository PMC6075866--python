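# cycplex

Analysis pipeline for **cyclic immunofluorescence (CyCIF)** — the tissue-imaging
protocol that builds highly multiplexed images by repeating rounds of
four-channel staining (one DNA stain + three antibody markers), imaging, and
chemical fluorophore inactivation on the same FFPE section. The raw product of
such an experiment is a pile of 16-bit grayscale tiles organized by
cycle × channel × grid position; the scientific product is a single-cell table
of marker intensities with spatial coordinates, and the statistics derived from
it.

`cycplex` implements the full computational path between the two, plus a
synthetic multiplexed-tissue generator with known ground truth so that every
stage is testable without any slide scans:

| module        | what it does |
|---------------|--------------|
| `synthgen`    | ground-truth phantoms: hard-core cell placement, per-cluster lognormal marker expression, tumor/stroma regions, per-cycle stage drift, per-tile illumination shading, cycle-decaying autofluorescence, Poisson + read noise, spatially biased cell dropout |
| `imgprep`     | retrospective flat-field estimation, rolling-ball background subtraction (50 px), optional unsharp masking, phase-correlation grid stitching with global least-squares reconciliation, rigid cross-cycle registration on the nuclear channel |
| `segquant`    | Otsu binarization, watershed splitting seeded from distance-transform maxima, centripetal cytoplasm expansion (3 px at 10X / 6 px at 40X), per-cell mean and integrated intensities for nucleus / cytoplasm / whole cell across all cycles and channels |
| `cycleqc`     | fluorophore-inactivation folds, tissue-integrity curves (nucleus counts normalized to cycle 1), dynamic range DR = log10(P95/P5), distribution overlap scores with high/moderate/low concordance bands, nominal resolution r = 0.61λ/NA (widefield) or 0.4λ/NA (confocal) |
| `phenotyping` | log / asinh transforms, 1st–99th percentile channel normalization, t-SNE embedding (perplexity 30), EM Gaussian-mixture clustering with 30 k-means++ restarts and knee-based model selection |
| `spatial`     | field-wise Shannon entropy E = −Σ s_i² ln s_i² on 1000 sampled cells, marker gating, smoothed-marker tumor/stroma region assignment, kNN (k = 4) density estimation, region-normalized co-occurrence maps and fold enrichment, bootstrap count uncertainties (100 rounds) |
| `pipeline`/`cli` | stage orchestration with a hashed provenance manifest; `cycplex` command-line entry point |

## Worked example

`examples/` holds one short script per capability. The end-to-end run:

```bash
python examples/00_full_pipeline.py
```

```
stages completed: ['simulate', 'prep', 'segment', 'qc', 'phenotype', 'spatial']
config hash: 5111eb0c0ee1760e
tissue integrity per cycle (normalized nucleus counts): [1.0, 0.877, 0.775]
phenotype clusters: k = 3, weights = [0.265, 0.431, 0.304]
```

The integrity vector is the fraction of cycle-1 nuclei still detected at each
cycle: the simulated tissue was configured to lose 25% of its cells by the last
cycle, and the segmentation-based curve tracks that loss (endpoint 0.775). The
mixture model selects k = 3 — the number of simulated phenotype clusters — from
the quantified marker intensities. Featureless overlap strips fall back to
nominal stitching offsets and are recorded as warnings in the run manifest.

Parameter recovery of the clustering itself (`examples/05_phenotype_clusters.py`):

```
chosen k = 3 (knee of the NLL curve)
true weights:      [0.5 0.3 0.2]
recovered weights: [0.509 0.287 0.204]
```

The same pattern holds across the package: every quantity the pipeline reports
is validated against the generator's truth manifest (registration against
applied drift, segmentation against true cell centers, integrity against the
configured dropout schedule, co-occurrence against co-placed point patterns).

Run from the shell instead:

```bash
cycplex all --config run.yaml      # or: cycplex simulate prep segment ...
```

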