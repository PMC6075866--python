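# Methods

`cycplex` turns raw cyclic-immunofluorescence tile sets into registered image
stacks, single-cell intensity tables, per-cycle quality metrics, phenotype
clusters and spatial statistics. This note records the models the package
implements, the parameters that matter, the numerical choices made where the
design was open, and what the synthetic-data tests do and do not demonstrate.

## The imaging model

A CyCIF experiment acquires `n_cycles` rounds of four-channel images on the
same section: channel 0 is a DNA stain repeated every cycle (the registration
and segmentation anchor), channels 1–3 carry antibody markers that change each
cycle, so a `c`-cycle run measures `3c` markers. Tiles overlap by a configured
fraction on a rectangular grid; the stage re-mounts between cycles, adding a
small rigid drift (translation plus a sub-degree rotation) per cycle.

The forward model used by the synthetic generator — and implicitly inverted by
the preparation chain — is

```
tile = Poisson{ [ (signal ∘ rigid_drift) + autofluorescence(cycle) ] × flatfield } + read noise
```

with one multiplicative flat-field per channel (an optical property of the
light path, identical across tile positions), an additive autofluorescence
amplitude that is non-increasing in cycle number (repeated bleaching destroys
endogenous fluorophores along with the dyes), Poisson photon statistics and
Gaussian read noise.

## Synthetic tissue generator (`synthgen`)

Cells are placed by dart throwing with hard-core rejection (centers at least
1.5 nuclear radii apart) — touching-but-distinct nuclei, the regime watershed
segmentation assumes. Each cell gets a cluster label from configurable mixture
weights and lognormal marker expression with per-cluster medians; the default
medians are e⁷ (≈1100) in each cluster's own marker block and e⁵ (≈150)
elsewhere with log-sd 0.35, giving ~1 log₁₀ of marker dynamic range, comparable
to the nuclear stain (peak 3000) — a realistic regime where markers are well
above the default autofluorescence (200 at cycle 1, halving each cycle) but not
noise-free. Nuclei render as isotropic Gaussians truncated at 3σ with
σ = radius/2 (smooth and analytically integrable: the truncated-disk integral
2πσ²A(1−e^{-9/2}) is tested against the rendered sum). Default nuclear radius
is 6 px with 0.5 px jitter — a ~8 µm nucleus at the default 0.65 µm/px.

A configured fraction of cells (default 25%) detaches by the final cycle, at a
uniformly drawn cycle ≥ 2, with selection probability biased toward locally
sparse cells (weight `exp(bias·(d₅/mean(d₅) − 1))`, default bias 0.5) —
mimicking the observation that tissue loss concentrates in low-cellularity
regions. The marginal loss rate stays binomial at the configured value.

Coordinates are 0-based pixel indices, `(row, col) = (y, x)`, origin top-left,
shared by every module. Tiles are written as 16-bit TIFFs named
`cyc{c:02d}_ch{k}_r{row}_c{col}.tif` with a JSON truth manifest (applied
transforms, autofluorescence schedule) and a ground-truth cell CSV.

What the generator does **not** emulate: real chromatin texture (nuclei are
smooth blobs), spectral bleed-through, 3-D structure, cell-shape irregularity,
or spatially varying antigenicity. Tests passing on this generator demonstrate
that the algorithms invert the stated forward model; they do not certify
performance on real tissue, where segmentation error is dominated by shape
irregularity the phantom lacks.

## Image preparation (`imgprep`)

**Flat-field estimation** is retrospective: the per-pixel median across ≥ 8
same-channel tiles suppresses sparse foreground, Gaussian smoothing
(σ = tile width/16) removes residual texture, and the field is renormalized to
spatial mean 1. An optional dark-field (per-pixel 1st percentile) is available.
This is a deliberately minimal stand-in for full retrospective estimators; on
the generator's smooth fields it recovers the truth at Pearson r > 0.99.

**Background subtraction** is the rolling-ball algorithm (default radius
50 px) via `skimage.restoration.rolling_ball`; for radii ≥ 16 the background is
computed on a 4× (8× above radius 100) downscaled image and upsampled — the
same shortcut the classic ImageJ implementation uses; the background is smooth
by construction so the approximation is far below feature scale. Features
smaller than the ball keep their height within 5%.

**Unsharp masking** (`out = img + amount·(img − blur)`) is optional, applied
after background subtraction to all channels when enabled. The processing
order relative to background subtraction is not externally constrained; this
package fixes it as: shading correction → stitching → rolling ball → optional
unsharp.

**Stitching** measures pairwise neighbor offsets by Hann-windowed phase
correlation inside the nominal overlap strips, reconciles them globally by
least squares over the tile graph (tile (0,0) anchored), and blends overlaps
with linear feathering. Low-confidence pairs (featureless overlap) fall back to
nominal offsets and are recorded as provenance warnings.

**Registration** aligns each cycle's nuclear mosaic to cycle 1: sub-pixel
translation by phase correlation (upsampled cross-correlation), and — when
enabled — rotation by a coarse 0.05° scan over ±2° maximizing correlation
confidence, refined by bounded scalar minimization. The stored transform is
the cycle's drift; assembly applies its inverse with bilinear interpolation and
marks out-of-frame pixels invalid. Because rotation is undone before the
translation is measured, the stored translation lives in the rotated frame;
for the ±1° drifts considered the difference from the applied vector is ≤ 0.2%
of its magnitude. Bilinear resampling biases integrated intensities by < 2%;
mean intensities are unaffected to first order.

## Segmentation and quantification (`segquant`)

The nuclear channel of the reference cycle is denoised (Gaussian σ = 1),
thresholded with Otsu, holes < 10 px filled, objects ≤ 20 px removed. Touching
nuclei are split by watershed on the negative Euclidean distance transform,
seeded at distance maxima with a minimum separation (default 5 px ≈ expected
radius); every connected component is guaranteed at least one seed so small
nuclei are never dropped. Cells are formed by simultaneous outward expansion
of all nuclei by 3 px (10X objective) or 6 px (40X); contested pixels go to the
nearest nucleus by Euclidean distance (the distance-transform index convention
breaks exact ties deterministically), so neighboring cells never overlap and
expansion halts at the equidistance boundary. The cytoplasm is the cell minus
its nucleus. How far a real cell extends past its nucleus is unknowable from a
DNA stain alone; the fixed-ring expansion is a proxy, not a membrane detector.

Quantification computes, per cell and per (cycle, channel, compartment), the
mean over valid pixels and the integrated intensity (plain sum), so
`integrated = mean × valid-pixel count` holds exactly — on the reference cycle
every pixel is valid and this equals `mean × compartment area`; on drifted
cycles edge cells with partially invalid pixels average over fewer pixels. Cells touching the border or
with > 50% invalid pixels in any cycle are flagged `valid=False` but kept —
integrity analysis needs raw counts. Segmentation is performed once on the
registered cycle-1 mosaic and applied to all cycles.

## Cycle QC (`cycleqc`)

* **Inactivation fold** = (median(pre) − background) / max(median(post) −
  background, ε). Medians resist segmentation outliers. Complete bleaching is
  typically 10²–10³-fold.
* **Integrity** = per-cycle nucleus counts normalized to cycle 1; values
  slightly above 1 are expected segmentation fluctuation. Cross-cycle cell
  matching uses greedy mutual-nearest-neighbor pairing within a distance
  budget (default: median nuclear radius).
* **Dynamic range** = log₁₀(P95/P5) of per-pixel or per-cell intensities
  (linear-interpolation percentiles; P5 is treated as background). Log base 10
  is this package's choice. Scale-invariant by construction; DR rises when
  background falls at fixed signal — the mechanism behind improving
  signal-to-noise in later cycles.
* **Overlap score** = ∫min(f̂_a, f̂_b) / ∫max(f̂_a, f̂_b) by trapezoidal
  integration of unit-area histograms (default 100 bins) on a shared support
  spanning the union of the 0.1–99.9 percentile ranges. The min/max (Jaccard)
  envelope is chosen because it yields the documented [0, 1] range with 1 ⇔
  identical histograms. Bands: > 0.8 high, 0.6–0.8 moderate (boundaries
  inclusive), < 0.6 low.
* **Nominal resolution** r = 0.61 λ/NA (widefield), 0.4 λ/NA (confocal),
  reported in µm.

## Phenotyping (`phenotyping`)

Intensities are variance-stabilized (`log(x+1)` or `asinh(x/cofactor)`,
default cofactor 5 — the common imaging/cytometry choice) and each channel is
rescaled to its 1st–99th percentile range, clipped to [0, 1]; constant channels
are excluded with a warning. t-SNE uses perplexity 30, learning rate 500 and
early exaggeration 4 — embeddings are treated as qualitative; no analysis
depends on their coordinates.

EM Gaussian-mixture clustering is implemented in-package: full covariances
with 10⁻⁶ diagonal regularization, k-means++ initialization, 30 restarts
(best negative log-likelihood kept), convergence at relative NLL change
< 10⁻⁷ or 500 iterations. The per-iteration NLL trace is exposed and asserted
non-increasing. Model selection fits each k in a range and picks the **knee**
of the best-NLL curve: the k with maximum deviation below the chord joining
the curve's endpoints, with a flatness guard (total drop < 1% of the NLL
magnitude ⇒ no mixture structure, smallest k). The naive max-second-difference
elbow was evaluated and rejected: on well-separated 3-component data the 1→2
improvement dominates and it systematically selects k = 2, while the knee rule
recovers 1, 3 and 4 components correctly on data generated with those counts.
The curve is returned alongside the choice for manual override. The number of
restarts matters more than the tolerance: single-start EM regularly lands in
merged-component optima.

## Spatial analysis (`spatial`)

* **Field entropy.** The mosaic is tiled into regular fields; a field with
  more than `n_sample` (default 1000) cells contributes
  E = −Σ s_i² ln(s_i²), where s is the sampled intensity vector rescaled to
  unit L2 norm (so s_i² is a probability). E ranges from 0 (one cell carries
  all signal) to ln(n_sample) (perfect homogeneity). Normalized entropy is
  E_field/E_sample with E_sample from a whole-specimen draw. Per-cell means
  are used as the intensity signal; fields at or below the sample size are
  excluded rather than sampled with replacement.
* **Gating** is Otsu on log-transformed per-cell means by default (positivity
  thresholds are specimen-dependent; a fixed threshold is available), and
  composite gates are conjunctions.
* **Regions**: per-cell stromal-marker intensity (e.g. α-SMA) is accumulated
  on a coarse grid, Gaussian-smoothed (bandwidth 50 px default) and
  Otsu-split; marker-high = stroma, marker-low = tumor. Degenerate (constant)
  fields collapse to a single region with a warning.
* **kNN density** at a grid point is (k−1)/(n·π·d_k²) with k = 4 — the
  bias-corrected form whose expectation equals the true density for uniform
  points (the uncorrected k/(n·π·d_k²) overestimates by k/(k−1) = 4/3). Only
  ratios and products of densities are consumed downstream, so the constant
  affects nothing else. d_k is floored at half the grid spacing to keep
  point-coincident evaluations finite.
* **Co-occurrence**: within each region, each population's density is
  renormalized to a probability over the region's grid points (removing
  between-region abundance differences), and the map is their pointwise
  product; fold enrichment is the ratio of region means, hotspots the top
  decile of the product map.
* **Bootstrap counts**: within-region resampling with replacement (same size,
  default 100 rounds); SEM = sd/√n_boot across replicates.

## Pipeline and provenance

Stages run in dependency order (simulate → prep → segment → qc → phenotype →
spatial), each reading and writing only plain TIFF/CSV/JSON artifacts in the
output directory, so any stage can be re-run in isolation. A manifest records
per-artifact SHA-256 hashes, the configuration hash (file paths excluded) and
all warnings; two runs with the same configuration and seeds produce
hash-identical artifacts (the manifest's own timestamps aside). JSON is
written with sorted keys; CSV floats carry 17 significant digits. One seed is
recorded per stochastic stage. An OME-TIFF export of the assembled stack is
provided for interoperability.

## Problem sizes and defaults

The default run simulates a 2×2 grid of 256-px tiles (≈480 px stitched canvas,
0.65 µm/px), 3 cycles, ~500 cells — large enough that every stage exercises
its full code path (multi-tile stitching, multi-cycle registration, mixture
fitting on ~490 single cells) while a complete pipeline run stays around a
minute on one CPU. Recovery suites use 10–20 seeded replicates. At the default
scale no field exceeds the 1000-cell entropy threshold, so the end-to-end
entropy map is empty by the field-size rule; the entropy implementation is
exercised directly on larger synthetic fields instead.

## Known limitations

* The stitcher assumes a regular grid with known nominal overlap; it is not a
  general mosaic solver.
* Registration is rigid only; tissue deformation across cycles is out of scope.
* Nuclear-only segmentation over- or under-segments irregular cells; the
  cytoplasm ring is a fixed-width proxy.
* The generator's simplifications (above) bound what synthetic validation can
  claim about real specimens.
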