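# Methods

## The assay model

The pipeline quantifies how a cargo protein (ATG9A) partitions between the
trans-Golgi network and the rest of the cell. Four channels are acquired per
field: nuclear stain, cell-body marker (β-3 tubulin class), TGN marker
(TGN46/Golgin-97 class) and the cargo itself. All quantities derive from
binary masks:

1. each channel is thresholded at `local_background + k · robust_scale`;
2. a *cell* is an 8-connected cell-body component that contains a nucleus
   component and does not touch the field border;
3. within each cell, cargo pixels overlapping the TGN mask are *inside*, the
   remainder of the cargo∩body pixels are *outside* — an exact partition;
4. the per-cell statistic is `ratio = Σ F.U. inside / Σ F.U. outside`, with
   F.U. measured after subtracting the local-background map (see below);
5. per-well mean ratios are mapped to **percent translocation** by the unique
   affine transform anchoring the plate's untreated-KO control mean at 0 %
   and its untreated-WT control mean at 100 %. The map is intentionally not
   clamped: scores outside [0, 100] diagnose control drift and are logged.
6. toxicity QC: a well's cell count is standardized against the plate's
   untreated-KO control wells (sample SD, n−1); strict `Z > −3` means
   non-toxic, so a well exactly at −3 is toxic.

References are **per plate**: thresholds are tuned per plate, so ratios are
only comparable within one. Aggregation order is cells → well mean → per-MOI
mean ± SD (per-well means weight wells equally regardless of cell count).
Cells whose outside compartment has zero fluorescence have an undefined
ratio; they are excluded from well means (to keep infinities from dominating)
but still counted in `n_cells`, and exclusions are logged. Control wells with
no defined mean ratio (e.g. zero segmented cells) are likewise excluded from
the reference means and logged.

## Local background and thresholds

"Local background" is estimated on a grid of `background_window_px`-sized
tiles (default 128 px): per-tile median and MAD, bilinearly interpolated to
full resolution. A tiled estimator behaves like a sliding median as long as
foreground occupies well under half of any tile, and it is orders of
magnitude faster — the practical requirement for scoring whole plates. The
MAD is floored (default 1e−3) so constant images yield empty masks instead of
degenerate thresholds. Per-channel multipliers `k` default to
nucleus 3 / cell body 2 / TGN 3 / cargo 1.5 and are the per-plate tuning
knobs exposed in `RunConfig.thresholds`. Mask components smaller than a
per-channel pixel floor (nucleus 16 px, body 64 px, TGN 9 px) are removed as
shot-noise speckle; the cargo mask is never size-filtered so dim diffuse
cargo is retained.

Fluorescence sums subtract the same local-background map before summing.
Without this the F.U. of a compartment scales with its mask area times the
camera offset, and the inside/outside split of a planted field could not be
recovered; with it, noiseless synthetic fields are recovered exactly.

Masks use 0-based, row-major pixel coordinates, 8-connectivity for labelling,
and all areas are reported in µm² via `pixel_size_um²`. A nucleus component
overlapping several bodies is assigned to the body holding the majority of
its pixels (ties to the lower label). Border-touching cells are discarded
because truncated cells bias intensity ratios.

## Synthetic data: what it emulates and what it does not

The generator renders cells as non-overlapping disks: cell body of radius
8 µm, nucleus 3.5 µm, and a TGN disk of 2.5 µm tangent to the nucleus, at
0.325 µm/px (a typical 40× high-content pixel pitch). Per cell, a fixed
total cargo fluorescence (20 000 F.U.) is split exactly between the TGN
footprint and the rest of the body according to `cargo_inside_fraction`
— the generative dial for the phenotype. Defaults: KO-like wells 0.84 and
WT-like wells 0.70, chosen so the true inside/outside ratios (5.25 and 2.33)
echo the magnitudes the assay class reports for knockout versus
treated/wild-type cells. Noise is additive Gaussian (sd 0.5) on a constant
background (20), clipped at zero.

Plates follow the standard control layout (16 KO-untreated + 8 WT-untreated
wells); acquisition uses the 5×5 grid of 24 sites at 330 µm pitch with the
centre square omitted. The centre can only be omitted from odd grids — an
even grid has no unique centre site and the generator refuses rather than
guesses. Treated wells take their inside fraction and expected per-site cell
count from a caller-supplied MOI table (the default table spans MOI 1×10³ to
1.6×10⁷ with attrition at ≥4×10⁶); per-site counts are Poisson draws, backed
off deterministically when a draw cannot be placed without overlap. Every
well has its own seeded stream (master seed ⊕ CRC32 of the well id), so wells
regenerate independently and identical seeds give bit-identical plates.

Tissue fields plant a perinuclear ring spanning (0, 3 µm] from each nucleus
boundary (Euclidean distance to the nearest nucleus pixel) at
`enrichment × background` intensity, plus calbindin disks of requested areas
(accurate to one pixel ring). What the generator does **not** emulate:
optics (PSF, chromatic shift), 3-D stacks (inputs are assumed
maximum-intensity projections), realistic neuronal morphology, uneven
illumination, or cell-to-cell heterogeneity in the cargo split. Passing
tests therefore demonstrate correctness of the scoring operators on their
stated geometry, not robustness to real-microscopy artifacts — the per-plate
`k` knobs and the explicit background model are the levers a user would tune
on real data.

Problem sizes throughout the test suite and the acceptance run (fields of
320², ~6 cells per site, 1–4 sites per well) are deliberate scale-downs of a
production screen; all anchoring identities are exact at any scale, and the
stochastic recovery checks hold at these sizes with fixed seeds.

## Profiling

33 named per-cell features: 7 shape descriptors, 5 intensity statistics
(mean/median/max/integrated/homogeneity) × 4 channels, 3 TGN-specific
measures, a neurite-outgrowth proxy, and the two cargo compartment sums.
The proprietary high-content measures have no published formulas, so two are
implemented as documented surrogates and named as such: *roughness* is the
isoperimetric deficit `perimeter²/(4π·area) − 1` (0 for a disk; perimeter by
the Crofton estimator, which is far less biased on smooth shapes than
pixel-edge counting), and *homogeneity* is `1/(1 + CV)` of the staining
(1 for perfectly uniform intensity). The neurite proxy is the morphological
skeleton length of the cell body outside the nucleus dilated by 1 µm. Shape
descriptors of degenerate (<5 px) cells are NaN, and missing features
propagate as missing, never as zero. Condition profiles are
`(condition mean − KO mean)/KO SD` per feature over per-well means, with
zero-SD features emitted as missing with a warning.

## Tissue quantification

The perinuclear region is an annulus between `inner_offset` and
`inner_offset + width` from the nucleus boundary, computed from the Euclidean
distance transform and clipped to each pixel's nearest nucleus, which makes
annuli disjoint by construction. The original macro geometry is
unpublished; the geometry here is an explicit named per-region profile
(cortex/hippocampus/cerebellum/brainstem, all defaulting to offset 0 µm,
width 3 µm) recorded in every output row. Image background is the 10th
percentile of pixels outside all annuli and nuclei. Per-cell values are
annulus mean / background; group fold change is computed on per-image means
then averaged per group, so images weight equally regardless of cell count,
and the WT group's fold change is 1 exactly.

Spheroids are connected components of the thresholded calbindin channel kept
when strictly larger than 19.904 µm²; an object measuring exactly the
threshold is not counted.

## Numerical choices and edge cases

- Translocation with equal KO/WT references raises a degenerate-controls
  error; a layout without both control roles fails before any image work.
- Z-scores require ≥2 control wells and nonzero sample SD.
- `potency_table` reports per-MOI SD as NaN for single replicates and
  excludes (with a log line) wells lacking a defined mean ratio.
- Determinism: identical `(config, seed)` produce byte-identical CSVs; the
  resolved config is written next to every run's outputs for audit.
- Placement uses rejection sampling with a deterministic back-off when a
  requested cell count cannot fit without overlap; direct `generate_field`
  calls instead raise an error reporting the achievable count.
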