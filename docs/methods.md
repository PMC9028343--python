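# Methods

## SEM texture quantification

**Model.** A secondary-electron micrograph of psoriatic stratum corneum shows
bright corneocyte surfaces separated by dark, deep intercellular gaps; plaque
detachment increases both the number of gaps and the fraction of the frame
they occupy. The analysis reduces each image to two per-tile statistics:
N_G, the number of 8-connected gap regions, and N_PC, the number of pixels
outside every gap region.

**Banner policy.** The reference raster is 1750×2560 px, yet the reference
tile layout is 60 tiles of 250×250 — which is 6×10, not the 7×10 that
1750/250 would give. Tabletop SEMs stamp an instrument metadata bar along the
bottom edge of the saved frame, so the package treats the bottom 250 rows as
that banner by default (for 1750-row rasters; 0 otherwise), crops it, and
tiles the remaining 1500×2560 scan area into exactly 60 full tiles.
`banner_rows` is configurable; partial edge tiles are always discarded.

**Thresholding.** A pixel is a gap iff its intensity is *strictly below*
40 % of the maximum intensity (`frac`, default 0.40). Strictness means a
uniform tile — including an all-zero one — contains no gaps. The maximum is
taken per tile by default (`threshold_scope="tile"`), which adapts to local
brightness; `"image"` switches to the parent-image maximum. Gap polarity
(dark = gap) follows from gaps being the deep intercellular regions in
secondary-electron contrast. No histogram equalization, denoising or
morphological post-processing is applied.

**Border following.** Gap regions are enumerated with the Suzuki–Abe
raster-scan border-following algorithm, implemented here from first
principles: 8-connected foreground, 4-connected background, outer borders
and hole borders distinguished by their start condition, visited border
pixels marked ±NBD so no border is traced twice. Each 8-connected region has
exactly one outer border, so N_G equals the outer-border count. A gap region
containing an island of cell pixels counts once; its hole border is reported
in the contour output but does not enter N_G. Candidate border starts are
precomputed vectorially (foreground pixels with an empty west or east
neighbour) — an exact optimization, since the per-pixel start conditions are
re-checked against the evolving marker image. Contours are ordered by the
raster position of their start pixel, so output is deterministic. A
configurable `min_area` (default 1 px = no filter) can suppress small
regions; none is applied by default.

N_PC is the count of non-gap pixels, so `n_pc + gap_px = tile_px²` holds on
every tile by construction and is asserted across runs as a wiring check.

## Group statistics

All tests are two-sided with α = 0.05. The Mann–Whitney U test uses
mid-ranks for ties and reports U = min(U1, U2). For combined n ≤ 12 with no
ties the exact null distribution is computed by the classical counting
recurrence N(u; i, j) = N(u−j; i−1, j) + N(u; i, j−1) and the two-sided p is
the probability of min(U1, U2) at least as extreme; with ties a forced
`method="exact"` enumerates all group assignments directly. Larger samples —
including the 60-vs-60 tile comparisons, where exact enumeration is
infeasible and the approximation error is negligible — use the normal
approximation with tie-corrected variance and a 0.5 continuity correction.
Quartiles use linear interpolation between order statistics (the numpy
convention; box edges differ across conventions, so this is fixed and
documented). Standard deviations use the n−1 denominator; SEM divides by √n
over animals, not sites.

The two-way ANOVA is the fixed-effects form with sequential sums of squares
(A, then B given A, then interaction), computed by least-squares projections;
this reduces to the textbook mean decomposition for balanced layouts and
stays defined for unbalanced ones. The repeated-measures design of the
in-vivo endpoints is deliberately reduced to this fixed-effects form plus
per-timepoint tests, because a repeated-measures covariance structure is not
identifiable from the summaries the pipeline consumes; this is a known
limitation. The Bonferroni post-hoc compares treatment levels pairwise
within each timepoint using the pooled error variance, multiplying raw
p-values by the number of comparisons (capped at 1). Degenerate inputs with
zero error variance report F = 0, p = 1 when the effect is also zero, and
F = ∞ with the smallest positive float otherwise; an absolute/relative
tolerance of 1e-10 × total SS separates structural zeros from least-squares
round-off. No multiple-testing correction is applied across the comparison
table's six cells (none is in the reference analysis).

## Permeation

Fractions are collected every `interval_min` = 30 min at
`flow_ul_min` = 4 µL/min, so each vial holds exactly 120 µL. The standard
curve is ordinary least squares of concentration on absorbance (Beer–Lambert
linearity assumed); negative calibrated concentrations are floored at 0 with
a logged warning. Each fraction's concentration is attributed to its
interval's **end** time by default — the vial aggregates 30 min of effluent —
with a midpoint option. For integration a (0, 0) anchor is prepended (the
receptor starts drug-free) and the composite trapezoidal rule is applied
with linear interpolation at the window edges; the default window is
0–180 min because the uptake saturates by 3 h, with the full span available.
AUC is reported in µg·min/mL; division by the 0.5 cm² diffusion surface is
an option, not the default.

Plateau onset is the earliest fraction end-time t\* such that every
successive step strictly after t\* satisfies |ΔC| / max(C) ≤ `rel_tol`
(default 0.05); `None` if the profile is still rising at its end. The rule
is scale-invariant. For the noise-free reference curve (τ = 45 min, no lag,
30-min fractions) the 90→120 min step is 6.6 % of the maximum and every
later step is below 5 %, so t\* = 120 min; with a 60-min lag the same
geometry shifts to t\* = 180 min, matching the observed 3 h plateau onset.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions used throughout the tests and the acceptance script.

**Textures.** A nearest-seed (Voronoi) partition of the pixel grid into
`n_cells` cells (default 150 for the 1750×2560 raster; seed positions
uniform). Pixels within `gap_width_px` (default 2 px half-width, measured by
Euclidean distance transform from the mosaic edges) are painted at
`gap_intensity_mean` = 30; cell interiors at `cell_intensity_mean` = 200.
A `detachment_fraction` of cells each sheds a displaced bright copy
(intensity 245, offset 5–15 px) with a 2-px dark rim; rims are added to the
gap mask, and the boundary network is painted last so it stays visible
through overlying plaques — detachment therefore only ever adds gap pixels,
making planted gap area monotone in severity. The ground-truth mask and its
8-connected component count are captured before Gaussian noise
(`noise_sd` = 8 gray levels) is added and clipped to 0–255; banner rows are
stamped flat mid-gray (120) and excluded from the truth. With noise off and
the constructed 30/200 separation, the 40 %-of-maximum threshold recovers
the planted mask exactly — that is the designed calibration check, and noisy
runs then quantify segmentation sensitivity. The nearest-seed labels are
computed with a k-d tree and the boundary band with a distance transform;
both are exact, vectorized equivalents of the brute-force per-pixel
construction.

What the textures do **not** emulate: topographic shading, charging
artifacts, intensity gradients, or the fine multi-scale roughness of real
corneocytes. Real gap networks also fragment differently: a noise-free
mosaic yields one large connected gap network per tile, whereas pixel noise
and plaque rims fragment it. Passing tests therefore demonstrate algorithmic
correctness and calibration on controlled topology, not performance on real
micrographs.

**Permeation.** C(t) = c_ss·(1 − e^{−(t−t_lag)/τ}) for t > t_lag, else 0,
sampled at fraction end times; defaults c_ss = 12 µg/mL, τ = 45 min, lag 0,
10 fractions (5 h). IMQ arms scale c_ss by `permeation_effect` (default
2.5). Absorbance = C/slope under the declared calibration (slope 20 µg/mL
per AU, intercept 0), Gaussian absorbance noise (sd 0.01 AU) floored at 0.
The true AUC over any window comes from the closed-form primitive
c·[(t−lag) − τ(1 − e^{−(t−lag)/τ})].

**Functional series.** Baselines: thickness 0.7 mm, perfusion 100 AU,
weight 22 g, TEWL 8 g/m²/h; n = 5 animals/arm at 0–96 h in 24-h steps. IMQ
means ramp linearly to +100 % thickness, 3× TEWL, −10 % weight and 1.6×
perfusion at 96 h; VAS means stay flat; animal-level lognormal noise with
σ = 0.05 multiplies every value.

**Tile-statistic generator.** The type-I-error and power calibration of the
comparison table needs hundreds of replicate studies, for which full image
synthesis would be disproportionate; `generate_tile_stat_table` instead
draws per-tile N_G ~ Poisson(40 × effect) and gap areas ~ Gamma(2, 60) px
directly, preserving all tile-stat invariants, and feeds the identical
statistical pipeline. The base rate of 40 gaps per 250×250 tile represents a
moderately fragmented gap network.

**Seeding.** Child seeds are `(master_seed × 2654435761 + crc32(label)) mod 2³¹`,
so arms are mutually independent but reproducible; every generator is
bit-deterministic given its seed.

## Problem sizes

The test suite runs reduced rasters (160–800 px a side) for the
conservation, recovery and determinism properties, which are size-invariant;
the acceptance script runs the full default 1750×2560, 12-condition study
once for the conservation count, 1000 random masks up to 64×64 for the
contour/labeler comparison, 500 null and 100 planted-effect replicate
studies for the error-rate calibration, and 100 seeded textures (160×160)
for ground-truth recovery.

## Known limitations

* Whether the reference analysis took the threshold maximum per tile or per
  image, and whether hole borders were counted as separate gaps, is not
  specified; per-tile scope and outer-border counting are the package's
  recorded choices (both configurable or documented above).
* The comparison table treats the 60 tiles of one image per condition as the
  Mann–Whitney samples; pooling tiles across animals is supported by simply
  concatenating tile tables but is not the default.
* Tiles are spatial subdivisions of one micrograph, so they are not strictly
  independent samples; the tests quantify the procedure as defined, not the
  exchangeability assumption.
* Absolute AUC levels of the reference experiments are not published
  numerically, so only relative and structural permeation properties are
  asserted.
* No mechanistic diffusion model, no mixed-effects/repeated-measures
  covariance modeling, no photorealistic SEM simulation.
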