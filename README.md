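# dermaquant

Quantitative analysis of psoriatic skin for experimental dermatology:
scanning-electron-microscopy (SEM) surface texture statistics, skin-on-a-chip
drug-permeation profiling, and longitudinal functional barrier readouts — plus
synthetic-data generators with known ground truth so the whole pipeline is
testable end to end.

In the imiquimod (IMQ) mouse model of psoriasiform dermatitis, corneocyte
plaques detach from the stratum corneum and deep intercellular gaps open
between them. `dermaquant` quantifies this from SEM micrographs and relates it
to barrier function:

1. **SEM gap statistics.** Each grayscale raster (reference size 1750×2560 px
   with a 250-row instrument banner) is cropped and cut into 250×250 tiles
   (60 per image). Each tile is binarized at 40 % of its maximum intensity —
   pixels strictly below the cutoff are *gap* pixels, the rest are cell
   surface. Gap regions are enumerated by raster-scan border following
   (Suzuki–Abe) on the 8-connected foreground, giving per tile

   *N<sub>G</sub>* = |G|, the number of gap regions, and
   *N<sub>PC</sub>* = |P<sub>C</sub>|, the number of cell-surface pixels.

   Vaseline-control (VAS) and IMQ arms are compared per (strain, timepoint)
   with the two-sided Mann–Whitney U test over the 60-tile sequences; tile
   sequences are also summarized as five-number boxplot rows.

2. **Skin-on-a-chip permeation.** Receptor effluent from a flow-through
   diffusion cell (4 µL/min, 30-min fractions, 0.5 cm² surface) is read
   spectrophotometrically at 273 nm. Absorbances map to concentrations via a
   linear standard curve; the concentration–time profile (each fraction at its
   interval's end time, a (0, 0) anchor prepended) is integrated by the
   composite trapezoidal rule to AUC (µg·min/mL, default window 0–180 min),
   and the plateau onset is the earliest fraction after which every successive
   step is ≤ 5 % of the profile maximum. Groups are compared with two-way
   ANOVA (treatment × timepoint) plus Bonferroni post-hoc, or Student's t.

3. **Functional parameters.** Double-fold skin thickness (2 sites), TEWL
   (3 sites), perfusion and body weight are site-averaged, normalized to the
   0 h baseline as percent change, and summarized as mean ± SEM per
   (strain, treatment) group.

All test statistics (Mann–Whitney with mid-ranks, exact small-sample
distribution and tie-corrected normal approximation; sequential-SS two-way
ANOVA; Bonferroni; Student's t) are implemented from first principles and
cross-checked against independent oracles in the test suite.

## Worked example

```python
from dermaquant import (TextureParams, generate_sem_texture, crop_scan_area,
                        tile_image, segment_tiles, mann_whitney)

# healthy-like texture: large cells, no plaque shedding
params = TextureParams(height_px=750, width_px=1000, banner_rows=0,
                       n_cells=40, noise_sd=8.0, rng_seed=1)
img, truth = generate_sem_texture(params)
stats = segment_tiles(tile_image(crop_scan_area(img), tile_px=250), frac=0.40)
print(len(stats), stats[0].n_g, stats[0].n_pc, stats[0].gap_px)

# psoriatic-like texture: smaller cells plus 30 % plaque detachment
sick = TextureParams(height_px=750, width_px=1000, banner_rows=0, n_cells=100,
                     detachment_fraction=0.3, noise_sd=8.0, rng_seed=2)
img2, _ = generate_sem_texture(sick)
stats2 = segment_tiles(tile_image(crop_scan_area(img2), 250), frac=0.40)
res = mann_whitney([s.n_pc for s in stats], [s.n_pc for s in stats2])
print(res.statistic_value, res.p_value)
```

prints

```
12 1 60468 2032
0.0 3.66e-05
```

— 12 tiles; the first healthy tile has one connected gap network of 2032
pixels and 60 468 cell-surface pixels; the diseased texture loses enough cell
surface that the Mann–Whitney U statistic over the two 12-tile N<sub>PC</sub>
sequences is 0 (complete separation), p ≈ 3.7 × 10⁻⁵.

On the permeation side, a noise-free saturating uptake curve with τ = 45 min
integrated over 0–180 min gives a trapezoid AUC of 1610.4 µg·min/mL against a
closed-form value of 1629.9 (1.2 % quadrature error at 30-min fraction
spacing), with the plateau rule firing at 120 min.

A full study (3 strains × VAS/IMQ × 24 h/96 h) runs from the command line:

```sh
dermaquant synthesize --seed 7 --out study/        # write a study bundle
dermaquant run --seed 7 --bundle study --out out/  # or omit --bundle to
                                                   # synthesize in memory
```

producing `tile_stats.csv`, `comparison_table.csv`, `boxplot_summary.csv`,
`auc_table.csv`, `functional_pct.csv`, per-arm yellow/blue gap overlays and a
`run_manifest.json` recording every parameter and seed. Identical config and
seed reproduce every CSV byte for byte.

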