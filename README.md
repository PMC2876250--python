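# silverquant

Laminar quantification of silver-stained lysosomal precipitates in
dark-field microscopy, with the factorial statistics of a
rearing x wheel-running x layer design.

Gallyas silver impregnation deposits silver on the secondary lysosomes
that accumulate transiently in remodeling axon terminals; in dark-field
optics these precipitates appear as bright, few-pixel spots on a dark
background, and their density per anatomical layer is a proxy for the
local rate of synaptic turnover. This package is for researchers who want
to (a) count such precipitates reproducibly inside predefined laminar
measuring fields, and (b) analyse per-animal counts from a 2 (enriched vs
deprived rearing) x 2 (voluntary wheel running) x layer design in the
hippocampal formation (dentate gyrus, CA3, CA1, subiculum, entorhinal
cortex). Because no raw micrographs or per-animal tables are publicly
available for the original cohort, the package ships first-class
synthetic generators — ground-truth dark-field images and cohort count
tables at the published group means — against which every stage is
validated.

## The method

**Counting.** Each measuring field (three joined 200 x 50 px subfields,
600 x 50 px total, height fitted per section) is processed in four steps:
conversion to an intensity raster; normalization of the field median to
zero; convolution with a zero-sum centre-surround filter that enhances
few-pixel bright spots; thresholding followed by "thinning" of every
detected spot to a single pixel, so the count is independent of spot
size. Thinning is one representative pixel per connected component. The
default threshold is robust (3.8 x a clipping-tolerant noise-scale
estimate of the filtered field) and transfers across spot densities.

**Statistics.** Per region, a fixed-effects factorial ANOVA
(Type III sums of squares, sum-to-zero contrasts, appropriate for the
unbalanced 7/6/7/5 animal cells) on rearing, wheel running and layer,
followed by Tukey–Kramer unequal-n HSD comparisons

  q_ij = |m_i − m_j| / sqrt( (MS_e/2)(1/n_i + 1/n_j) ),

referred to the studentized range distribution with the error term of the
region's full model. Reports give group means ± SEM over animals and
signed integer percent differences, `round(100 (comparison −
baseline)/baseline)`.

## Worked example

```python
from silverquant import (
    ImageSimSpec, generate_image, LayerLabel, build_field, count_field,
    CohortSimSpec, generate_cohort, animal_layer_means, group_summary,
    region_analysis, percent_difference,
)

# a 600 x 50 field with 250 ground-truth spots, dimmest spot at SNR 5
spec = ImageSimSpec(n_spots=250, noise_sigma=0.11, seed=7)
image, truth = generate_image(spec)
field = build_field(LayerLabel("DG", "iML", "spb"), anchor=(0, 0))
print("true spots:", len(truth), "| counted:", count_field(image, field))

# a simulated 25-animal cohort at the published group means
cohort = generate_cohort(CohortSimSpec(seed=7))
animals = animal_layer_means(cohort)
res = region_analysis(animals, "CA1")
print(res.anova.round(2).loc[["wheel", "lamina", "Residual"]])
```

prints

```
true spots: 250 | counted: 247
          df     sum_sq    mean_sq       F    p
wheel      1  151021.32  151021.32  114.75  0.0
lamina     3  666955.34  222318.45  168.92  0.0
Residual  84  110551.61    1316.09     NaN  NaN
```

— the count recovers ground truth to ~1% under heavy noise, and the
simulated CA1 cohort shows the design's signature: a strong laminar
gradient (stratum pyramidale lowest, lacunosum-moleculare highest) and a
strong wheel-running effect that compresses it. Continuing,

```python
cells = group_summary(animals)
er = cells.query("region=='CA1' and layer=='Sr' and rearing=='ER'")
base = er[er.wheel == 'no']['mean'].item()
comp = er[er.wheel == 'yes']['mean'].item()
print(f"{base:.1f} -> {comp:.1f} ({percent_difference(base, comp):+d}%)")
# 289.1 -> 188.4 (-35%)
```

i.e. four days of running lowers the ER stratum-radiatum count by about a
third in this simulated cohort.

The numbered scripts under `analysis/` run the same pipeline as a
narrative: `01_simulate_images.py` renders section montages with known
ground truth, `02_count_fields.py` counts every placed field,
`03_validate_detection.py` benchmarks recall/precision,
`04_simulate_cohort.py` … `07_report.py` take the cohort through
aggregation, regional ANOVA + post hocs, and the final comparison table
and figures (written under `results/`).

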