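# Methods

`silverquant` quantifies synaptic-remodeling proxies — bright, few-pixel
silver-stained lysosomal precipitates seen in dark-field microscopy of
Gallyas-impregnated brain sections — inside laminar measuring fields, and
analyses the resulting counts with the factorial design of the underlying
study: 2 rearing conditions (enriched, ER; deprived, DR) x 2 wheel-running
conditions x anatomical layer, in five regions (dentate gyrus, CA3, CA1,
subiculum, entorhinal cortex).

## Measuring fields

A measuring field is three rectangular subfields of 200 x h pixels joined
edge to edge into a 600 x h strip; h defaults to 50 px and is treated as a
per-section parameter so the field height can be fitted to the thickness
of the granule cell layer. The 200-px subfield width is fixed. Fields are
placed by a caller-supplied anchor and orientation (automatic anatomical
registration is out of scope); coordinates are 0-based row-major with
half-open rectangles `[r0, r1) x [c0, c1)`. The three subfields are
extracted as one contiguous strip, so objects straddling the internal
joins are never double-counted. Rotated placements are resampled
nearest-neighbour: intensities are never interpolated, and axis-aligned
integer placements are exact crops. The taxonomy is fixed at 21 laminar
positions: 10 in the dentate gyrus (oML, mML, iML, gcl, sgl in both the
suprapyramidal and infrapyramidal blade), 4 strata each in CA3 (So, Sp,
Sl, Sr) and CA1 (So, Sp, Sr, Slm), layer III of the subiculum, and
laminae II/III of the entorhinal cortex.

## The four-step counter

Counts per field are produced by:

1. **Grayscale.** RGB input is reduced with Rec. 709 luminance weights;
   grayscale input passes through unchanged.
2. **Median normalization.** The field's median intensity is shifted to
   zero, removing the (region- and illumination-dependent) background
   level. This makes the count invariant to global intensity offsets.
3. **Linear spot filter.** A zero-sum 5x5 centre-surround kernel (centre
   +1, outer ring -1/16, inner ring 0) is convolved with the field
   (reflected borders). The original tool's filter matrix is not public;
   this kernel realizes its stated purpose — contrast enhancement of
   few-pixel bright spots on a dark background. The zero inner ring means
   any spot fitting a 3x3 footprint retains its full contrast at its
   central pixel, so one threshold works across the 1-9 px size range.
   The kernel is fully configurable.
4. **Threshold, thin, count.** Pixels strictly above the threshold form
   the spot mask; every 8-connected component (4-connectivity optional)
   is then reduced to a single representative pixel — the component pixel
   nearest its centroid — and the representatives are counted. "Thinning"
   is deliberately implemented as one-pixel-per-component rather than
   morphological skeletonization, because its purpose is a count that is
   independent of precipitate size.

**Threshold choice.** The default threshold is `k_sigma` (3.8) times a
robust noise-scale estimate of the filtered field: the 62.5th-percentile
deviation above the median, divided by its standard-normal value 0.3186.
A conventional two-sided MAD is biased here for two reasons: the
dark-field background sits near the intensity floor, so its lower noise
tail is clipped (deflating the MAD), while at high spot densities the
spot pixels inflate it. The low upper quantile is insensitive to both
(it tolerates >30% contamination on either side). In sweeps over seeded
images the resulting threshold stays at 0.43–0.46 of dynamic range across
50–400 spots per field, inside the 0.40–0.50 band in which false
positives are below ~1 per empty field and recall of SNR-5 spots exceeds
0.99. On a noise-free field the estimate degenerates to zero and the
strict `>` threshold still recovers every spot exactly. An absolute
threshold can be supplied instead.

## Synthetic data

**Images.** `generate_image` renders a flat background (default 0.05 of
dynamic range) carrying `n_spots` compact blobs of 1–9 px (centre-out
spiral shapes, so every spot contains its central pixel) with intensities
uniform in 0.6–1.0, plus additive Gaussian noise clipped to [0, 1].
Spot centres keep a Chebyshev separation of `2 r_max + 2` px, leaving at
least two background pixels between footprints; ground truth is therefore
unambiguous (the number of bright connected components in the noiseless
rendering equals `n_spots` exactly, and is tested). Optional large bright
discs emulate vessel-like confounders and are excluded from ground truth.
Not modeled: staining chemistry, the microscope PSF, 3D section
thickness, background texture. Passing the recovery benchmark therefore
shows that the counting logic is correct under the stated noise model,
not that the detector is robust to every real-world artifact.

**Cohorts.** `generate_cohort` draws integer counts for each animal x
section x lamina as `round(max(0, mean + animal offset + section
noise))`. Defaults are the study's conditions: the published group mean
counts for all 21 laminae x 4 groups; 25 animals in cells ER/no-wheel 7,
ER/wheel 6, DR/no-wheel 7, DR/wheel 5 (13 enriched- and 12
deprived-reared animals, of which 6 and 5 ran wheels); 14–20 sections
per animal in DG/CA3/CA1 and 6–8 in subiculum/entorhinal cortex. The
animal offset (SD 40 counts) is shared across that animal's laminae —
between-animal variability in staining intensity affects all layers
together — and section noise (SD 60 counts) is independent. These SDs
are not published; they were fixed once at values giving group SEMs of
roughly 10–16 counts at the study's n (a between-animal CV of ~15–20% of
a typical 250-count layer), which is the plausible range for histological
counts of this magnitude. Counts truncate at zero; at the default means
(57–381) the truncation bias is far below 1%.

## Aggregation

Animals are the sampling unit: section counts are averaged within animal
and lamina first; group means and SEMs (SD/sqrt(n), ddof 1) are computed
over animal means. Animals missing a lamina drop out of that cell with a
logged warning, yielding the unequal n the post hoc is built for. Section
counts outside the design ranges warn but do not fail. With this rule one
observation per animal x lamina enters the regional models, which makes
the CA3/CA1 residual df 84 (25 x 4 observations minus 16 model df) — the
same denominator the original analyses report for those regions. The
original dentate gyrus denominator (21) is not reproducible under any
single aggregation rule over 25 animals and is not reverse-engineered.

## Statistics

Each region is fitted separately with a fixed-effects factorial ANOVA on
rearing x wheel x lamina (all interactions). Because the design is
unbalanced, Type III sums of squares under sum-to-zero contrasts are
used (the default of the software used in the original analyses); the fit
is an OLS cell-means model, F = MS_term/MS_error, p from the F
distribution. Empty design cells raise an aliasing error naming the
cells. The implementation is cross-checked in the tests against an
independent design-matrix least-squares projection (and, during
development, against R's `car::Anova`, which agrees to print precision).

Post hoc comparisons use the Tukey–Kramer unequal-n HSD: for cells i, j

    q = |m_i - m_j| / sqrt( (MS_error / 2) (1/n_i + 1/n_j) )

with MS_error and df from the same region's full factorial model, and the
adjusted p from the studentized range distribution with k = number of
cells. With equal n this reduces exactly to the classical Tukey HSD. The
Spjotvoll–Stoline variant (1/min(n_i, n_j) in place of the average;
conservative) is available behind a flag. The studentized-range tail is
evaluated by scipy's numerical integration (absolute error well below
1e-6 in the ranges used) and is verified against a million-draw Monte
Carlo oracle.

The factorial model treats animal x lamina observations as independent;
the shared per-animal offset in the generator induces within-animal
correlation, so the regional F tests on simulated cohorts are
approximate, exactly as they are for the real design (mixed models are a
non-goal). The Type-I calibration study therefore uses independent
Gaussian errors, where the Type III F test is exact.

## Reporting

Percent differences are `100 (comparison - baseline)/baseline`, rounded
half away from zero to signed integers; the baseline is always the
denominator, so the column is intentionally asymmetric. Three contrasts
are reported per lamina: ER vs DR, ER vs ER-after-running, DR vs
DR-after-running. Significance strings follow the study's convention:
thresholds at .05/.01/.001, trend p below .10 printed numerically (".09"),
otherwise "n.s.". One published cell (gcl spb, ER vs DR: 92 vs 106 prints
16, recomputation gives 15.2) shows the original percentages were taken
from unrounded means; round-trip checks are restricted to rows that are
self-consistent under rounding.

## Validation studies and problem sizes

All evaluation experiments live in `silverquant.validation` and are run
identically by the test suite, the analysis drivers and
`scripts/acceptance.py`:

* **Detection benchmark** — 100 seeded 600 x 50 fields, 50–400 spots,
  noise sigma 0.11 (dimmest spot at SNR 5), greedy one-to-one matching
  within 2 px: recall and precision ~0.99. 20 noise-free fields are
  counted exactly.
* **Type-I calibration** — 2000 null replicates of an unbalanced
  2 x 2 x 4 design; the rearing rejection rate at alpha .05 is within
  +/-0.015 of nominal.
* **Pattern recovery** — 60 cohort replicates at the default means:
  the lamina effect is significant at p < .001 in DG/CA3/CA1 in every
  replicate, and the "leveling" signature of wheel running (wheel main
  effect p < .05 together with a reduced SD of lamina means, averaged
  over the rearing groups) appears in >= 95% of replicates. The leveling
  statistic uses the wheel main effect rather than the wheel x lamina
  interaction: the interaction is the weaker, region-dependent signal
  (in CA3 the pyramidal layer count rises after running while the
  neuropil layers fall, and in the 10-lamina dentate model the
  interaction is underpowered at the study's n), whereas the main-effect-
  plus-spread criterion captures the compression of the laminar profile
  uniformly. CA3 is the borderline region (~95–97% of replicates) because
  the opposing pyramidal-layer shift erodes its wheel main effect.

## Known limitations

* The original filter matrix and threshold are not public; absolute
  counts from real micrographs are not expected to match the published
  table and are validated on synthetic ground truth only.
* Laminar curvature is approximated by rigid placement of the three-part
  strip; no bending rule is applied.
* No mixed-effects or repeated-measures modeling; regions are analysed
  separately without family-wise correction across regions, mirroring
  the original analysis.
* Cohort simulation reproduces group means and plausible dispersion, not
  the unpublished per-animal raw data; published F statistics are
  therefore out of reach by construction.
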