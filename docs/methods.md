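# Methods

`maizemap` implements a phenology-driven pipeline for mapping maize cropland
from multispectral satellite time series, exercised end to end on synthetic
scenes so that every stage is testable on a desktop without any satellite
download.  This note records the model, its assumptions, the tunable
parameters and the design choices that were genuinely open.

## Problem setting

In one-season planting regions a pixel bears a single crop per year, so one
April–November sequence of surface reflectance characterises it.  The
pipeline classifies each 30 m pixel into {maize, soybean, rice, others} from
Landsat-style 6-band reflectance (Blue, Green, Red, NIR, SWIR1, SWIR2) and
publishes a binary maize map (1 = maize, 0 = non-maize).

## Synthetic scenes

The simulator replaces the satellite archive and field surveys.  Each class
carries a piecewise-linear seasonal mean-reflectance curve per band
(`PhenologyProfile`): crops start at bare-soil (rice: open-water)
reflectance, green up to a canopy peak — maize peaks in late July, soybean
and rice two to three weeks later — and collapse back to soil after
harvest; "others" is a low-amplitude mixture whose seasonal NIR range stays
below 0.1.  Scenes are sampled on a 16-day revisit cadence over day-of-year
91–334 (no leap handling at this toy scale).  Per-pixel observations are
curve values plus Gaussian noise (s.d. 0.02 reflectance in every band — a
round figure for sensor noise plus within-class variability at Landsat
scale) truncated to [0, 1].  Cloud contamination is i.i.d. per pixel and
scene (default probability 0.05); contaminated observations are flagged and
overwritten with a bright signature with Blue ≥ 0.4, chosen so that a
max-value composite computed *without* cloud handling is visibly corrupted —
this is what makes the cloud stages observable in tests.

The landscape is a mosaic of rectangular single-class parcels (side ~4 px,
emulating small-scale farmland).  Parcel classes are allocated by exact
proportion (a shuffled list, not i.i.d. draws) so class pixel counts track
the requested fractions tightly.  Defaults: 64×64 grid, class fractions
(maize 0.30, soybean 0.25, rice 0.15, others 0.30) within cropland,
cropland fraction 0.8.  The fractions keep the qualitative ordering of a
large field-survey pool (maize and others most common, rice least) while
guaranteeing every class at least ~400 eligible pixels on the default grid,
the stratified sample size used throughout.  Non-cropland parcels always
carry the "others" profile and are excluded from the cropland mask.  A 2×2
block partition stands in for prefectures when areas are aggregated.
Reference ("yearbook") areas are per-region true maize areas perturbed by
multiplicative lognormal noise (default s.d. 0.05).

What the simulator does *not* emulate: atmospheric and BRDF effects,
topography, mixed pixels, spatially correlated clouds, registration error,
and inter-annual phenology shifts.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the stated noise model, not
real-Landsat accuracy.

## Compositing

1. **Scene filtering** — scenes whose flagged-pixel fraction exceeds
   `max_cloud_fraction` (default 0.8; any value is configurable) are
   dropped; it is an error if a two-month window loses all its scenes.
2. **Gap filling** — each remaining flagged (pixel, band, date) is replaced
   by the value at the nearest-in-time date where that pixel/band is clean,
   ties toward the earlier date; the search is unbounded within the season.
   Observations with no clean donor anywhere stay invalid and are excluded.
3. **Maximum-value composite** — per pixel, per band, the maximum over
   valid observations in each of the four fixed windows Apr 1–May 31,
   Jun 1–Jul 31, Aug 1–Sep 30, Oct 1–Nov 30, yielding 4 × 6 = 24 features
   per pixel, flattened period-major.  The maximum is taken independently
   per band; a whole-observation (e.g. max-NDVI) compositing criterion
   would also be defensible, but per-band is the simplest reading and is
   what the brute-force oracle tests pin down.  A period with no valid
   observation for a pixel marks that pixel invalid; invalid pixels are
   excluded from training and carry nodata in prediction.

NDVI, EVI and NDWI (the usual formulations) can be stacked per period as
channels 7–9 behind `compositing.use_indices`; the default model uses bands
only — the index ablation does not improve a model that already sees all
six bands, and the flag exists so the ablation can be rerun.

## Classifier

A 3-layer LSTM (hidden size 128) consumes the composite as a 4-timestep
sequence of 6-band vectors — the sequence-of-bands reading matches the
spectral-temporal framing; a 24-step scalar sequence would be the
alternative.  The final hidden state feeds a fully connected head
128 → 128 → 64 with tanh on the first two layers; the 64-dim output f is
the discriminative feature on which the center loss acts, and a linear +
softmax layer yields the 4-class probabilities.  A per-class-sigmoid output
(normalised to sum to one) is available via `output_activation="sigmoid"`;
softmax is the default because the cross-entropy target is a distribution
over the four classes.

Losses, with N the batch size and q the one-hot label:

- cross-entropy  L_ce = −(1/N) Σ_i Σ_j q_ij log p_ij  (probabilities
  clipped to [1e−12, 1 − 1e−12]);
- center loss    L_c = ½ Σ_i ‖f_i − c_{y_i}‖²  (a sum, not a mean);
- total          L = L_ce + w·L_c.

Centers are not optimizer parameters: after each gradient step, each class
present in the batch moves by c_j ← c_j − α·mean(c_j − f_i) with α = 0.5,
the standard mini-batch center update.  The center-loss gradient w·(f − c)
flows into the features.

**Sign of w.**  For the center term to *penalise* intraclass spread, w must
be positive; the default is w = +0.001.  With w = −0.001 the term rewards
spread: on well-separated synthetic data the features inflate, the tanh
head saturates and training accuracy collapses to chance within ~20 epochs
(a regression test documents this).  Both signs are accepted by the
configuration.

Training: Adam (lr 0.001, default betas), batch size 20, default 250
epochs; on the default synthetic scenario the loss plateaus long before
that, and the desk-scale experiments in the tests and the acceptance script
use 50 epochs.  All randomness (initialisation, shuffling) derives from the
configured seed; runs are bit-reproducible single-threaded.  Training is
4-class; mapping is binary (argmax = maize → 1), which keeps the negative
classes balanced during optimisation.

The network is implemented directly in NumPy with hand-written
backpropagation (verified against central finite differences in the test
suite); sequences of length 4 with small batches make this comfortably fast
without a deep-learning framework.

## Postprocessing

The binary map is cleaned in a fixed order: cropland masking first (pixels
outside the mask → 0, nodata propagated), then minimum-mapping-unit
despeckling (4-connected maize components smaller than `min_patch_px`,
default 4 px ≈ 0.36 ha, are removed).  Masking only shrinks components, so
mask→despeckle removes a superset of what despeckle→mask removes; the
stricter order is deliberate.  A `MaskSchedule` maps map years to mask
vintages (2013–2015 → 2015 mask, 2016–2019 → 2019 mask, 2020–2021 → 2020
mask) for multi-year production.

## Evaluation

Confusion matrices are oriented truth-rows/prediction-columns.  UA
(user's accuracy, precision) is column-wise, PA (producer's accuracy,
recall) row-wise, F1 their harmonic mean, OA the trace over the total;
4-class matrices can be collapsed to maize/non-maize with counts conserved.
Metrics are reported at full precision; `round_half_up` reproduces printed
2- or 3-decimal table style.  Area consistency is the squared Pearson
correlation R² between per-region mapped areas (maize pixels × 900 m², in
ha) and reference areas, computed in centered-sum form so exact agreement
gives exactly 1.0; 1 − SSE/SST against the identity line is available as a
secondary statistic that also penalises bias.

## Numerical and degenerate-input choices

- Zero denominators (spectral indices, empty confusion rows/columns,
  constant area vectors) yield NaN markers, never exceptions.
- Probabilities are clipped before logs; training aborts on non-finite loss.
- Nearest-date ties in gap filling go to the earlier date.
- Train/test split takes ⌊n·fraction + ½⌋ training samples per class.
- Rasters are float32 (reflectance, nodata −9999) or uint8 (maps, nodata
  255) TIFFs carrying ModelPixelScale/ModelTiepoint/GDAL_NODATA tags on a
  single local 30 m metric grid; no CRS machinery beyond that is modelled.

## Problem sizes

Default experiment: 64×64 pixels, 16 scenes, 1600 labeled samples (400 per
class, 70/30 split), 50 training epochs — a scale chosen so a full run
completes in about a minute on one CPU core while leaving every stage
statistically meaningful.  The oracle tests use ≤5×5 grids and ≤8 dates
where exhaustive enumeration is feasible.

## Known limitations

- The simulator's class separability is optimistic; held-out accuracies
  near 0.99 reflect the noise model, not expected real-world performance.
- Gap filling searches the whole season, so a donor from a different
  two-month window can (rarely, at 16-day cadence) shift a composite value
  relative to the hypothetical cloud-free composite.
- Center updates depend on batch composition, so training is reproducible
  only under the fixed shuffling seed.
- Areas are raw pixel counts; no sampling-design (stratified) area
  estimators are provided.
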