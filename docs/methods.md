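# Methods

This note documents the models, parameter choices and numerical decisions
behind `laiscape`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Retrieval model

The chain NDVI → FVC → LAI assumes a linear unmixing of NDVI between a
bare-soil endmember NDVI_s and a fully-vegetated endmember NDVI_v, and a
Beer–Lambert relation FVC = 1 − exp(−k·LAI) between cover fraction and
leaf area. Parameters:

| parameter | units | default | rationale |
|---|---|---|---|
| k (extinction coefficient) | – | 0.54 | standard value for mid-latitude solar geometry over crops; treated as a scalar (no zenith-angle dependence) |
| LAI cap | – | 7.0 | upper end of the plausible crop range; prevents the log inversion from diverging as NDVI → NDVI_v |
| endmember histogram bin | NDVI | 0.01 | endmember estimation below |

**Endmember estimation.** "Histogram analysis" of the reference classes is
operationalized as the *mode of a 0.01-wide histogram*, reported as the
mean of the values inside the modal bin. The within-bin mean makes the
estimator exact for degenerate (single-valued) references and insensitive
to how bin edges fall relative to the data; ties break toward the higher
bin for the vegetated endmember and the lower bin for the soil endmember.
Percentile- or inspection-based alternatives would be equally defensible;
the mode is robust to outliers and reproducible.

**Negative and saturated values.** NDVI below NDVI_s (bare-soil
heterogeneity) gives negative FVC and is clamped to LAI 0. NDVI above the
FVC value implied by the LAI cap is truncated to the cap, because the
inversion is unbounded as FVC → 1: near the vegetated endmember the
sensitivity dLAI/dNDVI grows without bound, the familiar NDVI saturation
regime, and retrieved values there carry little information.

## Field segmentation

A pixel is "potentially mixed" unless all 8 neighbours exist and share its
land-use class (Moore neighbourhood; the strictest reading, configurable to
4). Fields are 4-connected components of the kept pixels with identical
class; 4-connectivity is the conservative choice, and since removed borders
are one pixel wide on each side, 8-connectivity could not bridge them
anyway. Labels are assigned in row-major order of each component's first
pixel, so segmentation is fully deterministic. Adjacent fields of the same
class merge by construction — an inherent limitation of class-based
segmentation that matters when few classes are present (see "What the
synthetic tests show" below). The size filter removes fields with area
≤ threshold, the threshold defaulting to the median field area; majority
resampling of class rasters breaks ties toward the lowest class code.

Plausibility filtering marks pixels whose LAI exceeds a per-crop,
per-date-window maximum (e.g. substantial LAI on a maize field in winter
points to weeds, catch crops or misclassification). Defaults flag LAI
above 0.3 before a crop's emergence day. The filter applies to per-crop
analyses only; overall-arable-area statistics deliberately include the
flagged pixels, since they are real vegetation regardless of the label.
For field-level datasets whole fields are excluded; for pixel-level
datasets individual pixels.

## Variability statistics

All SDs are population SDs (divide by n): the rasters are complete
populations of the analysed area, not samples. Overall statistics use the
law of total variance with abundance weights,
Var = Σ wᵢ(SDᵢ² + (meanᵢ − m)²); a within-group-only pooling mode exists
but is not the default, because an overall SD that exceeds every per-crop
SD — the mid-season signature of crops at different phenological stages —
can only arise from the between-crop term.

RFD bins are half-open [c·w, (c+1)·w), anchored at zero, values on an edge
going up; class width defaults to 0.1 LAI. The field-mean RFD weights each
field by its pixel count (area weighting) so pixel- and field-level RFDs
are measure-compatible; an unweighted variant is a one-line change on the
aggregates table. The normal comparator RFD folds its sub-zero mass into
the first class (empirical LAI cannot be negative) and renormalizes;
truncation alternatives would change accordance values only in the third
decimal for the means and SDs that occur here.

Accordance Σ min(pᵢ,qᵢ) equals 1 − total-variation distance, is symmetric,
and can only decrease under bin refinement; the tests verify all three
properties against independent computations.

## Geostatistics

The empirical semivariogram uses the classical Matheron estimator on
half-open 200 m distance bins (configurable) up to a maximum lag, computed
blockwise so memory stays bounded for ~10⁴ points. Two details follow the
behaviour of the standard R geostatistics tooling rather than the textbook
formula: least-squares weights default to N(h)/h² (pair count over squared
distance), and the model is evaluated at each bin's *mean pair distance*
instead of the geometric bin centre. Both matter in practice — with plain
pair-count weights and bin centres, short effective ranges were
systematically overestimated by ~25% on fields-scale structure.

The fit ladder tries, in order: (1) nested two-exponential plus nugget
with default starts (ranges at 1/10 and 1/2 of the maximum lag, sills
split from the empirical plateau), (2) a 3×3 grid of range start pairs,
(3) the alternative weighting (plain pair counts), (4) nugget fixed at
zero, (5) a simple exponential, and (6) truncation of the empirical
variogram at 6 km followed by (1)–(5). A candidate is accepted when the
optimizer converged *and* its relative RMSE over the transition zone (lags
between 50% and 150% of the shortest effective range, or the first three
occupied bins when the transition is below bin resolution) is under 15% —
an operationalization of "the model must fit the transition to the
plateau". If every step fails, a non-converged model object is returned
rather than an exception, because unfittable dates are an expected outcome,
not an error.

Effective (practical) ranges are 3aᵢ, the lag where an exponential
component reaches ≈95% of its partial sill (exactly aᵢ·ln 20 ≈ 2.996aᵢ);
the raw parameters are reported alongside. Components whose partial sill
is below 10⁻⁶ of the total sill are treated as degenerate. Subsample
stability statistics ignore lag classes with fewer than 30 pairs in any
repetition. Abundance rebalancing before overall-area variograms removes
entities only from over-represented classes; the achievable subset size is
set by the scarcest class relative to its target share.

## Synthetic scene generator

The generator emulates an intensively farmed loess plain: defaults are
mean field area 2.06 ha with log-area spread parameter 0.8, crop shares
41% winter wheat / 28% sugar beet / 10% maize of the arable area (the
remainder an "other/bare" class), inter-field SD 1.0 LAI, intra-field
pixel SD 0.2 LAI, endmembers 0.90/0.15, k = 0.54, and 4% each of forest
and bare-ground reference area.

**Mosaic.** Binary space partitioning with jittered split positions gives
rectangular parcels. The total leaf count is fixed up front (domain area /
mean field area) and split counts cascade down with jittered area shares,
so the mean field area is exact by construction and the multiplicative
jitter cascade produces an approximately log-normal area spread. The
realized log-area SD (~0.65 at the default setting) is controlled by, but
not numerically equal to, the sigma parameter; the real field-size
distribution is unknown beyond summary statistics, so log-normal is a
modelling assumption, not a claim. Crops are assigned by a randomized
largest-remaining-deficit rule (fields visited in seeded random order,
each taking the crop furthest below its area target), which keeps realized
area shares within one field of the targets — plain i.i.d. sampling
fluctuates by several points at a few hundred fields.

**LAI curves.** Each crop has a four-parameter seasonal curve: zero before
emergence, logistic rise to the crop maximum at the peak day, linear
senescent decline to zero. Defaults reproduce the regional phenology
ordering — winter wheat greens up from early March (day 60, peak 140, max
7.3), sugar beet from mid-April (105, 185, 6.6), maize from mid-May (135,
190, 5.3) — with curve maxima set to simulated-canopy maxima for these
crops. Per-field offsets and the background field are sampled once per
scene seed (they represent persistent site quality), pixel noise per date.
True LAI is the clamped-at-zero sum of curve, field offset, background and
noise; forest pixels carry a constant high LAI, bare and fallow pixels
zero plus noise.

**Background field.** The km-scale component is a zero-mean stationary
Gaussian field with covariance sill·exp(−h/a), simulated by circulant
embedding on a 2×-padded torus (FFT diagonalization, eigenvalue clipping —
negligible for the exponential kernel at this padding). The exponential
covariance matches the exponential variogram family used in fitting, so
"truth" for recovery tests is well defined: a fitted range parameter
should equal the simulation's.

**Sensor model.** Red reflectance is held at 0.05 and NIR solved from the
target NDVI, since only NDVI matters downstream. When the land-use raster
is supplied, reference patches are written exactly at the endmembers
(forest = NDVI_v, bare = NDVI_s): a finite forest LAI pushed through the
FVC chain cannot reach NDVI_v, and the reference classes represent cover
types outside the crop LAI model anyway.

## What the synthetic tests show — and what they do not

Passing tests demonstrate that the analysis chain is internally correct
(exact round-trips, estimator/oracle equivalence, pooled-variance
identities) and that, on landscapes with the configured structure, the
method recovers that structure: short variogram ranges at field scale
(median ≈ 260 m for 2.06 ha fields, below the 325 m field-dimension
bound), long ranges when a km-scale background is present (median ≈ 4.2 km
for a 3 km effective-range background — recovered within the fit's
realization scatter), and pixel/field-mean accordance ≈ 0.90 in the
inter-field-dominated regime.

They do not show that real scenes satisfy the generator's assumptions:
real parcels are irregular, intra-field variability is spatially
structured (management tracks, soil patterns) rather than white, crop
calendars vary by farm, reflectance noise is not Gaussian or independent,
and real land-use maps contain misclassifications with no synthetic
counterpart. Accordance between pixel and field-mean distributions is also
intrinsically limited by the number of field entities: with a few hundred
fields the field-mean histogram is atomic at class-width resolution and
accordance cannot approach 1, which is why small demo scenes report much
lower values than full-size scenes (~1200 fields) or a real landscape
(~12000 fields). Segmentation merging of adjacent same-crop parcels is far
more frequent in the synthetic landscape (3–4 arable classes) than in a
detailed crop map; analyses that need true parcel identity should use the
generator's truth labels (`true_field_map`).

## Problem sizes

Default test and reproduction runs use scenes between 300×300 and
1500×1500 pixels, subsample fractions of 0.5–3%, and five seeds per
reported median; these sizes put every regime comfortably past its
statistical requirements (≥10³ fields for mosaic statistics, ≥5·10³
subsampled points per variogram) while keeping a full run of suite plus
reproduction script around a minute on one CPU.

## Known limitations

* The fit ladder's acceptance threshold (15% transition RMSE) is a
  pragmatic default, configurable in code but not exposed on the CLI.
* Variograms are isotropic; rectangular fields are anisotropic at the
  field scale, which slightly inflates short-range scatter.
* `other/bare` arable fields are simulated with zero mean LAI year-round;
  real fallow land carries catch crops and weeds with seasonal dynamics.
* Raster I/O writes plain single-band TIFF with a JSON metadata sidecar,
  not georeferenced GeoTIFF tags; coordinates are grid-relative.
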