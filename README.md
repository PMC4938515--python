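# laiscape

Spatial heterogeneity of leaf area index (LAI) on arable land: a tested
pipeline for retrieving LAI from two-band reflectance rasters, segmenting a
crop landscape into fields, quantifying spatial variability, and analysing
spatial structure with nested semivariogram models — together with a
synthetic agro-landscape generator so every stage can be exercised and
validated without proprietary satellite scenes.

It is aimed at researchers in agro-ecosystem modelling and vegetation
remote sensing who need LAI variability statistics (for flux modelling,
data assimilation, or downscaling studies) and want the full analysis chain
reproducible from raster to report.

## The science in brief

**Retrieval.** LAI is derived from NIR/Red reflectance via the normalized
difference vegetation index and fractional vegetation cover:

    NDVI = (NIR − Red) / (NIR + Red)
    FVC  = (NDVI − NDVI_s) / (NDVI_v − NDVI_s)
    LAI  = −ln(1 − FVC) / k

where NDVI_v and NDVI_s are per-date endmembers estimated by a histogram
analysis of permanently vegetated (broadleaf forest) and permanently bare
reference areas, and k = 0.54 is the Beer–Lambert light extinction
coefficient. NDVI below the soil endmember maps to LAI 0; retrieved LAI is
capped at 7.

**Fields.** Potentially mixed pixels — cells whose 8-neighbourhood is not
uniform in land use — are removed; the remaining uniform patches are
segmented into fields (4-connected components), and fields no larger than
the median area are excluded from field-level statistics.

**Variability.** Per-crop means and population SDs are combined into
overall statistics with abundance weights via the pooled variance (law of
total variance). Distributions are summarised as relative frequency
distributions (RFDs) with class width 0.1 LAI, compared by the accordance

    a = Σ_c min(D_a,c , D_b,c)

— the overlap of two relative frequency histograms, which equals 1 minus
their total-variation distance. A normal-distribution comparator RFD built
from a mean and SD provides the "is mean ± SD enough?" baseline.

**Structure.** Semivariograms are estimated with the classical Matheron
estimator on a random pixel subsample (default 0.5%), and a nested model
γ(h) = c₀ + Σᵢ cᵢ(1 − exp(−h/aᵢ)) with up to two exponential components is
fitted through a fallback ladder (start-value grid, alternative weighting,
zero nugget, simple model, 6 km cut-off). The effective range of a
component is 3aᵢ; in an arable landscape the short range reflects field
dimensions and the long range km-scale soil/weather gradients.

**Synthetic scenes.** The generator produces a rectangular-field mosaic
(binary space partitioning; mean field area 2.06 ha; crop shares 41/28/10%
winter wheat / sugar beet / maize), crop-specific seasonal LAI curves,
per-field offsets (inter-field variability), pixel noise (intra-field),
an optional exponential-covariance background field, and a forward NDVI
sensor model with forest/bare reference patches. The noiseless forward
model round-trips exactly through the retrieval chain.

## Worked example

```python
from laiscape import RunConfig, SceneConfig, run_pipeline

cfg = RunConfig(
    scene=SceneConfig(rows=400, cols=400, seed=1),
    dates=[175],                      # day of year: late June
    lag_width=100.0, max_lag=1500.0, subsample_fraction=0.03, seed=1,
)
report = run_pipeline(cfg)
d = report.per_date["175"]
print(d["endmembers"])
```

On this 2 × 2 km demo scene the run prints:

```
endmembers: {'ndvi_v': 0.9000000000000001, 'ndvi_s': 0.1499999999999999}
winter_wheat: mean=4.38 sd=0.91 acc_fieldmean=0.370 acc_normal=0.842
sugar_beet: mean=6.35 sd=0.73 acc_fieldmean=0.240 acc_normal=0.664
maize: mean=4.85 sd=0.88 acc_fieldmean=0.175 acc_normal=0.715
overall: mean=5.14 sd=1.24
overall variogram: short=376 m, step=1
```

Reading this: the per-date endmembers recovered from the scene's reference
patches are exact (0.90/0.15, the generator's truth); each crop's mean
sits on its seasonal curve for day 175 with SD ≈ 1 (the configured
inter-field variability, slightly reduced by clamping and the retrieval
cap); the overall SD (1.24) exceeds every single-crop SD because crops at
different phenological stages add between-crop variance — exactly the
pooled-variance behaviour expected mid-season. The accordance of pixel vs
field-mean distributions is low *on this small demo* because the segmented
landscape contains only a few dozen entities per crop (adjacent same-crop
fields merge); the regime analyses below show the landscape-scale
behaviour on full-size scenes. The fitted short range (376 m on a 100 m lag grid)
reflects field dimensions.

A command-line entry point mirrors the library
(`laiscape run --config run.yaml`, plus `retrieve`, `mask`, `segment`,
`filter-size`, `variogram`, `compare` for raster workflows).

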