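# Methods

This note documents the models and procedures implemented in
`palmconvert`, the assumptions behind them, the parameters that matter,
and the limits of what the synthetic test-bed can demonstrate.

## The analytical problem

Oil palm is repeatedly blamed for Indonesia's loss of old-growth
("primary") forest, but attributing deforestation to plantations requires
three distinct measurements: (i) how much old-growth forest was lost each
year; (ii) where and when oil-palm plantations were established; and
(iii) how often the two events coincide on the same land in the same
year. Each measurement comes from imperfect maps, so a fourth ingredient
— design-based accuracy assessment with error-adjusted area estimation —
quantifies how far the mapped totals can be trusted. A fifth asks whether
the annual rhythm of conversion tracks the crude-palm-oil (CPO) price.

## Change accounting

Forest loss in year *y* is the area of pixels whose annual tree-loss year
equals *y* **and** that lay inside the year-2000 old-growth mask; loss
outside the mask (regrowth, tree plantations) is excluded. Plantation
pixels established in 2001–2019 take exactly one of three fates:

* **rapid conversion** — forest in 2000, cleared in the same calendar year
  it was established. Same-year coincidence is the attribution criterion:
  a plantation appearing within months of clearing is very likely the
  cause of that clearing.
* **delayed conversion** — forest in 2000, cleared in an earlier year,
  planted later. The loss stays in its own loss year in the forest-loss
  series; the conversion is attributed to the establishment year.
* **on old non-forest** — established on land already cleared before 2000
  (or with no recorded loss).

Pixels planted before 2001 form the pre-2000 stock, outside the annual
expansion table. "Same calendar year" is integer equality of two annual
grids — both source products are annual, so no date arithmetic is
attempted. The accounting identity
`expansion = rapid + delayed + on_old_nonforest` holds exactly per year
and class, regional tables sum exactly to the national one, and
`Σ expansion + pre-2000 stock = 2019 plantation area`. On grids up to
50×50 the vectorized accounting is verified against a per-pixel loop
classifier, exactly.

Establishment years for smallholder plantations are dated from the
tree-loss grid under two assumptions: plantations are kept for the long
term (the 2019 extent bounds all expansion), and the tree-loss year is
the planting year (rapid conversion dominates empirically). Smallholder
pixels with no recorded loss are classed as pre-2000; smallholdings
established on land open since before 2001 are therefore undatable and
fold into the pre-2000 stock — a known, conservative bias. Industrial
establishment years come from the annual plantation mapping itself.

Pixel areas are constant for projected/synthetic grids (30 m → 0.09 ha)
and scale with the cosine of latitude for geographic grids (the
equal-area convention); summed cosine-law areas agree with the exact
spherical band formula to <0.1%.

## Compositing and NBR

Annual composites are built from cloud-masked observations (any
observation with the cloud bit set is dropped entirely) under two
criteria: the per-band, per-pixel **median**, and the **minimum-NBR**
selection, which copies all bands of the single observation with the
lowest normalized burn ratio, NBR = (NIR − SWIR)/(NIR + SWIR). The median
yields clean mosaics but can average away clearings late in the year; the
minimum-NBR composite is noisier but catches them. Both are exposed; the
pipeline records both. Even-count medians average the two central values;
minimum-NBR ties break to the earliest date; an undefined NBR
(NIR + SWIR = 0) propagates as missing and never wins the minimum.

## Conversion-year detection

A site's multi-date NBR series is averaged per calendar year and scanned
for consecutive-year drops. A drop qualifies if it is at least
`drop_threshold` (default 0.25 NBR units) and at least `persistence`
(default 2) raw observations from the drop year onward lie below the
midpoint of the pre- and post-drop annual means; the largest qualifying
drop wins and the post-drop year is returned. The defaults are free
parameters chosen to separate the synthetic pre-clearing (0.65) and
post-clearing (0.05) levels with noise sd 0.05; both are exposed.
Counting raw post-drop observations (rather than whole subsequent years)
keeps clearings in the final year of the record detectable.

## Accuracy assessment and adjusted areas

Reference sites are a stratified simple random sample from the map
classes (industrial / smallholder / other; the study allocation is
635/398/2,407 = 3,440 sites). Sites whose reference label is "unknown"
are removed before tabulation. With mapped-area weights `W_i` and cell
proportions `p_ij = W_i n_ij / n_i.`:

* `OA = Σ_j p_jj`, `UA_i = p_ii / Σ_j p_ij`, `PA_j = p_jj / Σ_i p_ij`;
* `V(UA_i) = UA_i(1−UA_i)/(n_i.−1)`; `V(OA) = Σ W_i² V(UA_i)`; PA by the
  stratified delta formula;
* adjusted area `Â_j = Σ_i A_i n_ij / n_i.`, with
  `SE(Â_j) = A_total √(Σ_i W_i² (n_ij/n_i.)(1−n_ij/n_i.)/(n_i.−1))`.

All CIs use z = 1.96 with no finite-population correction (the pixel
population is effectively infinite). The identity `Â_j = A_j·UA_j/PA_j`
is asserted at run time, as is exact closure `Σ_j Â_j = A_total`. Cohen's
kappa is computed from the raw sample counts, separately from the
area-weighted estimators. Published CI bounds are property-checked rather
than digit-matched, since the exact critical value behind them is not
recoverable from the printed tables.

## Price elasticity

The elasticity is the slope of an OLS fit of `ln(area_t)` on
`ln(price_t)` over calendar years — a 1% price change associates with a
β% change in conversion. Prices are annualized as arithmetic means of
the monthly USD series; pairing is contemporaneous (lag 0), with an
integer lag exposed because the true investment lag is unknown. Pearson's
r is reported on the logged series in the elasticity context and on raw
series when comparing against an external annual estimate, where the
zero-intercept slope `Σab/Σb²` summarizes proportional agreement. No
causal claim is made; this is an association in 19 annual observations.

## The synthetic landscape

The generator provides ground truth for every stage. It emulates:
industrial estates as large rectilinear blocks (8–25 cells a side) and
smallholdings as small irregular patches (5–40 cells); a clustered
year-2000 forest mask (smoothed-noise threshold, default 55% cover);
plantation pixels split into a pre-2000 stock (48%) and 2001–2019
expansion composed of 34% rapid / 3% delayed / 63% on old non-forest;
background clearing scaled so total forest loss is 3.16× the conversion
loss; establishment years drawn with probabilities proportional to a
price-coupled annual series `ln(area_t) = α + β ln(price_t) + ε`, ε ~
N(0, 0.10), β default 1.08, over monthly prices following a log random
walk (step sd 0.04) around 600 USD/t; multi-date 3-band observations (8
scenes/year, 30% cloud) whose NBR steps from 0.65 to 0.05 at clearing
with noise sd 0.05; and a degraded map with omission 8.3%/36.1% and
commission 4.7%/12.6% for industrial/smallholder. These defaults are the
study conditions where stated and field-plausible choices where not.
Randomness descends from one seed through fixed named substreams
(landscape, observations, prices, degradation, sampling), so every
generator is individually reproducible.

Two conventions are worth flagging. First, a pixel's clearing falls in
the first third of its labelled loss year, so the cleared state dominates
that year's observations — this encodes the annual dating convention of
a loss product (the label names the year the change is observed); without
it, pixels cleared near a year boundary are not attributable to either
year by any annual detector. Second, the observation model is a
statistical stand-in: bands are derived from the target NBR at fixed
brightness, with no atmospheric, phenological or sensor-geometry realism.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under the assumed error structure — not robustness to real
Landsat artifacts, mixed pixels, regrowth spectra or spatially correlated
classification error (the degradation model errs i.i.d. per pixel, which
real maps do not).

## Problem sizes and numerical choices

Test landscapes are 110–300 cells a side — large enough that the study's
full 3,440-site sample allocation fits in the "other" stratum, small
enough that the whole suite runs in seconds. Calibration checks use 200
replicates (adjusted-area CI coverage; elasticity CI coverage) against a
≥90% coverage bar for nominal 95% intervals. The end-to-end elasticity
check runs three replicate pipelines and requires coverage in at least
two, since single-run CI coverage is itself a ~95% event. Accounting is
done in full double precision with rounding only at report time
(percentages half-up to integers, Mha to two decimals); empty inputs
yield empty — not erroneous — tables; division by a zero total reports
NaN with a flag rather than raising.

## Known limitations

* Establishment-year dating via tree loss cannot see smallholder
  expansion onto long-open land; the generator reproduces this blind spot
  rather than correcting it.
* The elasticity regression has 19 annual observations; its CI is wide
  and the estimate is sensitive to weak price variation in any one draw.
* The error-rate model degrades classes independently per pixel; spatial
  correlation of mapping error would widen true sampling variances
  relative to the estimators' assumptions.
* Raster I/O uses plain TIFF with a JSON sidecar for codes and
  georeference; full GeoTIFF CRS handling is out of scope.
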