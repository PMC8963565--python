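# palmconvert

Annual accounting of oil-palm-driven forest conversion in Indonesia-style
landscapes: how much old-growth forest is lost each year, how much of that
loss is attributable to industrial and smallholder oil-palm expansion, how
trustworthy the underlying maps are, and whether conversion tracks the
crude-palm-oil price.

The package is written for remote-sensing and conservation analysts who
work with annual tree-loss grids, plantation maps and stratified
reference samples, and who need the bookkeeping and the design-based
statistics to be reproducible and testable rather than buried in ad-hoc
scripts.

## What it computes

**Change accounting.** Forest loss per year is the tree-loss grid
intersected with a year-2000 old-growth mask. Each plantation pixel
established in 2001–2019 is classified as *rapid conversion* (forest
cleared and planted the same calendar year — the attribution criterion),
*delayed conversion* (cleared first, planted later) or *expansion on old
non-forest*, with the identity `expansion = rapid + delayed +
old_nonforest` holding exactly per year, class and region.

**Design-based accuracy and adjusted areas.** From a stratified reference
sample with map classes as strata (area weights `W_i = A_i/A_total`,
`p_ij = W_i n_ij/n_i.`):

    OA  = Σ_j p_jj          UA_i = p_ii / Σ_j p_ij     PA_j = p_jj / Σ_i p_ij
    Â_j = Σ_i A_i n_ij/n_i.          (≡ A_j·UA_j/PA_j)

with stratified variance estimators, 95% CIs (z = 1.96) and Cohen's
kappa. `Σ_j Â_j = A_total` closes exactly.

**Supporting stages.** Annual median and minimum-NBR cloud-free
composites; base-map integration with fixed precedence (industrial >
pulp > coconut removal > smallholder); conversion-year detection from NBR
time series; log-log OLS price elasticity, `ln(area_t) = α +
β·ln(price_t)`; and a synthetic landscape generator with known ground
truth (configurable class fractions, conversion composition, price
coupling, observation noise, omission/commission rates) against which
every estimator is calibrated.

## Worked example

Run the full synthetic pipeline (generate → composite → integrate →
account → validate → correlate) from the shell:

```sh
palmconvert run-all --seed 0 --outdir example_out
```

On the default 200×200 landscape this prints, among other blocks:

```
=== 2019 mapped and adjusted extents ===
industrial   mapped 420 ha; adjusted 433 ha (CI 418 ha-449 ha)
smallholder  mapped 209 ha; adjusted 295 ha (CI 271 ha-318 ha)
mapped split   67% / 33%
adjusted split 60% / 40%

=== Map accuracy (stratified reference sample) ===
overall accuracy: 94.5% (CI 93.8-95.3); kappa 0.87
...
smallholder  UA  87.7% (CI 84.5-90.9)  PA 62.3% (CI 57.4-67.1)

=== Price elasticity (log-log OLS) ===
industrial expansion: beta 1.21 (CI 0.93-1.50), r 0.90, p 1.85e-07, n 19
```

Reading this: the map was degraded with 36.1% smallholder omission, and
the estimated producer's accuracy (62.3%) recovers that; the adjusted
smallholder area (295 ha) corrects the mapped 209 ha back toward the
truth; and the fitted price elasticity's CI covers the generator's true
β = 1.08. Intermediate artifacts (accounting tables, error matrix,
adjusted areas, elasticity fits, a manifest with checksums) are written
as CSV/JSON under `example_out/`.

The same stages are available individually (`simulate`, `composite`,
`integrate`, `account`, `validate`, `elasticity`, `agreement`) for real
raster and CSV inputs, and as library functions
(`palmconvert.conversion_accounting`, `palmconvert.adjusted_areas`, …).

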