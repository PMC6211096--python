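# defolmap

Mapping the severity of insect defoliation in pine forests from paired-date
satellite reflectance, calibrated against high-resolution ground-truth cells.

## The problem

Winter-feeding defoliators such as the pine processionary moth
(*Thaumetopoea pityocampa*) strip Mediterranean pine stands over a single
season. A 30 m multispectral sensor sees this as a change in canopy
greenness and moisture between a pre-outbreak and a post-outbreak
acquisition. `defolmap` turns that change signal into a four-class severity
map (nil / low / medium / high defoliation) and quantifies how well the map
agrees with interpreted ground truth — the workflow a forest-health analyst
needs when field data are scarce and ground truth comes from a handful of
photo-interpreted 30 m cells (e.g. from UAV orthoimagery).

## The method

For each acquisition the package computes five vegetation indices from the
red / NIR / SWIR bands (surface reflectance, integer-scaled ×10⁴):

| index | formula | behaviour under defoliation |
|-------|---------|------------------------------|
| MID   | B6 + B7 | rises |
| MSI   | B6 / B5 | rises (moisture stress) |
| NDMI  | (B5 − B6)/(B5 + B6) | falls |
| NDVI  | (B5 − B4)/(B5 + B4) | falls |
| NBR   | (B5 − B7)/(B5 + B7) | falls |

The change predictor is the difference `dVI = VI(pre) − VI(post)`
(symbol *X*). Each ground-truth cell contributes an observed defoliated
fraction *Y* ∈ [0, 1], interpreted at 5% intervals, and the calibration is a
two-parameter logistic

```
Y = 1 / (1 + e^−(a + bX))
```

fitted per index by maximizing the fractional-response Bernoulli
quasi-likelihood. Fit quality is McFadden's pseudo-R² on the deviance
scale; the best index's curve is inverted at the class boundaries
Y ∈ {0.10, 0.35, 0.70},

```
X = (ln(Y / (1 − Y)) − a) / b
```

giving the threshold limits that carve the dVI raster into the four
severity classes. Accuracy against the observed cells is reported as a
confusion matrix with producer's, user's and overall accuracy.

A synthetic-scene generator (paired band stacks driven by a known
defoliation field, with clouds, non-forest patches, reflectance noise and
5%-interval interpreter rounding) stands in for real imagery, so the whole
pipeline is testable end to end without any download.

## Worked example

```
$ defolmap run --preset default --seed 7 --out demo/
best index: dNDMI; overall accuracy at cells: 0.84
```

The run writes the synthetic inputs, per-index sample tables and fits, the
threshold set of the best model, the severity map and a manifest. For this
seed the manifest ranks the five indices by McFadden R²

```
dNDMI 0.929  >  dMSI 0.915  >  dNBR 0.897  >  dMID 0.885  >  dNDVI 0.724
```

and inverts the winning dNDMI fit into threshold limits
`(376, 1605, 2746)` (increasing orientation: larger dNDMI means more
defoliation). Classifying the dNDMI raster with those limits and comparing
the map against the 50 interpreted cells (10 nil / 23 low / 8 medium /
9 high) gives an overall accuracy of 0.84, with producer's accuracy 1.00
for nil, 0.78 for low, 0.63 for medium and 1.00 for high — the map
resolves the extreme classes cleanly and confuses neighbouring middle
classes, the typical behaviour of threshold classification on a continuous
response.

The same stages are available individually (`defolmap sim scene`,
`defolmap vi compute/dvi/stability`, `defolmap calib fit/thresholds/compare`,
`defolmap map classify/accuracy`) and as library functions.

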