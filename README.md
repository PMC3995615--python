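# dbmap — distance-based mapping of disease risk

`dbmap` estimates a smooth disease-risk surface over a planar study region
from case locations, whether those locations are exact coordinates
(*continuous* data) or administrative-unit centroids with case counts
(*discrete* data, e.g. ZIP-code or census-tract tallies).  It also ships a
complete simulation framework for quantifying how much localization accuracy
is lost when exact locations are aggregated to centroids — one facet of the
modifiable areal unit problem that matters to anyone running surveillance on
privacy-coarsened spatial data.

## The method

Let `S` be a disk-shaped study region, `F0` the distance distribution of the
expected ("reference") population and `X_1, …, X_n` the observed case
locations.  Fix `N` points `c_1, …, c_N` on a circle circumscribing `S`.
Each `c_i` defines a one-dimensional projection: the distance
`d = ‖c_i − X‖`, with empirical CDF `F̂_i` from the cases and reference CDF
`F0_i` (closed-form disk–disk lens areas for a uniform-disk reference, a
weighted step function for centroid-mass references).  At an evaluation
point `y`, take the reference-probability band of content `p0` centered at
`t = ‖c_i − y‖`,

    lo = F0_i⁻¹(F0_i(t) − p0/2),    hi = F0_i⁻¹(F0_i(t) + p0/2),

and score the projection by the observed-minus-expected band mass

    γ_i(y) = [F̂_i(hi) − F̂_i(lo)] − [F0_i(hi) − F0_i(lo)].

The disease score is the average `Γ(y) = (1/N) Σ_i γ_i(y)` over a lattice of
`r` grid points.  When observed equals expected, `Γ` is flat (zero in
expectation); case excess near `y` pushes `Γ(y)` up.  Working through
one-dimensional distance distributions sidesteps the curse of
dimensionality, and combining many projection angles recovers the spatial
information a single projection loses.  Defaults are `N = 20`, `p0 = 0.1`
(simulations) and `N = 40` for real centroid tables.

For discrete data the same construction runs on the centroid sample space:
cases and reference mass sit on the unit centroids, and every CDF becomes a
step function.  Color scales are calibrated by resampling datasets of the
observed size from the reference and pooling the null scores.

The simulation framework draws cases from the mixture
`f = 0.9·f0 + 0.1·g0` — uniform disk background plus a uniform square
cluster `C` of chosen side ("diameter") — aggregates them onto square
lattices of side 2/15, 0.2, 1/3 and 0.5, and scores every map by the AUC of
in-cluster vs out-of-cluster grid-point classification, plus a
difference-in-distances (DiD) statistic comparing the located high-risk area
against the cluster focus and the case-weighted average centroid.

## Worked example

`python examples/aggregation_effect.py` simulates one outbreak dataset
(100 cases, cluster diameter 0.2) and maps it from exact locations and at
four aggregation levels:

```
side 0.000 (exact locations): m = inf, AUC = 0.999
side 0.133 (centroid counts): m = 201, AUC = 0.998
side 0.200 (centroid counts): m =  88, AUC = 0.992
side 0.333 (centroid counts): m =  36, AUC = 0.988
side 0.500 (centroid counts): m =  16, AUC = 0.844
```

`m` is the number of aggregation cells intersecting the disk; the AUC is the
probability that a random in-cluster grid point outscores a random outside
one.  Fine aggregation barely hurts; once the cell side (0.5) exceeds the
cluster diameter (0.2), localization degrades sharply.  The other examples
map exact-location outbreaks (`map_outbreak.py`) and registry-style centroid
tables with population-at-risk references (`centroid_data_map.py`).

The same pipelines are scriptable from the shell:

```sh
dbm map cases.csv --out-dir out/            # point or unit-table CSV in,
                                            # map.csv + palette.csv + map.png out
dbm simulate config.yaml --out-dir sim/     # full aggregation-effect experiment
```

Every run writes a JSON manifest (inputs, seeds, achieved grid size `r` and
cell count `m`) sufficient to reproduce it.

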