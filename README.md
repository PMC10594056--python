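# vorogis

Quantitative spatial analysis of labelled cells in 2D microscopy fields,
built around the question of how Purkinje neurons (PNs) organize in
cultured cerebellar slices: Reelin-deficient (reln−/−) slices show PNs
clumped in a compact central mass, Reelin-competent ones a stratified
Purkinje cell layer, and co-cultures an intermediate, dispersing state.
The package turns a table of cell centroids into reproducible numbers that
discriminate these phenotypes, for cell biologists and image analysts who
would otherwise click through a GIS or spreadsheet workflow by hand.

Two complementary arms operate on the same calibrated point pattern:

**Voronoi cellular sociology.** The centroids are tessellated; marginal
polygons (site on the convex hull, or any vertex outside the hull) are
excluded; each retained polygon X contributes its area A(X), perimeter
L(X) and roundness factor RF = 4πA/L². The population topography indices
are

    RFav = (1/N) Σ 4π A(Xi) / L(Xi)²          mean roundness factor
    AD   = 1 − (1 + σ_A / A_av)⁻¹             area disorder
    RFH  = (1 + σ_RF / RFav)⁻¹                roundness-factor homogeneity

with AD → 0 and RFH → 1 for a perfectly ordered (congruent-polygon)
population.

**Hexbin spatial statistics.** The frame is tessellated with ≈400 regular
pointy-top hexagons and centroids are joined to cells. On the count raster
the package computes the geographic distribution summary (central feature,
mean/median center, standard distance, deviational ellipse), the
Clark–Evans average nearest neighbor index R = OMD/EMD, Getis–Ord General
G, global Moran's I (randomization moments, z, p), multi-distance Ripley's
K with a 99-permutation CSR envelope, Anselin Local Moran's I with
HH/LL/HL/LH cluster/outlier classes, and Gi* hot/cold spots with 90/95/99%
confidence bins, optionally Benjamini–Hochberg corrected. Class areas are
reported as percentages of the tessellation.

A synthetic generator (`vorogis.synthetic`) emulates the three phenotypes
plus complete spatial randomness, so the entire pipeline is testable
without imaging data, and `vorogis.inference`/`vorogis.power` provide the
group-comparison layer (ROUT outlier removal, Lilliefors KS normality,
ordinary/Welch/Brown–Forsythe ANOVA with Tukey or Dunnett T3 post-hoc
tests) and the Wilcoxon–Mann–Whitney a-priori sample-size calculator.

## Worked example

```python
from vorogis.pipeline import AnalysisConfig, analyze_slice
from vorogis.synthetic import PatternSpec, generate

pattern = generate(PatternSpec(kind="central_mass", n=300, seed=42))
report = analyze_slice(pattern, AnalysisConfig(seed=42))
```

prints (via the fields of `report`):

```
n points        : 300
retained cells  : 267
mean area (um2) : 161.3
RFav            : 0.7104
AD              : 0.4732
RFH             : 0.8754
ANN ratio R     : 0.7920  (z = -6.89)
Moran's I z     : 24.65
General G z     : 26.68
LISA HH percent : 1.50
```

Read: of 300 simulated PNs, 267 Voronoi polygons survive marginal
exclusion; their small mean area (161 μm²) and high RFH mark a dense,
fairly homogeneous clump. R < 1 with z = −6.9 means the points are
significantly closer together than a random pattern of the same intensity;
the very large Moran's I and General G z-scores say the hexagon counts are
strongly spatially clustered (high counts next to high counts) — the
signature of the central-mass phenotype. 1.5% of the tessellation is
flagged as significant high-high cluster area.

The same machinery is exposed as a CLI:

```sh
vorogis simulate layered slice.csv --n 300 --seed 7
vorogis analyze slice.csv --out report.json
vorogis power --d 2 --target 0.95
```

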