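# Methods

## Input contract and conventions

The universal input is a `PointPattern`: calibrated 2D centroids (μm) of
labelled cells inside a rectangular frame, with slice and group labels.
Coordinates keep the image convention (origin top-left, y downward) exactly
as exported from ImageJ/FIJI; every implemented statistic is invariant
under that reflection, and the deviational-ellipse rotation is reported in
this frame. All quantities are carried natively in μm — no unit
workarounds. The analysis frame defaults to the calibrated image rectangle
(e.g. 900×900 px × scale); the minimum enclosing rectangle of the points is
used only where an analysis conventionally defaults to it (the
nearest-neighbor index's study area and Ripley's K envelope), which means
isolated peripheral cells inflate that area — a property of the
convention, preserved deliberately.

## Voronoi cellular sociology

Tessellation is exact computational geometry (scipy's Voronoi/Qhull), not
a pixel raster: polygon areas and perimeters come from the shoelace
formula on the polygon ring, so small systematic differences from
rasterized particle measurements are expected and accepted. Preconditions:
≥3 sites, no duplicate sites within 1e-6 μm, not all collinear.

Marginal-polygon exclusion uses two conditions: (1) the cell is open —
its region is unbounded, equivalently its site lies on the convex hull of
the pattern; (2) any polygon vertex lies strictly outside the hull by more
than eps = 1e-9 × hull diameter. A vertex exactly on the hull counts as
inside, so polygons touching the hull are retained. Open cells carry no
area or perimeter and are never clipped to the frame; the exclusion rules
remove them. Zero retained cells is a legal outcome.

Index SDs use the sample convention (divisor N−1, the spreadsheet STDEV
default); population SDs are available via `ddof=0`. Whether the original
spreadsheet workflow used sample or population SDs is not documentable, so
both are supported.

## Hexagonal binning

Pointy-top hexagons, edge length a, horizontal spacing √3·a, row spacing
1.5·a, odd rows shifted half a cell. The default edge gives ≈400 analysis
hexagons over the frame: a = √(2·A_frame/(3√3·400)). The lattice extends
one partial ring beyond every frame edge so its union covers the frame,
but only hexagons whose *center* falls inside the frame are analysis
cells. Points are joined to the nearest in-frame center (exact hexagonal
containment for interior points; boundary-strip points are absorbed into
the adjacent in-frame cell; ties go to the lower cell index). The reason
is exposure balance: edge cells that overlap the frame only partially
receive systematically fewer points, and that deterministic low-count rim
is itself spatially clustered — on completely random input it biases
Moran's I strongly positive (measured mean I ≈ +0.08 on a ~500-cell
raster where −0.002 is expected). With equal-exposure analysis cells the
null calibration is clean (mean I within Monte-Carlo error of −1/(n−1),
5%-level type-I error ≈ 0.047).

Feature sets: global statistics (Moran's I, General G) run on the full
in-frame count raster — the empty hexagons carry the dispersion signal,
and a compact cell mass that occupies few hexagons is otherwise invisible
to them. Local statistics (Local Moran, Gi*) run on the occupied cells
only, mirroring the select-hexagons-with-cells step of the interactive
workflow this package replaces; the total in-frame hexagon count is kept
as the denominator of the class-area percentages. Hexagon size is a
controlled parameter and must be identical across compared groups; the
comparison layer enforces this.

## Spatial weights

Two conceptualizations: inverse Euclidean distance (w_ij = 1/d_ij within a
cutoff) and fixed distance band (binary). The default cutoff is the
maximum nearest-neighbor distance among features — the smallest distance
guaranteeing every feature at least one neighbor. Optional row
standardization. Coincident features under inverse distance get the capped
weight 1/ε with ε = 1e-6 μm and a warning. Gi* weights include the self
term (w_ii = 1).

## Global statistics

* **ANN**: OMD = mean nearest-neighbor distance; EMD = 0.5/√(n/A);
  R = OMD/EMD; SE = 0.26136/√(n²/A); z = (OMD−EMD)/SE. The standard
  Clark–Evans reading applies: R < 1 clustering, R > 1 dispersion. (Some
  published prose inverts this reading; the package documents and uses the
  standard convention.) No edge correction; under CSR the mean R carries a
  small positive bias (calibrated to [0.97, 1.06] at n=1000).
* **General G** (Getis–Ord 1992): G = Σw_ij x_i x_j / Σx_i x_j (i≠j),
  E[G] = S0/(n(n−1)), randomization variance from the standard moment
  formulas (requires n ≥ 4 and non-negative values with at least two
  distinct).
* **Moran's I**: I = (n/S0)·(Σw_ij z_i z_j/Σz_i²), E[I] = −1/(n−1),
  variance under the randomization assumption. Inference is analytic
  (moment-based z) by default; conditional permutation (999 by default,
  seeded) is available.
* **Ripley's K**: K(d) = A·ΣΣ 1[d_ij ≤ d]/(n(n−1)), L = √(K/π), no edge
  correction (flagged in metadata); the envelope is the pointwise min/max
  of n_perm (default 99) CSR simulations conditioned on n in the minimum
  enclosing rectangle. Maximum distance is capped at half the shorter
  frame side.

## Local statistics

Local Moran uses the classic Anselin scaling I_i = (z_i/m2)·Σw_ij z_j with
m2 = Σz²/n, which makes the LISA decomposition exact: Σ I_i = S0·I_global.
Default inference is conditional permutation (999, seeded): feature i's
value is held fixed, the remaining values are permuted into its
neighborhood; the analytic alternative uses the exact conditional
sampling-without-replacement moments. Significant features (p ≤ 0.05, or
BH-adjusted p when the FDR variant is on) are classified by the quadrant
rule — own value above/below the mean × spatial lag above/below the mean
lag (ties within 1e-12 → NS) — into HH/LL clusters and HL/LH outliers.
Note a consequence of conditional inference: a lone high cell among
neighbors whose values are typical of the pool is *not* significant; HL
outliers require a neighborhood that is extreme relative to the value
distribution.

Gi* follows Ord–Getis (1995) with self-inclusive weights; z thresholds
1.645/1.960/2.576 give the 90/95/99% hot/cold bins, the sign giving hot
vs cold. The "optimized" variants are implemented as the same statistics
plus Benjamini–Hochberg FDR over the per-feature p before classification;
automatic incident aggregation and scale selection are out of scope
because the hexagon size is an explicit, cross-group-constant parameter.

Class-area percentages are 100·n_class/n_total over the in-frame
tessellation cell count, so unoccupied area contributes to the
denominator.

## Group inference

Analysis order for per-slice summaries follows the study design: ROUT
outlier check (Q = 1%) → Kolmogorov–Smirnov normality with the Lilliefors
correction (parameters estimated from the sample; the plain fixed-parameter
KS is available) → the ANOVA suite. All three omnibus tests are always
computed: ordinary one-way ANOVA with Tukey HSD, Welch's heteroscedastic
ANOVA, and the Brown–Forsythe equality-of-means F* (both with fractional
Satterthwaite df). Unequal-variance post-hoc comparisons use Dunnett T3
(Welch t per pair, studentized-maximum-modulus adjustment, computed by
numeric integration of the SMM distribution). Welch and the ordinary F
coincide exactly for two equal-variance equal-size groups and only
asymptotically for k ≥ 3 (Welch's denominator correction).

ROUT is implemented for the constant (location-only) model, the use case
here: robust center = median, scale = RSDR (68.27th percentile of absolute
residuals × n/(n−1)), per-point t statistic with df = n−1, then an FDR
scan from the most extreme point at thresholds α_i = Q(n−i+1)/n, stopping
at the first non-significant point. Full nonlinear-regression ROUT is out
of scope.

## Power calculator

The a-priori sample-size routine reproduces the Wilcoxon–Mann–Whitney
(normal parents) dialog: for equal groups of size n, the t-test
noncentrality δ = d·√(n/2) is scaled by √(3/π) (the WMW asymptotic
relative efficiency under normal parents) and the df become N·(3/π) − 2,
fractional; the critical t is the two-sided central-t quantile at α and
achieved power comes from the noncentral t. n is incremented from 2 until
the target power is reached. The plain unpaired-t calculator is also
provided. This construction regenerates the published parameter block
(δ = 3.9088201, critical t = 2.1557656, df = 13.2788745, n = 8+8,
power = 0.9508778) exactly, which is why it was chosen over the dialog's
ambiguous labelling.

## Synthetic phenotype generator

Static snapshots, not a migration simulation. Defaults (all overridable):
frame 900×900 μm, n = 300 per pattern.

* `central_mass`: Gaussian mixture of two isotropic clusters, σ = 40 μm,
  centers 150 μm apart about the frame center — two adjacent high-density
  areas like those seen in reln−/− single cultures.
* `layered`: three concentric bands 80 μm apart (radii 160/240/320 μm,
  chosen to fit comfortably inside the frame) with 12 μm Gaussian radial
  spread and uniform angle; full rings by default (an angular-range
  parameter allows arcs).
* `dispersing`: per-point Bernoulli(λ) mixture of the two, λ = 0.5
  (exact degeneration to the pure components at λ = 0/1).
* `csr`: uniform on the frame, the null for calibration.

Out-of-frame draws are rejected and redrawn (preserving the distribution
shape inside the frame; a rejection rate above 99% raises an error).
`triad()` derives the three phenotypes from one seed via fixed child-seed
offsets (+1/+2/+3).

**What the generator does and does not emulate.** It reproduces the
density contrasts that drive the global statistics — and indeed the
phenotype ordering of the global clustering z-scores (central mass >
dispersing > layered for both Moran's I and General G), the mean
retained-polygon area (lowest for the central mass) and the RFH direction
(highest for the central mass) are recovered robustly over seeds. It does
not emulate slice-wide scattered single cells, irregular slice outlines,
or extended (several-hundred-μm) central masses with flat density cores.
Three consequences, measured and accepted rather than papered over:

1. The Gaussian central mass spans a ~20-fold intensity range inside its
   hull, so its retained Voronoi areas are strongly heterogeneous
   (cv ≈ 0.97) and its AD is *not* lower than the layered pattern's —
   the AD axis of the order/disorder diagram does not reproduce the real
   slices' direction under these defaults (the RFH axis does).
2. Cluster-class area percentages are footprint-driven: the bands and the
   dispersed mixture tile several times more hexagons than the compact
   mass, so HH% is not highest for the central mass, and LL% is ≈ 0
   everywhere (counts are bounded below by zero, so low values are never
   extreme under permutation).
3. The λ = 0.5 mixture halves each component's density, so its mean
   nearest-neighbor distance is close to (not between) the pure patterns';
   only the central-mass dominance of OMD is asserted.

Passing tests therefore demonstrate correct machinery and the density-
contrast orderings, not a full replica of cultured-slice morphology.

## Numerical choices and degenerate inputs

Weiszfeld iteration for the median center: tolerance 1e-8 μm on the step,
cap 10,000 iterations, standard perturbation when an iterate lands on a
data point (a majority data point is returned directly — it is the
median). Deviational ellipse and standard distance use divisor n (no df
correction); collinear input yields a zero-minor-axis ellipse flagged
degenerate rather than an error. Duplicate Voronoi sites, constant fields,
all-zero values and degenerate rectangles raise typed errors early.
Permutation inference is seeded everywhere; identical config + seed gives
byte-identical reports.

## Problem sizes

Default simulation sizes were chosen to keep the statistical checks
well-powered at desk scale: 500 CSR rasters for the Moran null, 200×n=1000
patterns for the ANN calibration, 50 envelope runs for Ripley coverage,
20 triad seeds for ordering checks, 999 conditional permutations for
local statistics.

## Deposited-data re-analysis

`vorogis.deposited` can recompute the per-slice indices and group ANOVAs
from the study's deposited per-polygon tables (Figshare DOIs
10.6084/m9.figshare.21063616/21063517/21063280) when those files are
available locally. Nothing downloads automatically and no offline test
depends on them.

## Known limitations

2D only — no treatment of optical-section (Z-stacking) selection effects;
supplied centroids are taken as ground truth. No edge correction in ANN or
Ripley's K (the conventions mirrored here). No geodesic distances, no
Manhattan metric, no square/triangular tessellations. ArcGIS bit-parity is
not a goal: the deviational-ellipse df convention and the "optimized"
tools' automatic scale search are version-dependent features replaced by
documented fixed choices.
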