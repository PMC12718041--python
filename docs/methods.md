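# Methods

## Coordinate frame and depth reference

All geometry lives in a vine-centred Cartesian frame in centimetres:
x inter-row, y along the planting row, z vertical positive up, origin at
the grafting point. Two planes matter for depth-based traits:

| parameter        | default | meaning                                                  |
|------------------|---------|----------------------------------------------------------|
| `soil_surface_z` | −5 cm   | graft union sits ~5 cm above the soil                    |
| `stem_base_z`    | −25 cm  | rooted cuttings planted ~20 cm deep; roots attach here   |

Depth is always `soil_surface_z − z`, so every depth-based trait takes the
surface plane explicitly and both planes are per-plant configurable. The
published tables for comparable field data do not state unambiguously
whether layer boundaries are referenced to the soil surface or the graft
origin (a ~5 cm offset); the reader therefore exposes the reference as
configuration rather than guessing, and the RSML reader has a `flip_z`
flag for depositories that store depth as positive-down coordinates.

The buried stem section is stored as stem geometry and never counted as
root length, mirroring how excavated vines are weighed by compartment.

## Length partitioning (layers, grid, planting box)

Each digitized root is a polyline; every trait operates on its straight
segments. For any region system (horizontal soil layers, XY grid cells,
the planting-area box), a segment's full 3-D Euclidean length is allocated
in proportion to the fraction of its linear parametrization whose
projection falls in each region — an exact line integral obtained by
clipping the parameter interval against region boundaries. This
"proportional" rule is the unique allocation that conserves total length
and equals the limit of infinitely fine subdivision; the coarser
convention of splitting a segment's length *equally* among all layers it
touches is available as `mode="equal"` for comparison with simpler
implementations. Length above the soil surface accrues to an explicit
`above` bucket and length below the last boundary to `below`, so the layer
partition sums to the total exactly (tests enforce < 1e-9 relative error).

Grid cells follow `cell (i, j) = [i·c, (i+1)·c) × [j·c, (j+1)·c)` with
c = 10 cm and the stem at (0, 0). The Directional Bias Index classifies
cells by their centre offsets: |y| > |x| counts as along-row (L_v),
|x| ≥ |y| as inter-row (L_h), and `DBI = (L_h − L_v)/(L_h + L_v)`. Both
sums use absolute cell coordinates so the index is invariant under
reflecting either axis — the row direction is an arbitrary sign — and
diagonal ties go to the inter-row sum. Degenerate inputs (zero total
length) yield NaN with a warning rather than an exception.

The planting-area box defaults to x ∈ [−100, 100], y ∈ [−50, 50] cm
(the 2 m × 1 m soil allocation per vine); the outside fraction ignores
depth and is computed by the same exact clipping.

## Hulls, spread, aspect ratio

Convex hulls use Qhull (scipy); the 3-D volume is reported in dm³ and the
XY-projection area in dm². Point clouds that are coplanar (3-D) or
collinear (2-D) — typical for very young plants — return 0 with a
`degenerate` flag instead of raising, so batch runs never abort on one
sparse root system. Maximum horizontal spread is the diameter of the XY
projection of the segment endpoints (computed on the 2-D hull vertices);
an alternative definition, twice the maximal radial distance from the
stem, is available as `mode="radial"` because published spread values do
not always state which convention the source software used. The aspect
ratio divides the x-extent by the y-extent of the projected hull; values
below 1 mean elongation along the planting row.

## Leaf area

Single-leaf area is estimated from the two digitized secondary vein
lengths (straight-line PL3→PL5 and PL3→PL6 distances) as
`area = c · (L_left · L_right)^k`. The default `c = 0.9, k = 1.0` is an
**uncalibrated placeholder**: cultivar-specific coefficients from a
destructive leaf-area calibration must be supplied to reproduce absolute
leaf areas. Exclusion rules applied at digitization time (apical internodes
< 1 cm, primary vein < 3 cm) are not re-filtered here; violations produce
a validation warning only.

## SMA allometry

Standardized major axis regression on log-transformed trait pairs:
slope `b = sign(r)·s_y/s_x`, intercept through the bivariate mean,
`R² = r²`, and the standard 95 % slope interval
`b·(√(B²+1) ± B)` with `B = √[(1−r²)/(n−2)]·t₀.₉₇₅,ₙ₋₂`. Logs are base 10
by default; slope and R² are base-invariant, the intercept is not, which
matters when comparing published intercepts whose base is unstated. Fits
require n ≥ 3 strictly positive values and refuse zero-variance axes. No
common-slope test across groups is provided; per-group fitting is a
grouping option of the same operation.

## PLS-DA

Class membership is dummy-coded (one centred, unit-variance column per
class); predictors are centred and scaled to unit variance (sample sd).
Components are extracted with the classical NIPALS PLS2 iteration
(convergence 1e-13 relative on the score vector, 1000 iterations max),
deflating both blocks by the X-scores. Y-scaling mirrors the common
reference implementations, which scale the dummy block even though only
X-scaling is usually reported. Signs are fixed so the largest-magnitude
X-loading entry of each component is positive, making runs reproducible.
R²X/R²Y are cumulative explained sum-of-squares fractions;
`VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` so mean(VIP²) = 1.

Q² uses stratified k-fold cross-validation (7 folds by default — the
customary default where the source analysis does not state a count — and
never more folds than the smallest class). Each fold refits the model,
including the scaling, on the training plants only and predicts the
held-out dummy responses with the full-component regression coefficients;
`Q²cum = 1 − PRESS/TSS` on the centred scaled dummy matrix. Fold
assignment is fixed by an explicit seed. An optional label-permutation
test provides a p-value for Q².

## Synthetic architecture generator

The generator emulates the statistical structure of excavated field-grown
grafted vines so every pipeline stage can be exercised without excavation
data. Roots grow by discrete apical steps: the heading blends its previous
direction with a gravitropic pull `g` toward −z, a planting-row pull
`β` toward ±y (each axis prefers one row direction), and isotropic
Gaussian noise. The row pull decays geometrically along each axis
(`row_bias_decay = 0.75` per step) — young tips follow the loosened
planting-row soil, older tips wander or dive — which keeps the along-row
extent realistic. Laterals initiate at `branch_density` per cm behind a
10 cm apical zone, leave roughly perpendicular, and recurse to order 2
with geometrically reduced step lengths. Shoots are phytomer chains with
lognormal internodes, Bernoulli lateral shoots and six-landmark leaves;
time points after leaf fall (T2, T4) carry no leaves.

Growth schedules map the four excavation ages to cumulative step counts
(roots 5/10/12/18; shoots 4/12/22/40); the small T2→T3 increment encodes
winter dormancy. Dry weights are per-tissue linear densities × organ
length with lognormal noise, multiplied by an age-dependent secondary
thickening factor (0.16/0.40/0.70/1.0 at T1–T4). The thickening factor is
what makes specific root length fall from ~150–200 cm g⁻¹ in the first
summer to ~25–40 cm g⁻¹ after two seasons and puts the cross-age SMA
slopes near 0.9–1.0 with R² > 0.8, as observed for real vines.

The three default archetypes (`deep`, `shallow_wide`, `intermediate`)
were parameterized once to land in the realistic range for an 18-month
field vine — total root length ~4–6 × 10³ cm, rooting depth 1.2–1.8 m,
spread 1.2–1.6 m, ≤ ~12 % of root length outside the planting area, DBI
negative for every plant, root:shoot dry-weight ratio ~0.8–2 — while
building in the habit orderings the analysis is meant to detect (depth and
below-ground allocation: deep > intermediate > shallow; spread and shoot
investment: the reverse). They reproduce orderings, not the exact trait
means of any particular genotype; matching a specific genotype is a user
calibration exercise. Every plant draws from an independent child stream
of `(master_seed, plant_index)`, so one master seed fixes every generated
byte and cohorts can be extended without perturbing existing plants.

What passing tests on synthetic cohorts do **not** show: real excavations
have digitizer noise correlated along axes, root loss and breakage during
excavation, soil-driven heterogeneity (stones, moisture layers) and
between-block field effects, none of which the generator emulates.
Pipeline correctness on synthetic data therefore validates the estimators
and their invariants, not field accuracy of any particular trait value.

## Numerical choices and degenerate inputs

* Attachment of a child root to its parent is checked against the parent's
  polyline continuum with a 0.5 cm tolerance (digitizer noise scale);
  exceeding it warns rather than errors.
* RSML files declaring non-centimetre units are rejected outright — no
  silent rescaling.
* Zero-length segments (duplicate digitized points) are retained and
  contribute zero length everywhere.
* Warnings, not exceptions, for: empty/degenerate hulls, zero along-row
  extent (aspect ratio NaN), zero total length (DBI and outside fraction
  NaN), missing dry weights (missing ratios). Batch trait-table assembly
  never aborts on a single degenerate plant.
* Test problem sizes (100 random systems for property/oracle sweeps,
  1e4-step subdivision oracles, 1e6-sample Monte-Carlo hull checks,
  200-replicate SMA recovery, 24-plant PLS-DA cohorts) were chosen as the
  package's own verification budget; all are generated programmatically at
  run time.

## Known limitations

* Root diameters are not digitized, so no volume/biomass-from-geometry
  traits; SRL requires measured dry weights.
* The leaf-area model is a two-parameter power law on vein lengths;
  lobing and curvature beyond the six landmarks are invisible to it.
* PLS-DA is limited to predictive components (no orthogonal/OPLS variant)
  and dense numeric trait tables.
* The generator is phenomenological: no soil–root interaction, water
  uptake or carbon balance.
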